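"""Session recordings, stimulus timelines and the wearable packet codec.

The wearable streams 20-byte notification packets at a nominal 100 Hz, each
carrying one reading per sensor (PPG, EDA, EMG, SKT).  Off-line analysis works
on :class:`SessionRecording` objects loaded from CSV files or from raw packet
streams.  All times are seconds on the sample grid ``index / sample_rate_hz``,
0-based.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

REQUIRED_CHANNELS = ("ppg", "eda", "skt")
OPTIONAL_CHANNELS = ("emg",)
EMOTIONS = ("joy", "anger", "fear", "disgust", "sadness", "neutral", "blank")

#: maximum dropout run (seconds) that is linearly interpolated; longer runs are
#: filled too but flagged unusable in the gap report
MAX_INTERP_GAP_S = 0.5


class SchemaError(ValueError):
    """A file is missing required channels or columns."""


class PacketFormatError(ValueError):
    """A byte string is not a valid 20-byte sample packet."""


# ---------------------------------------------------------------------------
# sample packets
# ---------------------------------------------------------------------------

#: little-endian: u16 seq, u16 ppg, u16 eda, u16 emg, i16 skt (centi-degC),
#: 10 reserved zero bytes -> 20 bytes total
_PACKET = struct.Struct("<HHHHh10x")
PACKET_SIZE = 20
SEQ_MODULUS = 65536


@dataclass(frozen=True)
class SamplePacket:
    """One wearable notification packet: a sequence counter plus the four
    sensor readings.  PPG/EDA/EMG are raw unsigned ADC counts; SKT is signed
    centi-degrees Celsius."""

    seq: int
    ppg: int
    eda: int
    emg: int
    skt_centi_degc: int

    def __post_init__(self) -> None:
        for name in ("seq", "ppg", "eda", "emg"):
            v = getattr(self, name)
            if not 0 <= v <= 0xFFFF:
                raise ValueError(f"{name}={v} outside unsigned 16-bit range")
        if not -0x8000 <= self.skt_centi_degc <= 0x7FFF:
            raise ValueError(
                f"skt_centi_degc={self.skt_centi_degc} outside signed 16-bit range"
            )


def encode_packet(p: SamplePacket) -> bytes:
    """Serialize a packet to its 20-byte wire form."""
    return _PACKET.pack(p.seq, p.ppg, p.eda, p.emg, p.skt_centi_degc)


def decode_packet(raw: bytes) -> SamplePacket:
    """Decode a 20-byte wire packet; inverse of :func:`encode_packet`."""
    if len(raw) != PACKET_SIZE:
        raise PacketFormatError(
            f"expected {PACKET_SIZE}-byte packet, got {len(raw)} bytes"
        )
    seq, ppg, eda, emg, skt = _PACKET.unpack(raw)
    return SamplePacket(seq, ppg, eda, emg, skt)


# ---------------------------------------------------------------------------
# session recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapRun:
    """A run of missing samples in one channel, as found at load time."""

    channel: str
    start: int          # first missing sample index
    stop: int           # one past the last missing index
    usable: bool        # True if short enough to interpolate safely

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class SessionRecording:
    """Synchronized multi-channel biosignal arrays on a common sample grid.

    ``channels`` must contain "ppg", "eda" and "skt"; "emg" is optional and
    never used for feature extraction.  Units are raw ADC counts except SKT,
    which is degrees Celsius.
    """

    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0
    units: dict[str, str] = field(default_factory=dict)
    gap_report: list[GapRun] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise SchemaError(f"missing required channels: {missing}")
        lengths = {name: len(a) for name, a in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch: {lengths}")
        self.channels = {
            name: np.asarray(a, dtype=float) for name, a in self.channels.items()
        }
        for name in REQUIRED_CHANNELS:
            if np.isnan(self.channels[name]).any():
                raise ValueError(f"NaN in required channel {name!r} after load")
        if not self.units:
            self.units = {name: "adc" for name in self.channels}
            self.units["skt"] = "degC"

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate_hz


def _fill_gaps(values: np.ndarray, channel: str, sample_rate_hz: float
               ) -> tuple[np.ndarray, list[GapRun]]:
    """Fill NaN runs (dropped packets) by linear interpolation and report each
    run.  Runs longer than MAX_INTERP_GAP_S are filled too, so downstream code
    never sees NaN, but flagged unusable."""
    isnan = np.isnan(values)
    if not isnan.any():
        return values, []
    runs: list[GapRun] = []
    max_n = int(round(MAX_INTERP_GAP_S * sample_rate_hz))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        runs.append(GapRun(channel, int(start), int(stop),
                           usable=(stop - start) <= max_n))
    filled = (
        pd.Series(values)
        .interpolate(method="linear", limit_direction="both")
        .to_numpy()
    )
    return filled, runs


def read_session(path, sample_rate_hz: float = 100.0) -> SessionRecording:
    """Load a session CSV (header ``t_s,ppg,eda,skt[,emg]``).

    Rows with missing readings in required channels are treated as BLE
    dropouts: gaps are filled per the gap policy and listed in the returned
    recording's ``gap_report``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required channels {missing}")
    channels: dict[str, np.ndarray] = {}
    report: list[GapRun] = []
    for name in REQUIRED_CHANNELS + OPTIONAL_CHANNELS:
        if name not in df.columns:
            continue
        filled, runs = _fill_gaps(
            df[name].to_numpy(dtype=float), name, sample_rate_hz
        )
        channels[name] = filled
        report.extend(runs)
    t0 = float(df["t_s"].iloc[0]) if "t_s" in df.columns and len(df) else 0.0
    return SessionRecording(
        sample_rate_hz=sample_rate_hz, channels=channels, t0=t0, gap_report=report
    )


def write_session(session: SessionRecording, path) -> None:
    """Write a session to CSV, inverse of :func:`read_session` for gap-free
    recordings (bit-exact via repr-round-tripping floats)."""
    cols = {"t_s": session.times}
    for name in REQUIRED_CHANNELS + OPTIONAL_CHANNELS:
        if name in session.channels:
            cols[name] = session.channels[name]
    # %.17g guarantees binary64 -> text -> binary64 identity
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_packet_stream(path, sample_rate_hz: float = 100.0) -> SessionRecording:
    """Assemble a session from a raw binary file of concatenated 20-byte
    packets.  Dropped packets (sequence-counter jumps, modulo 65536) become
    gaps handled by the same gap policy as CSV loading."""
    raw = open(path, "rb").read()
    if len(raw) % PACKET_SIZE:
        raise PacketFormatError(
            f"stream length {len(raw)} is not a multiple of {PACKET_SIZE}"
        )
    packets = [decode_packet(raw[i:i + PACKET_SIZE])
               for i in range(0, len(raw), PACKET_SIZE)]
    if not packets:
        raise ValueError("empty packet stream")
    # place packets on a virtual grid by unwrapped sequence number
    idx = [0]
    for prev, cur in zip(packets, packets[1:]):
        step = (cur.seq - prev.seq) % SEQ_MODULUS
        idx.append(idx[-1] + max(step, 1))
    n = idx[-1] + 1
    arrays = {name: np.full(n, np.nan) for name in ("ppg", "eda", "emg", "skt")}
    for i, p in zip(idx, packets):
        arrays["ppg"][i] = p.ppg
        arrays["eda"][i] = p.eda
        arrays["emg"][i] = p.emg
        arrays["skt"][i] = p.skt_centi_degc / 100.0
    channels, report = {}, []
    for name, vals in arrays.items():
        filled, runs = _fill_gaps(vals, name, sample_rate_hz)
        channels[name] = filled
        report.extend(runs)
    return SessionRecording(sample_rate_hz=sample_rate_hz, channels=channels,
                            gap_report=report)


def write_packet_stream(session: SessionRecording, path) -> None:
    with open(path, "wb") as fh:
        emg = session.channels.get("emg")
        for i in range(session.n_samples):
            p = SamplePacket(
                seq=i % SEQ_MODULUS,
                ppg=int(round(session.channels["ppg"][i])),
                eda=int(round(session.channels["eda"][i])),
                emg=int(round(emg[i])) if emg is not None else 0,
                skt_centi_degc=int(round(session.channels["skt"][i] * 100)),
            )
            fh.write(encode_packet(p))


# ---------------------------------------------------------------------------
# stimulus timelines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    start_s: float
    duration_s: float
    label: str
    target_emotion: str = "neutral"
    media_ref: str | None = None

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        if self.target_emotion not in EMOTIONS:
            raise ValueError(f"unknown target_emotion {self.target_emotion!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class StimulusTimeline:
    """Ordered stimulus schedule; blank/inter-stimulus gaps are explicit
    events with ``target_emotion='blank'``."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [e.start_s for e in self.events]
        if starts != sorted(starts):
            raise ValueError("events must be sorted by start_s")

    @property
    def total_duration_s(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].end_s - self.events[0].start_s

    def stimuli(self) -> list[StimulusEvent]:
        """Events that are actual stimuli (not blank gaps)."""
        return [e for e in self.events if e.target_emotion != "blank"]


def build_iaps_timeline(
    n_pictures: int,
    display_s: float,
    blank_s: float,
    labels: list[str],
    target_emotions: list[str] | None = None,
    start_s: float = 0.0,
) -> StimulusTimeline:
    """Alternating picture/blank schedule of the still-picture protocol:
    each picture shown ``display_s`` seconds followed by a ``blank_s`` blank
    screen, so total duration is ``n_pictures * (display_s + blank_s)``."""
    if n_pictures != len(labels):
        raise ValueError(f"n_pictures={n_pictures} != len(labels)={len(labels)}")
    if n_pictures and (display_s <= 0 or blank_s < 0):
        raise ValueError("durations must be positive")
    if target_emotions is None:
        target_emotions = ["neutral"] * n_pictures
    if len(target_emotions) != n_pictures:
        raise ValueError("target_emotions length mismatch")
    events: list[StimulusEvent] = []
    t = start_s
    for label, emo in zip(labels, target_emotions):
        events.append(StimulusEvent(t, display_s, label, emo))
        t += display_s
        events.append(StimulusEvent(t, blank_s, "blank", "blank"))
        t += blank_s
    return StimulusTimeline(events)


def read_timeline(path) -> StimulusTimeline:
    """Read a stimulus annotation file (CSV or YAML) with fields
    ``start_s,duration_s,label,target_emotion``."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            rows = yaml.safe_load(fh) or []
    else:
        rows = pd.read_csv(path).to_dict("records")
    events = [
        StimulusEvent(
            float(r["start_s"]), float(r["duration_s"]),
            str(r["label"]), str(r.get("target_emotion", "neutral")),
            r.get("media_ref"),
        )
        for r in rows
    ]
    return StimulusTimeline(events)


def write_timeline(timeline: StimulusTimeline, path) -> None:
    rows = [
        {"start_s": e.start_s, "duration_s": e.duration_s, "label": e.label,
         "target_emotion": e.target_emotion}
        for e in timeline.events
    ]
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)
    else:
        pd.DataFrame(rows, columns=["start_s", "duration_s", "label",
                                    "target_emotion"]).to_csv(path, index=False)
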