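"""Synthetic wearable-session generator with known ground truth.

Emulates a recording session: a relax (baseline) period, then scripted
emotional episodes.  Each episode produces the canonical orienting-response
morphology — a cardiac deceleration beginning ~1 s before a skin-conductance
response onset (deceleration is immediate at the stimulus, the electrodermal
onset is latent) — followed by a sustained heart-rate level shift and a slow
fingertip-temperature trend, with per-channel Gaussian noise on top.

* PPG: Gaussian pulses (FWHM 80 ms) at beat times obtained by integrating
  the instantaneous heart-rate profile; riding on a mid-scale ADC baseline.
* EDA: tonic level plus bi-exponential SCRs (rise tau 1 s, decay tau 4 s).
* SKT: baseline plus per-episode linear trends (deg C / min); after an
  episode ends the excursion relaxes back to the thermoregulated set point
  with an exponential time constant (skin temperature is homeostatic).
* All three channels additionally carry a slow baseline drift (band-limited
  noise below ~0.01 Hz) emulating resting autonomic tone wander, so relax-
  period statistics — and the deadbands derived from them — are non-trivial.

Fixed seed => bit-identical output.  Not modelled: dicrotic notch, motion
artifacts, respiration, EMG, between-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import SessionRecording, StimulusTimeline, build_iaps_timeline

SCR_TAU_RISE_S = 1.0
SCR_TAU_DECAY_S = 4.0
PPG_PULSE_FWHM_S = 0.08
DECEL_LEAD_S = 1.0          # HR deceleration starts this long before SCR onset
SHIFT_RELEASE_S = 10.0      # HR level shift ramps back over this many seconds
SKT_RETURN_TAU_S = 90.0     # thermoregulatory return toward the set point
#: band of the slow baseline wander; periods of 50-120 s, short enough that
#: a 3-min relax window samples the full wander distribution
DRIFT_BAND_HZ = (1.0 / 120.0, 1.0 / 50.0)


@dataclass(frozen=True)
class EpisodeScript:
    """One scripted emotional episode and its autonomic fingerprint."""

    t_s: float                       # SCR onset time (the OR moment)
    emotion: str
    scr_amplitude: float = 150.0     # ADC counts at the SCR peak
    hr_decel_bpm: float = 8.0        # depth of the orienting deceleration
    decel_duration_s: float = 4.0    # down-ramp length (recovery mirrors it)
    hr_shift_bpm: float = 5.0        # sustained post-episode HR change
    skt_slope_degc_per_min: float = 0.0
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.scr_amplitude < 0 or self.decel_duration_s < 0 or self.duration_s < 0:
            raise ValueError("amplitudes and durations must be non-negative")

    @property
    def span_s(self) -> tuple[float, float]:
        return (self.t_s - DECEL_LEAD_S, self.t_s + self.duration_s)


@dataclass(frozen=True)
class GeneratorConfig:
    sample_rate_hz: float = 100.0
    session_length_s: float = 600.0
    baseline_hr_bpm: float = 70.0
    baseline_eda: float = 2000.0     # ADC counts
    baseline_skt_degc: float = 33.5
    ppg_baseline: float = 2048.0
    ppg_pulse_amplitude: float = 1000.0
    ppg_noise: float = 20.0          # per-channel additive Gaussian sigma
    eda_noise: float = 2.0
    skt_noise: float = 0.02
    #: slow baseline wander (std); a few times smaller than the scripted
    #: effect sizes, the regime in which level comparison is meaningful
    hr_drift_bpm: float = 0.5
    eda_drift: float = 5.0
    skt_drift_degc: float = 0.02
    seed: int = 0


def _hr_profile(t: np.ndarray, cfg: GeneratorConfig,
                scripts: list[EpisodeScript]) -> np.ndarray:
    """Instantaneous HR: baseline plus piecewise-linear episode responses
    (deceleration ramp, recovery overshooting into the level shift, hold,
    release)."""
    hr = np.full_like(t, cfg.baseline_hr_bpm)
    for e in scripts:
        t0 = e.t_s - DECEL_LEAD_S
        dd = max(e.decel_duration_s, 1e-6)
        xp = [t0, t0 + dd, t0 + 2 * dd,
              e.t_s + e.duration_s, e.t_s + e.duration_s + SHIFT_RELEASE_S]
        fp = [0.0, -e.hr_decel_bpm, e.hr_shift_bpm, e.hr_shift_bpm, 0.0]
        hr += np.interp(t, xp, fp, left=0.0, right=0.0)
    return hr


def _beats_from_hr(t: np.ndarray, hr_bpm: np.ndarray) -> np.ndarray:
    """Beat times from the cumulative phase of the instantaneous rate."""
    from scipy.integrate import cumulative_trapezoid

    phase = cumulative_trapezoid(hr_bpm / 60.0, t, initial=0.0)
    ks = np.arange(1, int(np.floor(phase[-1])) + 1)
    return np.interp(ks, phase, t)


def _slow_drift(rng: np.random.Generator, n: int, fs: float, std: float
                ) -> np.ndarray:
    """Band-limited baseline wander: low-passed white noise rescaled to the
    requested standard deviation."""
    if std <= 0 or n < 32:
        return np.zeros(n)
    from scipy.signal import butter, filtfilt

    lo, hi = (f / (fs / 2.0) for f in DRIFT_BAND_HZ)
    b, a = butter(2, (min(lo, 0.98), min(hi, 0.99)), btype="bandpass")
    raw = filtfilt(b, a, rng.normal(0.0, 1.0, n), padlen=min(n - 1, 2000))
    s = raw.std()
    return raw * (std / s) if s > 0 else raw


def _scr_shape(u: np.ndarray) -> np.ndarray:
    """Bi-exponential SCR, peak-normalized to 1 (u in seconds from onset)."""
    tr, td = SCR_TAU_RISE_S, SCR_TAU_DECAY_S
    raw = np.where(u >= 0, np.exp(-np.maximum(u, 0) / td)
                   - np.exp(-np.maximum(u, 0) / tr), 0.0)
    u_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-u_peak / td) - np.exp(-u_peak / tr)
    return raw / peak


def generate_session(
    cfg: GeneratorConfig,
    scripts: list[EpisodeScript] | None = None,
) -> tuple[SessionRecording, dict]:
    """Render a session recording plus ground truth.

    Ground truth holds the true beat times, SCR onset times, the noiseless
    instantaneous HR profile and the episode scripts themselves.  Episodes
    (including their 1-s deceleration lead) must not overlap.
    """
    scripts = sorted(scripts or [], key=lambda e: e.t_s)
    for a, b in zip(scripts, scripts[1:]):
        if a.span_s[1] > b.span_s[0]:
            raise ValueError(
                f"episodes at t={a.t_s} and t={b.t_s} overlap"
            )
    fs = cfg.sample_rate_hz
    n = int(round(cfg.session_length_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(cfg.seed)

    hr_true = _hr_profile(t, cfg, scripts)
    hr_true = hr_true + _slow_drift(rng, n, fs, cfg.hr_drift_bpm)
    beat_times = _beats_from_hr(t, hr_true)
    ppg = np.full(n, cfg.ppg_baseline)
    sigma = PPG_PULSE_FWHM_S / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4 * sigma * fs))
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        ppg[lo:hi] += cfg.ppg_pulse_amplitude * np.exp(
            -0.5 * ((t[lo:hi] - tb) / sigma) ** 2
        )

    eda = np.full(n, cfg.baseline_eda) + _slow_drift(rng, n, fs, cfg.eda_drift)
    for e in scripts:
        i0 = int(round(e.t_s * fs))
        if i0 >= n:
            continue
        eda[i0:] += e.scr_amplitude * _scr_shape(t[i0:] - e.t_s)

    skt = (np.full(n, cfg.baseline_skt_degc)
           + _slow_drift(rng, n, fs, cfg.skt_drift_degc))
    for e in scripts:
        rate = e.skt_slope_degc_per_min / 60.0
        ramp = np.clip(t - e.t_s, 0.0, e.duration_s) * rate
        t_end = e.t_s + e.duration_s
        decay = np.where(t > t_end,
                         np.exp(-np.maximum(t - t_end, 0.0) / SKT_RETURN_TAU_S),
                         1.0)
        skt += ramp * decay

    ppg = ppg + rng.normal(0.0, cfg.ppg_noise, n) if cfg.ppg_noise else ppg
    eda = eda + rng.normal(0.0, cfg.eda_noise, n) if cfg.eda_noise else eda
    skt = skt + rng.normal(0.0, cfg.skt_noise, n) if cfg.skt_noise else skt

    session = SessionRecording(
        sample_rate_hz=fs,
        channels={"ppg": ppg, "eda": eda, "skt": skt},
    )
    truth = {
        "beat_times_s": beat_times,
        "scr_onsets_s": np.array([e.t_s for e in scripts]),
        "episodes": scripts,
        "hr_inst_bpm": hr_true,
    }
    return session, truth


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

RELAX_S = 180.0   # three-minute relax period before the stimuli

#: stand-in picture identifiers for the still-picture protocol; the pleasant
#: half elicits joy, the unpleasant half disgust
IAPS_PLEASANT = ["p01", "p02", "p03", "p04", "p05",
                 "p06", "p07", "p08", "p09", "p10"]
IAPS_UNPLEASANT = ["u01", "u02", "u03", "u04", "u05",
                   "u06", "u07", "u08", "u09", "u10"]
SCR_LATENCY_S = 1.5   # stimulus onset to EDA onset

JOY_EPISODE = dict(hr_decel_bpm=8.0, decel_duration_s=4.0, hr_shift_bpm=5.0,
                   skt_slope_degc_per_min=0.2)
DISGUST_EPISODE = dict(hr_decel_bpm=8.0, decel_duration_s=4.0, hr_shift_bpm=5.0,
                       skt_slope_degc_per_min=-0.3)


def scripted_protocol(
    preset: str, seed: int = 0
) -> tuple[GeneratorConfig, list[EpisodeScript], StimulusTimeline]:
    """Ready-made sessions mirroring the two study protocols at desk scale.

    ``iaps_520``: 3-min relax, then 20 still pictures (10 pleasant, 10
    unpleasant) shown 6 s each with 20-s blanks — a 520-s stimulus block.
    The unpleasant pictures script disgust episodes; the first pleasant
    picture scripts a joy episode.

    ``film_joy_14``: 3-min relax within a 1800-s session containing 14
    scripted joy scenes.
    """
    if preset == "iaps_520":
        timeline = build_iaps_timeline(
            20, 6.0, 20.0,
            labels=IAPS_PLEASANT + IAPS_UNPLEASANT,
            target_emotions=["joy"] * 10 + ["disgust"] * 10,
            start_s=RELAX_S,
        )
        stimuli = timeline.stimuli()
        scripts = [
            EpisodeScript(stimuli[0].start_s + SCR_LATENCY_S, "joy",
                          duration_s=20.0, **JOY_EPISODE)
        ]
        scripts += [
            EpisodeScript(s.start_s + SCR_LATENCY_S, "disgust",
                          duration_s=20.0, **DISGUST_EPISODE)
            for s in stimuli[10:]
        ]
        cfg = GeneratorConfig(session_length_s=RELAX_S + 520.0 + 60.0, seed=seed)
        return cfg, scripts, timeline
    if preset == "film_joy_14":
        length = 1800.0
        scene_starts = np.linspace(RELAX_S + 20.0, length - 140.0, 14)
        events = []
        scripts = []
        for k, start in enumerate(scene_starts):
            from .signal_io import StimulusEvent

            events.append(StimulusEvent(float(start), 10.0, f"scene{k+1:02d}",
                                        "joy"))
            gap_end = float(scene_starts[k + 1]) if k + 1 < 14 else length
            events.append(StimulusEvent(float(start) + 10.0,
                                        gap_end - float(start) - 10.0,
                                        "blank", "blank"))
            scripts.append(
                EpisodeScript(float(start) + SCR_LATENCY_S, "joy",
                              duration_s=60.0, **JOY_EPISODE)
            )
        cfg = GeneratorConfig(session_length_s=length, seed=seed)
        return cfg, scripts, StimulusTimeline(events)
    raise ValueError(f"unknown preset {preset!r}")
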