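"""Orienting-response (OR) detection.

An orienting response — the attention reflex to a novel stimulus — is indexed
by a rapid electrodermal onset accompanied by cardiac deceleration.  The
validation rule checks the heart-rate slope over a 2-s window starting 1 s
before the EDA change: a sufficiently negative slope marks a valid OR
(successful emotion elicitation); a positive slope of the same magnitude
marks a defensive response (aversive/phobic acceleration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import FeatureSeries

#: fraction of a run's peak derivative that marks the onset instant; chosen
#: to cancel the backward smear of the zero-phase low-pass on an SCR rise
ONSET_PEAK_FRACTION = 0.6


@dataclass(frozen=True)
class ORParams:
    pre_s: float = 1.0            # slope window starts this long before onset
    span_s: float = 2.0           # slope window length
    min_decel_bpm_per_s: float = 0.5
    deriv_k: float = 4.0          # onset threshold in baseline derivative stds
    min_run_s: float = 0.5        # derivative must stay supra-threshold this long
    refractory_s: float = 5.0     # minimum spacing between onsets
    baseline_interval_s: tuple[float, float] = (0.0, 180.0)
    rise_span_s: float = 5.0      # where to measure the onset amplitude


@dataclass
class OREvent:
    """One detected orienting response candidate.

    ``valid`` and ``defensive`` are mutually exclusive: valid requires HR
    deceleration at the EDA onset, defensive requires acceleration.  ``covered``
    is False when HR was not defined across the whole check window.
    """

    t_eda_onset_s: float
    hr_slope_bpm_per_s: float
    eda_rise: float = float("nan")
    valid: bool = False
    defensive: bool = False
    covered: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.defensive:
            raise ValueError("valid and defensive are mutually exclusive")


def detect_eda_onsets(
    eda_filtered: np.ndarray,
    sample_rate_hz: float,
    params: ORParams = ORParams(),
) -> np.ndarray:
    """Onset times where the filtered-EDA derivative exceeds a
    baseline-calibrated threshold for a sustained run.

    The threshold is ``deriv_k`` times the derivative's standard deviation
    over the baseline (relax) interval — unit-free, so raw ADC counts work.
    Runs must last ``min_run_s``; accepted onsets are separated by the
    refractory interval.  Returns an empty array when nothing fires.

    Because the zero-phase low-pass smears a response's rising edge
    backwards in time, the raw threshold crossing precedes the true onset;
    the reported onset is therefore the first sample of the run whose
    derivative reaches ``ONSET_PEAK_FRACTION`` of the run's peak derivative,
    which sits on the steep part of the rise and tracks the true onset
    closely.
    """
    eda = np.asarray(eda_filtered, dtype=float)
    deriv = np.gradient(eda) * sample_rate_hz
    b0, b1 = params.baseline_interval_s
    i0 = max(int(b0 * sample_rate_hz), 0)
    i1 = min(int(b1 * sample_rate_hz), len(eda))
    base = deriv[i0:i1] if i1 > i0 else deriv
    sigma = float(np.std(base))
    theta = params.deriv_k * sigma
    above = deriv > theta
    min_run = max(int(round(params.min_run_s * sample_rate_hz)), 1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    onsets: list[float] = []
    last = -np.inf
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_run:
            continue
        # runs touching the array edges are zero-phase-filter transients
        if start == 0 or stop == len(eda):
            continue
        run = deriv[start:stop]
        onset_idx = start + int(np.argmax(run >= ONSET_PEAK_FRACTION * run.max()))
        t = onset_idx / sample_rate_hz
        if t - last < params.refractory_s:
            continue
        onsets.append(t)
        last = t
    return np.asarray(onsets)


def check_or(
    onset_s: float,
    hr: FeatureSeries,
    pre_s: float = 1.0,
    span_s: float = 2.0,
    min_decel: float = 0.5,
) -> OREvent:
    """Score one EDA onset against the cardiac-deceleration criterion.

    Least-squares HR slope over ``[onset - pre_s, onset - pre_s + span_s]``;
    valid iff slope <= -min_decel, defensive iff slope >= +min_decel.  If HR
    is undefined anywhere on the window, the event is returned unvalidated
    with ``covered=False``.
    """
    t_start = onset_s - pre_s
    vals = hr.slice_time(t_start, t_start + span_s)
    t = np.arange(len(vals)) / hr.sample_rate_hz
    expected = int(round(span_s * hr.sample_rate_hz))
    if len(vals) < max(expected, 2) or np.isnan(vals).any():
        return OREvent(onset_s, float("nan"), covered=False)
    slope = float(np.polyfit(t, vals, 1)[0])
    return OREvent(
        onset_s,
        slope,
        valid=slope <= -min_decel,
        defensive=slope >= min_decel,
    )


def validate_elicitation(
    hr: FeatureSeries,
    eda_filtered: np.ndarray,
    sample_rate_hz: float,
    params: ORParams = ORParams(),
) -> list[OREvent]:
    """Detect all EDA onsets and score each against the OR criterion.

    ``eda_rise`` is the filtered-EDA excursion from onset to its maximum over
    the following ``rise_span_s`` seconds.
    """
    eda = np.asarray(eda_filtered, dtype=float)
    events: list[OREvent] = []
    for onset in detect_eda_onsets(eda, sample_rate_hz, params):
        ev = check_or(onset, hr, params.pre_s, params.span_s,
                      params.min_decel_bpm_per_s)
        i0 = int(round(onset * sample_rate_hz))
        i1 = min(int(round((onset + params.rise_span_s) * sample_rate_hz)),
                 len(eda))
        if i1 > i0:
            ev.eda_rise = float(np.max(eda[i0:i1]) - eda[i0])
        events.append(ev)
    events.sort(key=lambda e: e.t_eda_onset_s)
    return events


def events_to_frame(events: list[OREvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t_onset_s": e.t_eda_onset_s,
                "hr_slope": e.hr_slope_bpm_per_s,
                "eda_rise": e.eda_rise,
                "valid": e.valid,
                "defensive": e.defensive,
                "covered": e.covered,
            }
            for e in events
        ],
        columns=["t_onset_s", "hr_slope", "eda_rise", "valid", "defensive",
                 "covered"],
    )
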