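"""Tonic-channel (EDA, SKT) filtering and rolling statistics.

Both slow channels are low-passed with a zero-phase 2nd-order Butterworth
filter at a normalized cutoff of 0.005 (fraction of Nyquist; 0.25 Hz at
100 Hz sampling) before rolling mean/std extraction.  The forward-backward
pass doubles the effective order and cancels phase shift, so filtered
transients stay time-locked to their causes — essential for onset timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .windows import FeatureSeries, rolling_mean, rolling_std


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass specification; ``normalized_cutoff`` is a fraction of the
    Nyquist frequency, so the absolute cutoff scales with the sample rate."""

    order: int = 2
    normalized_cutoff: float = 0.005
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.normalized_cutoff < 1:
            raise ValueError("normalized_cutoff must be in (0, 1)")


def lowpass_zero_phase(signal: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth low-pass applied forward and backward (zero net phase).

    Edge transients are suppressed by odd-extension padding scaled to the
    filter's settling time (about ``10 / normalized_cutoff`` samples, capped
    by the signal length): at very low cutoffs the scipy default of
    ``3 * max(len(b), len(a))`` samples is far shorter than the impulse
    response and leaves visible boundary transients.
    """
    signal = np.asarray(signal, dtype=float)
    b, a = butter(spec.order, spec.normalized_cutoff, output="ba")
    min_len = 3 * max(len(a), len(b))
    if len(signal) <= min_len:
        raise ValueError(
            f"signal of {len(signal)} samples too short for order-{spec.order} "
            f"zero-phase filtering (needs > {min_len})"
        )
    padlen = min(len(signal) - 1, int(np.ceil(10.0 / spec.normalized_cutoff)))
    return filtfilt(b, a, signal, padlen=padlen)


def rolling_mean_std(
    signal: np.ndarray,
    window_s: float,
    sample_rate_hz: float,
    name: str = "tonic",
) -> tuple[FeatureSeries, FeatureSeries]:
    """Centered rolling mean and std with edge truncation."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    signal = np.asarray(signal, dtype=float)
    m = rolling_mean(signal, window_s, sample_rate_hz)
    s = rolling_std(signal, window_s, sample_rate_hz)
    return (
        FeatureSeries(f"{name}mean", m, window_s, sample_rate_hz),
        FeatureSeries(f"{name}std", s, window_s, sample_rate_hz),
    )
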