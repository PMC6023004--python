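"""PPG-derived heart-rate-variability features.

The chain is: peak detection on the raw photoplethysmogram -> beat times ->
interbeat intervals (IBI, ms) -> cubic interpolation onto the uniform sample
grid -> rolling time-domain statistics (HR, SDNN, SDSD, RMSSD, SDNN/RMSSD)
and windowed spectral band features (LF, HF, LF/HF).

Conventions
-----------
* An IBI value is attributed to the *later* beat of its pair; the grid series
  is a cubic spline through those knots, held constant between the first beat
  and the first knot, NaN outside beat coverage.
* Time-domain features use a short centered window (default 10 s); spectral
  features need at least one LF cycle (1/0.04 Hz = 25 s) and default to 60 s.
* The spectral "power" is, deliberately, the trapezoidal integral of the
  MAGNITUDE spectrum of the windowed IBI series over each band — this is the
  literal published computation; set ``power=True`` for magnitude-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .windows import FeatureSeries, rolling_mean, rolling_std, window_samples

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
#: one cycle of the lowest LF frequency; shorter spectral windows are flagged
MIN_SPECTRAL_WINDOW_S = 1.0 / LF_BAND[0]

DEFAULT_TIME_WINDOW_S = 10.0
DEFAULT_FREQ_WINDOW_S = 60.0
DEFAULT_REFRACTORY_S = 0.33   # caps detectable HR at ~180 bpm


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------


def detect_peaks(
    ppg: np.ndarray,
    sample_rate_hz: float,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    threshold_percentile: float = 75.0,
    threshold_window_s: float = 2.0,
    smooth_s: float = 0.03,
) -> np.ndarray:
    """Detect systolic peaks in a raw PPG trace; returns beat times in s.

    The signal is lightly Gaussian-smoothed (matched roughly to pulse width),
    then local maxima are kept if they exceed an adaptive threshold derived
    from a moving percentile over ``threshold_window_s``, with a refractory
    period between accepted beats.  On a signal with no pulses the result is
    empty (with a warning), never an exception.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 2 * sample_rate_hz:
        raise InsufficientDataError("need at least 2 s of PPG signal")
    x = gaussian_filter1d(ppg, sigma=max(smooth_s * sample_rate_hz, 1.0))
    w = window_samples(threshold_window_s, sample_rate_hz)
    import pandas as pd

    base = (
        pd.Series(x)
        .rolling(w, min_periods=1, center=True)
        .quantile(threshold_percentile / 100.0)
        .to_numpy()
    )
    # lift the floor above in-window noise: percentile alone admits noise
    # maxima between beats, so require a fraction of the local peak-to-floor
    # span as prominence-like margin
    span = (
        pd.Series(x).rolling(w, min_periods=1, center=True).max().to_numpy() - base
    )
    height = base + 0.25 * span
    distance = max(int(round(refractory_s * sample_rate_hz)), 1)
    idx, _ = find_peaks(x, height=height, distance=distance)
    if len(idx) == 0:
        warnings.warn("no PPG peaks found", stacklevel=2)
        return np.empty(0)
    return idx / sample_rate_hz


# ---------------------------------------------------------------------------
# interbeat intervals
# ---------------------------------------------------------------------------


@dataclass
class IBISeries:
    """Beat times, interbeat intervals, and the uniform-grid interpolation."""

    beat_times_s: np.ndarray      # strictly increasing
    ibi_ms: np.ndarray            # len == n_beats - 1
    ibi_grid: np.ndarray          # ms on the sample grid; NaN outside coverage
    sample_rate_hz: float

    @property
    def n_samples(self) -> int:
        return len(self.ibi_grid)


def _grid_interpolate(
    knot_times: np.ndarray,
    knot_values: np.ndarray,
    sample_rate_hz: float,
    n_samples: int,
    t_first_beat: float,
) -> np.ndarray:
    """Cubic spline through (knot_times, knot_values) evaluated on the sample
    grid; constant extension back to the first beat; NaN outside coverage.
    Falls back to linear interpolation when there are too few knots."""
    t = np.arange(n_samples) / sample_rate_hz
    out = np.full(n_samples, np.nan)
    if len(knot_times) >= 4:
        spline = CubicSpline(knot_times, knot_values, extrapolate=False)
        vals = spline(t)
    else:
        vals = np.interp(t, knot_times, knot_values,
                         left=np.nan, right=np.nan)
    inside = (t >= knot_times[0]) & (t <= knot_times[-1])
    out[inside] = vals[inside]
    lead = (t >= t_first_beat) & (t < knot_times[0])
    out[lead] = knot_values[0]
    return out


def ibi_series(
    beat_times_s: np.ndarray,
    sample_rate_hz: float,
    n_samples: int | None = None,
) -> IBISeries:
    """Interbeat intervals in ms, cubically interpolated onto the sample grid.

    Needs at least 3 beats.  ``n_samples`` fixes the grid length (defaults to
    just covering the last beat) so feature series align with the session.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if len(beat_times_s) < 3:
        raise InsufficientDataError("need at least 3 beats for an IBI series")
    if np.any(np.diff(beat_times_s) <= 0):
        raise ValueError("beat times must be strictly increasing")
    ibi_ms = np.diff(beat_times_s) * 1000.0
    if n_samples is None:
        n_samples = int(np.floor(beat_times_s[-1] * sample_rate_hz)) + 1
    grid = _grid_interpolate(
        beat_times_s[1:], ibi_ms, sample_rate_hz, n_samples, beat_times_s[0]
    )
    return IBISeries(beat_times_s, ibi_ms, grid, sample_rate_hz)


# ---------------------------------------------------------------------------
# time-domain features
# ---------------------------------------------------------------------------


def hr(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Heart rate in bpm: 60 s x sampling frequency / peak-to-peak duration,
    i.e. 60000 / IBI(ms), smoothed by a centered rolling mean."""
    inst = 60000.0 / ibi.ibi_grid
    vals = rolling_mean(inst, window_s, ibi.sample_rate_hz)
    return FeatureSeries("HR", vals, window_s, ibi.sample_rate_hz)


def hr_from_peak_to_peak(duration_samples: float, sample_rate_hz: float) -> float:
    """The headline HR formula: (60 s x sampling frequency) / peak-to-peak
    duration in samples."""
    return 60.0 * sample_rate_hz / duration_samples


def mean_ibi(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Centered rolling mean of the gridded IBI (ms)."""
    vals = rolling_mean(ibi.ibi_grid, window_s, ibi.sample_rate_hz)
    return FeatureSeries("meanIBI", vals, window_s, ibi.sample_rate_hz)


def sdnn(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Rolling standard deviation of the gridded IBI (ms)."""
    vals = rolling_std(ibi.ibi_grid, window_s, ibi.sample_rate_hz)
    return FeatureSeries("SDNN", vals, window_s, ibi.sample_rate_hz)


def _diff_grid(ibi: IBISeries, transform) -> np.ndarray:
    """Successive beat-to-beat IBI differences, transformed then interpolated
    to the grid.  Differencing happens beat-wise BEFORE interpolation."""
    if len(ibi.ibi_ms) < 2:
        raise InsufficientDataError("need at least 4 beats for IBI differences")
    d = transform(np.diff(ibi.ibi_ms))
    knots = ibi.beat_times_s[2:]
    return _grid_interpolate(
        knots, d, ibi.sample_rate_hz, ibi.n_samples, ibi.beat_times_s[0]
    )


def sdsd(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Rolling std of |successive IBI differences| (ms)."""
    g = _diff_grid(ibi, np.abs)
    vals = rolling_std(g, window_s, ibi.sample_rate_hz)
    return FeatureSeries("SDSD", vals, window_s, ibi.sample_rate_hz)


def rmssd(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Rolling root-mean-square of successive IBI differences (ms): squared
    differences are interpolated to the grid, rolling-averaged, then rooted."""
    g = _diff_grid(ibi, np.square)
    # cubic interpolation can overshoot below zero between knots
    g = np.clip(g, 0.0, None)
    vals = np.sqrt(rolling_mean(g, window_s, ibi.sample_rate_hz))
    return FeatureSeries("RMSSD", vals, window_s, ibi.sample_rate_hz)


def sdnn_rmssd(ibi: IBISeries, window_s: float = DEFAULT_TIME_WINDOW_S) -> FeatureSeries:
    """Elementwise SDNN/RMSSD; windows with zero RMSSD are missing (NaN),
    never infinite."""
    num = sdnn(ibi, window_s).values
    den = rmssd(ibi, window_s).values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return FeatureSeries("SDNN_RMSSD", ratio, window_s, ibi.sample_rate_hz)


# ---------------------------------------------------------------------------
# frequency-domain features
# ---------------------------------------------------------------------------


def spectral_band_features(
    ibi: IBISeries,
    window_s: float = DEFAULT_FREQ_WINDOW_S,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    hop_s: float = 1.0,
    power: bool = False,
) -> tuple[FeatureSeries, FeatureSeries, FeatureSeries]:
    """LF / HF band integrals and their ratio from windowed FFTs of the
    gridded IBI series.

    Per centered window: DFT scaled by the window length, positive-half
    magnitude spectrum, trapezoidal integral over each band.  Values are
    computed on a ``hop_s`` stride and linearly interpolated to the sample
    grid; only full interior windows are defined (NaN at the edges).
    """
    fs = ibi.sample_rate_hz
    w = window_samples(window_s, fs)
    if w < 2:
        raise ValueError("spectral window must span at least 2 samples")
    if window_s < MIN_SPECTRAL_WINDOW_S:
        warnings.warn(
            f"window {window_s} s is shorter than one LF cycle "
            f"({MIN_SPECTRAL_WINDOW_S:.0f} s); LF estimates are unreliable",
            stacklevel=2,
        )
    n = ibi.n_samples
    half = w // 2
    freqs = np.arange(half) * fs / w
    lf_mask = (freqs >= lf_band[0]) & (freqs <= lf_band[1])
    hf_mask = (freqs >= hf_band[0]) & (freqs <= hf_band[1])

    lo0 = w // 2                       # first center with a full window
    hi0 = n - 1 - (w - 1 - w // 2)     # last center with a full window
    hop = max(int(round(hop_s * fs)), 1)
    lf_g = np.full(n, np.nan)
    hf_g = np.full(n, np.nan)
    if hi0 >= lo0:
        centers = np.arange(lo0, hi0 + 1, hop)
        if centers[-1] != hi0:
            centers = np.append(centers, hi0)
        lf_c = np.full(len(centers), np.nan)
        hf_c = np.full(len(centers), np.nan)
        for j, c in enumerate(centers):
            seg = ibi.ibi_grid[c - w // 2: c - w // 2 + w]
            if np.isnan(seg).any():
                continue
            spec = np.abs(np.fft.fft(seg) / w)[:half]
            if power:
                spec = spec**2
            lf_c[j] = np.trapezoid(spec[lf_mask], freqs[lf_mask])
            hf_c[j] = np.trapezoid(spec[hf_mask], freqs[hf_mask])
        grid_idx = np.arange(lo0, hi0 + 1)
        ok = ~np.isnan(lf_c)
        if ok.any():
            lf_g[lo0:hi0 + 1] = np.interp(grid_idx, centers[ok], lf_c[ok])
            hf_g[lo0:hi0 + 1] = np.interp(grid_idx, centers[ok], hf_c[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        lhf = np.where(hf_g > 0, lf_g / hf_g, np.nan)
    return (
        FeatureSeries("LF", lf_g, window_s, fs),
        FeatureSeries("HF", hf_g, window_s, fs),
        FeatureSeries("LHF", lhf, window_s, fs),
    )
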