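"""Centered rolling-window primitives shared by all feature extractors.

Semantics follow the feature table's printed contract
``rolling(window, min_periods=1, center=True)``: the window is centered on
each sample and truncated at the recording edges, NaNs inside a window are
skipped, and a value is produced at every sample.  For a window of ``w``
samples centered on index ``i`` the covered index range is
``[i - w//2, i + (w-1)//2]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureSeries:
    """A per-sample feature track aligned to the session sample grid."""

    name: str
    values: np.ndarray
    window_s: float
    sample_rate_hz: float
    t0: float = 0.0
    centered: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sample_rate_hz

    def slice_time(self, t_start: float, t_end: float) -> np.ndarray:
        """Values for samples with t_start <= t < t_end (grid time)."""
        i0 = int(np.ceil((t_start - self.t0) * self.sample_rate_hz - 1e-9))
        i1 = int(np.ceil((t_end - self.t0) * self.sample_rate_hz - 1e-9))
        i0 = max(i0, 0)
        return self.values[i0:i1]


def window_samples(window_s: float, sample_rate_hz: float) -> int:
    w = int(round(window_s * sample_rate_hz))
    return max(w, 1)


def rolling_mean(x: np.ndarray, window_s: float, sample_rate_hz: float) -> np.ndarray:
    w = window_samples(window_s, sample_rate_hz)
    return pd.Series(x).rolling(w, min_periods=1, center=True).mean().to_numpy()


def rolling_std(x: np.ndarray, window_s: float, sample_rate_hz: float) -> np.ndarray:
    """Sample standard deviation (ddof=1); single-sample windows give NaN."""
    w = window_samples(window_s, sample_rate_hz)
    return pd.Series(x).rolling(w, min_periods=1, center=True).std().to_numpy()
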