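"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

FS = 100.0


def brute_rolling(x: np.ndarray, w: int, stat: str) -> np.ndarray:
    """Independent per-window recomputation of a centered rolling statistic
    with edge truncation and NaN skipping: window [i - w//2, i + (w-1)//2]."""
    n = len(x)
    out = np.full(n, np.nan)
    for i in range(n):
        seg = x[max(i - w // 2, 0): i + (w - 1) // 2 + 1]
        seg = seg[~np.isnan(seg)]
        if len(seg) == 0:
            continue
        if stat == "mean":
            out[i] = np.mean(seg)
        elif stat == "std":
            out[i] = np.std(seg, ddof=1) if len(seg) > 1 else np.nan
        else:
            raise ValueError(stat)
    return out


def gaussian_pulse_train(beat_times_s, fs=FS, duration_s=None, amplitude=1.0,
                         fwhm_s=0.08):
    """Clean PPG surrogate: one Gaussian pulse per beat."""
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if duration_s is None:
        duration_s = beat_times_s[-1] + 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sigma = fwhm_s / (2 * np.sqrt(2 * np.log(2)))
    x = np.zeros(n)
    for tb in beat_times_s:
        x += amplitude * np.exp(-0.5 * ((t - tb) / sigma) ** 2)
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return FS
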