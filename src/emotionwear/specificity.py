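"""ANS-specificity emotion classification.

After a validated orienting response, the 60-s mean levels of HR, EDA and
SKT are compared against a relax-period baseline; each channel's direction
(up / flat / down, with a deadband in baseline standard deviations) is
matched against per-emotion sign patterns drawn from autonomic-specificity
research: joy raises all three channels; disgust (and fear, which shares the
signature) raise HR and EDA while fingertip temperature falls.  Ties are
reported as sets, never silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
from scipy.stats import binomtest

from .orienting import OREvent
from .windows import FeatureSeries

CHANNELS = ("hr", "eda", "skt")
DEFAULT_DEADBAND_K = 0.5
DEFAULT_INTERVAL_S = 60.0
DEFAULT_MIN_SCORE = 0.5


class PatternConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ANSPattern:
    """Per-emotion channel-direction signature; directions in {-1, 0, +1},
    0 meaning the channel is not scored for this emotion."""

    emotion: str
    hr: int
    eda: int
    skt: int

    def __post_init__(self) -> None:
        for d in (self.hr, self.eda, self.skt):
            if d not in (-1, 0, 1):
                raise ValueError("directions must be -1, 0 or +1")
        if self.hr == self.eda == self.skt == 0:
            raise ValueError("pattern needs at least one nonzero direction")

    def direction(self, channel: str) -> int:
        return getattr(self, channel)


def default_patterns() -> list[ANSPattern]:
    """Signatures quotable from autonomic-specificity findings: joy and
    disgust are anchored; fear shares the disgust signature (the two are
    known to be hard to distinguish from these three channels).  Anger and
    sadness ship unset and must be user-configured."""
    return [
        ANSPattern("joy", +1, +1, +1),
        ANSPattern("disgust", +1, +1, -1),
        ANSPattern("fear", +1, +1, -1),
    ]


@dataclass
class BaselineProfile:
    """Per-channel mean and std over the relax period (default first 180 s)."""

    interval_s: tuple[float, float]
    mean: dict[str, float]
    std: dict[str, float]


@dataclass
class EmotionCall:
    """Classification of one post-OR window: observed directions, best-match
    emotions (a set — ties are explicit) and the match score."""

    t0: float
    t1: float
    directions: dict[str, int]
    emotions: frozenset[str]
    score: float
    truncated: bool = False


def baseline_profile(
    features: dict[str, FeatureSeries],
    relax_interval_s: tuple[float, float] = (0.0, 180.0),
) -> BaselineProfile:
    """Channel means/stds over the declared relax interval."""
    t0, t1 = relax_interval_s
    mean, std = {}, {}
    for ch in CHANNELS:
        fs = features[ch]
        if t0 < fs.t0 - 1e-9 or t1 > fs.t0 + len(fs) / fs.sample_rate_hz + 1e-9:
            raise ValueError(
                f"relax interval [{t0}, {t1}] outside recording for {ch!r}"
            )
        vals = fs.slice_time(t0, t1)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"no defined {ch!r} samples in the relax interval")
        mean[ch] = float(np.mean(vals))
        std[ch] = float(np.std(vals))
    return BaselineProfile(relax_interval_s, mean, std)


def window_directions(
    features: dict[str, FeatureSeries],
    window_s: tuple[float, float],
    baseline: BaselineProfile,
    deadband_k: float = DEFAULT_DEADBAND_K,
) -> dict[str, int]:
    """Per-channel direction of the window mean relative to baseline.

    +1 above ``mean + deadband``, -1 below ``mean - deadband``, else 0, with
    ``deadband = deadband_k * baseline std``; deadband_k=0 reduces to the
    pure sign of the mean difference.
    """
    t0, t1 = window_s
    dirs: dict[str, int] = {}
    for ch in CHANNELS:
        vals = features[ch].slice_time(t0, t1)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            dirs[ch] = 0
            continue
        delta = float(np.mean(vals)) - baseline.mean[ch]
        deadband = deadband_k * baseline.std[ch]
        dirs[ch] = int(delta > deadband) - int(delta < -deadband)
    return dirs


def classify(
    dirs: dict[str, int],
    patterns: list[ANSPattern] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[frozenset[str], float]:
    """Best-matching emotion(s) for an observed direction triple.

    Score = matched channels / scored channels, scoring only channels whose
    pattern direction is nonzero; an observed 0 never matches a nonzero
    target.  All patterns achieving the top score above ``min_score`` are
    returned; the result is order-independent in the pattern table.
    """
    if patterns is None:
        patterns = default_patterns()
    if not patterns:
        raise PatternConfigError("pattern table is empty")
    scores: dict[str, float] = {}
    for p in patterns:
        scored = [ch for ch in CHANNELS if p.direction(ch) != 0]
        matched = sum(dirs.get(ch, 0) == p.direction(ch) for ch in scored)
        scores[p.emotion] = matched / len(scored)
    best = max(scores.values())
    if best < min_score or best == 0.0:
        return frozenset(), best
    return frozenset(e for e, s in scores.items() if s == best), best


def recognize(
    features: dict[str, FeatureSeries],
    or_events: list[OREvent],
    baseline: BaselineProfile,
    patterns: list[ANSPattern] | None = None,
    interval_s: float = DEFAULT_INTERVAL_S,
    deadband_k: float = DEFAULT_DEADBAND_K,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[EmotionCall]:
    """One emotion call per *valid* orienting response, over the
    ``interval_s`` window following the OR moment; windows truncated by the
    session end are flagged."""
    duration = min(
        f.t0 + len(f) / f.sample_rate_hz for f in features.values()
    )
    calls: list[EmotionCall] = []
    for ev in or_events:
        if not ev.valid:
            continue
        t0 = ev.t_eda_onset_s
        t1 = t0 + interval_s
        truncated = t1 > duration + 1e-9
        dirs = window_directions(features, (t0, min(t1, duration)), baseline,
                                 deadband_k)
        emotions, score = classify(dirs, patterns, min_score)
        calls.append(EmotionCall(t0, t1, dirs, emotions, score, truncated))
    return calls


def segment_directions(
    features: dict[str, FeatureSeries],
    baseline: BaselineProfile,
    interval_s: float = DEFAULT_INTERVAL_S,
    span_s: tuple[float, float] | None = None,
    deadband_k: float = DEFAULT_DEADBAND_K,
) -> list[dict[str, int]]:
    """Directions for consecutive ``interval_s`` segments of the recording —
    the "before" mode of the match-rate study, which scores the whole film
    rather than post-OR windows only."""
    if span_s is None:
        f = next(iter(features.values()))
        span_s = (f.t0, f.t0 + len(f) / f.sample_rate_hz)
    t0, t_end = span_s
    out = []
    while t0 + interval_s <= t_end + 1e-9:
        out.append(window_directions(features, (t0, t0 + interval_s),
                                     baseline, deadband_k))
        t0 += interval_s
    return out


def match_rate_test(
    window_dirs: list[dict[str, int]],
    pattern: ANSPattern,
    chance_p: float = 0.5,
) -> dict[str, tuple[float, float]]:
    """Per-channel fraction of windows matching the target pattern and a
    one-sided exact binomial p-value against chance.

    Returns ``{channel: (match_fraction, p_value)}`` over the pattern's
    scored channels.  Feed post-OR windows for the "after" mode or
    :func:`segment_directions` output for the "before" mode.
    """
    if not window_dirs:
        raise ValueError("need at least one scored window")
    out: dict[str, tuple[float, float]] = {}
    n = len(window_dirs)
    for ch in CHANNELS:
        target = pattern.direction(ch)
        if target == 0:
            continue
        k = sum(d.get(ch, 0) == target for d in window_dirs)
        p = binomtest(k, n, chance_p, alternative="greater").pvalue
        out[ch] = (k / n, float(p))
    return out
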