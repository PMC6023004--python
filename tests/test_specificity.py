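"""Baseline profiling, direction coding, pattern matching and the
match-rate statistic."""

from math import comb

import numpy as np
import pytest

import emotionwear as ew
from emotionwear.specificity import PatternConfigError

from conftest import FS


def _feats(hr=70.0, eda=1000.0, skt=33.0, n=30000, hr_arr=None, eda_arr=None,
           skt_arr=None):
    def mk(name, const, arr):
        vals = arr if arr is not None else np.full(n, const, dtype=float)
        return ew.FeatureSeries(name, vals, 10.0, FS)

    return {
        "hr": mk("HR", hr, hr_arr),
        "eda": mk("EDAmean", eda, eda_arr),
        "skt": mk("SKTmean", skt, skt_arr),
    }


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------


def test_constant_baseline_profile():
    base = ew.baseline_profile(_feats(), (0.0, 180.0))
    assert base.mean == {"hr": 70.0, "eda": 1000.0, "skt": 33.0}
    assert all(s == 0.0 for s in base.std.values())


def test_baseline_uses_exactly_the_relax_interval(rng):
    """The 3-minute relax interval contributes exactly 180 s of samples."""
    n = int(520 * FS)
    hr_arr = np.concatenate([rng.normal(70, 2, int(180 * FS)),
                             np.full(n - int(180 * FS), 100.0)])
    feats = _feats(n=n, hr_arr=hr_arr)
    base = ew.baseline_profile(feats, (0.0, 180.0))
    seg = hr_arr[: int(180 * FS)]
    assert base.mean["hr"] == pytest.approx(seg.mean(), abs=1e-12)
    assert base.std["hr"] == pytest.approx(seg.std(), abs=1e-12)


def test_baseline_outside_recording_raises():
    with pytest.raises(ValueError):
        ew.baseline_profile(_feats(n=1000), (0.0, 180.0))


# ---------------------------------------------------------------------------
# direction coding
# ---------------------------------------------------------------------------


def test_window_at_baseline_is_flat():
    feats = _feats()
    base = ew.baseline_profile(feats, (0.0, 180.0))
    assert ew.window_directions(feats, (200.0, 260.0), base) == {
        "hr": 0, "eda": 0, "skt": 0}


def test_direction_sign_construction(rng):
    n = 30000
    cut = int(200 * FS)
    hr_arr = rng.normal(70, 1.0, n)
    eda_arr = rng.normal(1000, 5.0, n)
    skt_arr = rng.normal(33, 0.05, n)
    hr_arr[cut:] += 5.0          # well past any deadband
    eda_arr[cut:] += 3 * 5.0     # +3 baseline stds
    skt_arr[cut:] -= 2 * 0.05 * 2  # -2 baseline stds and margin
    feats = _feats(hr_arr=hr_arr, eda_arr=eda_arr, skt_arr=skt_arr)
    base = ew.baseline_profile(feats, (0.0, 180.0))
    dirs = ew.window_directions(feats, (210.0, 270.0), base, deadband_k=1.0)
    assert dirs == {"hr": 1, "eda": 1, "skt": -1}


def test_zero_deadband_reduces_to_sign():
    feats = _feats(hr_arr=np.concatenate([np.full(20000, 70.0),
                                          np.full(10000, 70.001)]))
    base = ew.baseline_profile(feats, (0.0, 180.0))
    dirs = ew.window_directions(feats, (210.0, 260.0), base, deadband_k=0.0)
    assert dirs["hr"] == 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_fear_disgust_tie_reported_as_set():
    """The (+1,+1,-1) signature is shared: fear and disgust tie at 1.0 and
    are both reported."""
    emotions, score = ew.classify({"hr": 1, "eda": 1, "skt": -1})
    assert emotions == frozenset({"fear", "disgust"})
    assert score == 1.0


def test_joy_signature_unique():
    emotions, score = ew.classify({"hr": 1, "eda": 1, "skt": 1})
    assert emotions == frozenset({"joy"})
    assert score == 1.0


def test_flat_directions_make_no_call():
    emotions, score = ew.classify({"hr": 0, "eda": 0, "skt": 0})
    assert emotions == frozenset()


def test_classify_permutation_invariant():
    pats = ew.default_patterns()
    dirs = {"hr": 1, "eda": 1, "skt": -1}
    assert ew.classify(dirs, pats) == ew.classify(dirs, pats[::-1])


def test_empty_pattern_table_rejected():
    with pytest.raises(PatternConfigError):
        ew.classify({"hr": 1, "eda": 1, "skt": 1}, [])


def test_pattern_validation():
    with pytest.raises(ValueError):
        ew.ANSPattern("anger", 0, 0, 0)
    with pytest.raises(ValueError):
        ew.ANSPattern("anger", 2, 0, 0)


# ---------------------------------------------------------------------------
# recognize on generated sessions
# ---------------------------------------------------------------------------


def _run_session(emotion, skt_slope, seed):
    cfg = ew.GeneratorConfig(session_length_s=420.0, seed=seed,
                             ppg_noise=0.0, eda_noise=0.0, skt_noise=0.0,
                             hr_drift_bpm=0.0, eda_drift=0.0,
                             skt_drift_degc=0.0)
    eps = [ew.EpisodeScript(200.0 + 90 * k, emotion, duration_s=60.0,
                            skt_slope_degc_per_min=skt_slope)
           for k in range(2)]
    session, truth = ew.generate_session(cfg, eps)
    beats = ew.detect_peaks(session.channels["ppg"], FS)
    ibi = ew.ibi_series(beats, FS, session.n_samples)
    hr10, hr2 = ew.hr(ibi, 10.0), ew.hr(ibi, 2.0)
    eda = ew.lowpass_zero_phase(session.channels["eda"])
    edam, _ = ew.rolling_mean_std(eda, 10.0, FS, name="EDA")
    skt = ew.lowpass_zero_phase(session.channels["skt"])
    sktm, _ = ew.rolling_mean_std(skt, 10.0, FS, name="SKT")
    feats = {"hr": hr10, "eda": edam, "skt": sktm}
    events = ew.validate_elicitation(hr2, eda, FS)
    base = ew.baseline_profile(feats, (0.0, 180.0))
    calls = ew.recognize(feats, events, base)
    return truth, calls


@pytest.mark.parametrize("emotion,slope", [("disgust", -0.3), ("joy", +0.2)])
def test_noiseless_scripted_sessions_recover_label(emotion, slope):
    """Every scripted noiseless episode yields a call containing the true
    emotion label."""
    truth, calls = _run_session(emotion, slope, seed=1)
    assert len(calls) == len(truth["scr_onsets_s"])
    for call in calls:
        assert emotion in call.emotions
        assert call.score == 1.0


def test_no_valid_or_no_calls():
    feats = _feats()
    base = ew.baseline_profile(feats, (0.0, 180.0))
    assert ew.recognize(feats, [], base) == []


def test_truncated_window_flagged():
    feats = _feats(n=int(250 * FS))
    base = ew.baseline_profile(feats, (0.0, 180.0))
    ev = ew.OREvent(220.0, -2.0, valid=True)
    calls = ew.recognize(feats, [ev], base)
    assert calls[0].truncated


# ---------------------------------------------------------------------------
# match-rate statistic
# ---------------------------------------------------------------------------


def _binom_tail(k, n, p):
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def test_perfect_match_rate_p_value():
    """10/10 matching windows against chance 0.5: p = 0.5^10."""
    dirs = [{"hr": 1, "eda": 1, "skt": 1}] * 10
    res = ew.match_rate_test(dirs, ew.ANSPattern("joy", 1, 1, 1))
    for frac, p in res.values():
        assert frac == 1.0
        assert p == pytest.approx(0.5**10, rel=1e-12)


def test_half_match_rate_not_significant():
    dirs = [{"hr": 1, "eda": 1, "skt": 1}] * 5 + \
           [{"hr": -1, "eda": -1, "skt": -1}] * 5
    res = ew.match_rate_test(dirs, ew.ANSPattern("joy", 1, 1, 1))
    for frac, p in res.values():
        assert frac == 0.5
        assert p > 0.05


@pytest.mark.parametrize("n", [1, 2, 5, 11, 20])
def test_match_rate_equals_closed_form_tail(n, rng):
    """The p-value equals the exact binomial tail on all small instances."""
    pattern = ew.ANSPattern("disgust", 1, 1, -1)
    dirs = [
        {"hr": int(rng.integers(-1, 2)), "eda": int(rng.integers(-1, 2)),
         "skt": int(rng.integers(-1, 2))}
        for _ in range(n)
    ]
    res = ew.match_rate_test(dirs, pattern, chance_p=0.5)
    for ch, (frac, p) in res.items():
        k = round(frac * n)
        assert p == pytest.approx(_binom_tail(k, n, 0.5), rel=1e-12)


def test_zero_windows_rejected():
    with pytest.raises(ValueError):
        ew.match_rate_test([], ew.ANSPattern("joy", 1, 1, 1))


def test_after_or_windows_beat_whole_film_segments():
    """Post-OR windows match the target pattern more significantly than
    blind 60-s segmentation of the whole recording, on every channel.

    Uses a sparse-elicitation session (4 transient joy episodes in 30 min):
    the contrast between OR-locked and blind averaging exists exactly when
    most of the runtime is emotionally neutral."""
    cfg = ew.GeneratorConfig(session_length_s=1800.0, seed=4)
    scripts = [
        ew.EpisodeScript(240.0 + 420.0 * k, "joy", duration_s=30.0,
                         skt_slope_degc_per_min=0.2)
        for k in range(4)
    ]
    session, _ = ew.generate_session(cfg, scripts)
    beats = ew.detect_peaks(session.channels["ppg"], FS)
    ibi = ew.ibi_series(beats, FS, session.n_samples)
    hr10, hr2 = ew.hr(ibi, 10.0), ew.hr(ibi, 2.0)
    eda = ew.lowpass_zero_phase(session.channels["eda"])
    edam, _ = ew.rolling_mean_std(eda, 10.0, FS, name="EDA")
    skt = ew.lowpass_zero_phase(session.channels["skt"])
    sktm, _ = ew.rolling_mean_std(skt, 10.0, FS, name="SKT")
    feats = {"hr": hr10, "eda": edam, "skt": sktm}
    base = ew.baseline_profile(feats, (0.0, 180.0))
    events = ew.validate_elicitation(hr2, eda, FS)
    after = [
        ew.window_directions(feats, (e.t_eda_onset_s, e.t_eda_onset_s + 60.0),
                             base)
        for e in events if e.valid
    ]
    before = ew.segment_directions(feats, base, 60.0)
    joy = ew.ANSPattern("joy", 1, 1, 1)
    res_after = ew.match_rate_test(after, joy)
    res_before = ew.match_rate_test(before, joy)
    for ch in ("hr", "eda", "skt"):
        assert res_after[ch][1] < res_before[ch][1]
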