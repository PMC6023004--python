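"""Response-stimulus synchronisation (RSS).

Aligns detected orienting responses and their emotion calls with the
stimulus timeline: each stimulus is greedily matched to the earliest
unclaimed OR whose onset falls within its latency window; ORs matching no
stimulus are labelled non-specific (spontaneous electrodermal activity).
A stimulus scores a "hit" when its matched window's emotion call contains
the stimulus's target emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orienting import OREvent
from .signal_io import StimulusEvent, StimulusTimeline
from .specificity import EmotionCall

DEFAULT_MAX_LATENCY_S = 10.0   # still pictures; 5 s suits continuous film
DEFAULT_PRE_WINDOW_S = 0.0


@dataclass
class StimulusMatch:
    stimulus: StimulusEvent
    or_event: OREvent | None
    latency_s: float | None
    call: EmotionCall | None
    hit: bool


@dataclass
class AlignmentReport:
    matches: list[StimulusMatch]
    non_specific: list[OREvent]

    @property
    def n_matched(self) -> int:
        return sum(m.or_event is not None for m in self.matches)


def _call_for_event(ev: OREvent, calls: list[EmotionCall]) -> EmotionCall | None:
    for c in calls:
        if abs(c.t0 - ev.t_eda_onset_s) < 1e-6:
            return c
    return None


def align(
    timeline: StimulusTimeline,
    events: list[OREvent],
    calls: list[EmotionCall] | None = None,
    max_latency_s: float = DEFAULT_MAX_LATENCY_S,
    pre_window_s: float = DEFAULT_PRE_WINDOW_S,
) -> AlignmentReport:
    """Greedy one-to-one stimulus/OR matching, earliest stimulus first.

    A stimulus claims the earliest unclaimed OR with onset in
    ``[start - pre_window_s, start + max_latency_s]``; each OR is matched to
    at most one stimulus.  Latency is onset minus stimulus start (negative
    only if a pre-window is allowed).
    """
    calls = calls or []
    events = sorted(events, key=lambda e: e.t_eda_onset_s)
    claimed = [False] * len(events)
    matches: list[StimulusMatch] = []
    for stim in sorted(timeline.stimuli(), key=lambda e: e.start_s):
        chosen = None
        for i, ev in enumerate(events):
            if claimed[i]:
                continue
            if stim.start_s - pre_window_s <= ev.t_eda_onset_s <= stim.start_s + max_latency_s:
                chosen = i
                break
        if chosen is None:
            matches.append(StimulusMatch(stim, None, None, None, False))
            continue
        claimed[chosen] = True
        ev = events[chosen]
        call = _call_for_event(ev, calls)
        hit = bool(call and stim.target_emotion in call.emotions)
        matches.append(
            StimulusMatch(stim, ev, ev.t_eda_onset_s - stim.start_s, call, hit)
        )
    non_specific = [ev for i, ev in enumerate(events) if not claimed[i]]
    return AlignmentReport(matches, non_specific)


def hit_rate(report: AlignmentReport) -> dict[str, float]:
    """Per-target-emotion fraction of stimuli whose matched call contains
    the target."""
    if not report.matches:
        raise ValueError("empty alignment report")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for m in report.matches:
        emo = m.stimulus.target_emotion
        totals[emo] = totals.get(emo, 0) + 1
        hits[emo] = hits.get(emo, 0) + int(m.hit)
    return {emo: hits[emo] / totals[emo] for emo in totals}


def report_to_frame(report: AlignmentReport) -> pd.DataFrame:
    rows = []
    for m in report.matches:
        rows.append(
            {
                "stim_start_s": m.stimulus.start_s,
                "stim_label": m.stimulus.label,
                "target_emotion": m.stimulus.target_emotion,
                "or_onset_s": m.or_event.t_eda_onset_s if m.or_event else None,
                "latency_s": m.latency_s,
                "call_emotions": "|".join(sorted(m.call.emotions)) if m.call else "",
                "hit": m.hit,
            }
        )
    for ev in report.non_specific:
        rows.append(
            {
                "stim_start_s": None,
                "stim_label": "non-specific",
                "target_emotion": "",
                "or_onset_s": ev.t_eda_onset_s,
                "latency_s": None,
                "call_emotions": "",
                "hit": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["stim_start_s", "stim_label", "target_emotion", "or_onset_s",
                 "latency_s", "call_emotions", "hit"],
    )
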