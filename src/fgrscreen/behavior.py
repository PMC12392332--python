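"""Behavioral outcome scoring.

Implements the study's scoring rules verbatim: the 0-5 negative-geotaxis
climb-up score binned on latency, the Y-maze spontaneous-alternation index
(correct consecutive-entry triads over entries minus one, times 100), the
novel-object recognition index, and the rota-rod motor-learning difference
between two trials capped at the 300 s protocol limit.
"""

from __future__ import annotations

import logging
from typing import Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "climb_up_score",
    "alternation_index",
    "recognition_index",
    "rotarod_learning",
    "ROTAROD_CAP_S",
]

ROTAROD_CAP_S = 300.0


def climb_up_score(latency_s: float, reacted: bool, fell: bool) -> int:
    """Negative-geotaxis climb-up score on a 0-5 ordinal scale.

    Falling or not reacting scores 0; otherwise latency bins (left-closed,
    right-open; a 15 s latency scores 4): [0,15) -> 5, [15,30) -> 4,
    [30,45) -> 3, [45,60) -> 2, >= 60 s -> 1.
    """
    if fell or not reacted:
        return 0
    if latency_s < 0:
        raise ValueError("latency must be nonnegative")
    for bound, score in ((15.0, 5), (30.0, 4), (45.0, 3), (60.0, 2)):
        if latency_s < bound:
            return score
    return 1


def alternation_index(arm_sequence: Sequence[int], denominator: str = "entries_minus_1") -> float:
    """Y-maze spontaneous-alternation index in percent.

    Counts windows of three consecutive entries visiting three distinct arms
    (1-2-3, 1-3-2, 2-1-3, 2-3-1, 3-1-2, 3-2-1), divides by the number of
    entries minus one, and multiplies by 100. The conventional denominator
    (entries minus two, making a perfect score 100) is available via
    ``denominator='entries_minus_2'``; the default follows the study's
    printed formula.
    """
    seq = list(arm_sequence)
    if len(seq) < 3:
        raise ValueError("need at least 3 arm entries")
    if any(a not in (1, 2, 3) for a in seq):
        raise ValueError("arm entries must be in {1, 2, 3}")
    triads = sum(
        1 for i in range(len(seq) - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    if denominator == "entries_minus_1":
        denom = len(seq) - 1
    elif denominator == "entries_minus_2":
        denom = len(seq) - 2
    else:
        raise ValueError("denominator must be 'entries_minus_1' or 'entries_minus_2'")
    return triads / denom * 100.0


def recognition_index(t_novel_s: float, t_familiar_s: float) -> float:
    """Novel-object recognition index: novel time over total exploration."""
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValueError("exploration times must be nonnegative")
    total = t_novel_s + t_familiar_s
    if total == 0:
        raise ValueError("recognition index undefined when both times are zero")
    return t_novel_s / total


def rotarod_learning(trial1_latency_s: float, trial2_latency_s: float) -> float:
    """Motor-learning delta: second-trial minus first-trial fall latency.

    Latencies beyond the 300 s protocol cap (4-40 rpm over 5 min) are clamped
    with a warning.
    """
    if trial1_latency_s < 0 or trial2_latency_s < 0:
        raise ValueError("latencies must be nonnegative")
    t1, t2 = trial1_latency_s, trial2_latency_s
    if t1 > ROTAROD_CAP_S or t2 > ROTAROD_CAP_S:
        logger.warning("rota-rod latency above the %.0f s cap clamped", ROTAROD_CAP_S)
        t1, t2 = min(t1, ROTAROD_CAP_S), min(t2, ROTAROD_CAP_S)
    return t2 - t1
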