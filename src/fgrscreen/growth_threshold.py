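"""Birth-weight threshold rule for classifying fetal growth restriction (FGR).

Clinical growth charts define FGR by percentile cut-offs (3rd-10th percentile,
i.e. roughly -1.88 to -1.28 SD under normality); for an experimental cohort
without a growth chart the threshold is instead set at ``mean - k * SD`` of an
untreated reference group, with ``k = 1.5`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import norm

from .cohort_types import PupRecord

__all__ = [
    "ThresholdRule",
    "z_from_percentile",
    "fgr_threshold",
    "classify_pups",
    "below_fraction",
]


@dataclass(frozen=True)
class ThresholdRule:
    """Reference-group birth-weight statistics and the SD multiplier.

    Attributes
    ----------
    reference_mean_g : float
        Mean birth weight of the reference (untreated) group, in grams.
    reference_sd_g : float
        Standard deviation of the reference group, in grams (>= 0).
    k_sd : float
        Number of standard deviations below the mean defining the cut-off.
    """

    reference_mean_g: float
    reference_sd_g: float
    k_sd: float = 1.5

    def __post_init__(self) -> None:
        if not self.reference_mean_g > 0:
            raise ValueError("reference_mean_g must be positive")
        if self.reference_sd_g < 0:
            raise ValueError("reference_sd_g must be nonnegative")
        if not self.k_sd > 0:
            raise ValueError("k_sd must be positive")


def z_from_percentile(q: float) -> float:
    """Standard-normal quantile (z-score) for a percentile ``q`` in (0, 1).

    E.g. the 10th percentile corresponds to -1.28 SD and the 3rd to -1.88 SD.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {q!r}")
    return float(norm.ppf(q))


def fgr_threshold(rule: ThresholdRule) -> float:
    """Birth-weight cut-off in grams: ``mean - k_sd * SD`` of the reference."""
    return rule.reference_mean_g - rule.k_sd * rule.reference_sd_g


def classify_pups(pups: Iterable[PupRecord], threshold_g: float) -> list[PupRecord]:
    """Flag each pup as FGR iff its birth weight is strictly below the cut-off.

    Ties at the exact threshold are classified non-FGR ("below" is strict).
    Returns new records; the input is not mutated.
    """
    if not threshold_g > 0:
        raise ValueError("threshold must be positive")
    out: list[PupRecord] = []
    bad: list[str] = []
    for pup in pups:
        w = pup.birth_weight_g
        if w is None or not w == w:  # None or NaN
            bad.append(pup.pup_id)
            continue
        out.append(pup.with_fgr(w < threshold_g))
    if bad:
        raise ValueError(f"pups with missing birth weight: {', '.join(bad)}")
    return out


def below_fraction(pups: Sequence[PupRecord], threshold_g: float) -> float:
    """Fraction of pups with birth weight strictly below ``threshold_g``."""
    pups = list(pups)
    if not pups:
        raise ValueError("below_fraction requires a non-empty cohort")
    classified = classify_pups(pups, threshold_g)
    return sum(p.is_fgr for p in classified) / len(classified)
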