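"""Per-protein birth-weight association screen with FDR control.

The screening funnel: for every quantified CSF protein, compute Spearman's
rank correlation with birth weight separately on postnatal days 4 and 5;
call a protein significant on a day when p < 0.05 and Storey q < 0.1 (q
computed within that day's full protein set); keep proteins significant on
both days with the same sign of correlation; finally retain those annotated
as expressed at >= Medium level in a neuronal, glial or Purkinje cell class
in any brain region.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_types import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenRow",
    "QvalueConfig",
    "BrainAnnotation",
    "CandidateSet",
    "rank_transform",
    "spearman_rho",
    "spearman_pvalue",
    "estimate_pi0",
    "storey_qvalues",
    "screen_day",
    "concordant_candidates",
    "brain_expression_filter",
    "union_report",
    "rows_to_frame",
]

LEVEL_ORDER = {"not_detected": 0, "low": 1, "medium": 2, "high": 3}
CELL_CLASSES = {
    "neuronal", "glial", "endothelial", "neuropil",
    "purkinje", "granular_layer", "molecular_layer", "other",
}
REGIONS = {"cerebral_cortex", "hippocampus", "caudate", "cerebellum"}


@dataclass(frozen=True)
class ScreenRow:
    """Screening statistics of one protein on one day."""

    protein_id: str
    day: str
    n: int
    rho: float
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class QvalueConfig:
    """Storey q-value settings: how the null proportion pi0 is estimated."""

    pi0_mode: str = "smoother"
    lambda_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
    pi0_fixed: float = 1.0
    pi0_floor: float | None = None  # defaults to 1/m at estimation time

    def __post_init__(self) -> None:
        if self.pi0_mode not in ("smoother", "fixed"):
            raise ValueError("pi0_mode must be 'smoother' or 'fixed'")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size and (np.any(np.diff(grid) <= 0) or grid.min() < 0 or grid.max() >= 1):
            raise ValueError("lambda_grid must be strictly increasing within [0, 1)")
        if not 0.0 < self.pi0_fixed <= 1.0:
            raise ValueError("pi0_fixed must be in (0, 1]")


@dataclass(frozen=True)
class BrainAnnotation:
    """Expression levels of one protein by brain region and cell class."""

    protein_id: str
    entries: tuple[tuple[str, str, str], ...]  # (region, cell_class, level)

    def __post_init__(self) -> None:
        for region, cell_class, level in self.entries:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if cell_class not in CELL_CLASSES:
                raise ValueError(f"unknown cell class {cell_class!r}")
            if level not in LEVEL_ORDER:
                raise ValueError(f"unknown level {level!r}")


@dataclass(frozen=True)
class CandidateSet:
    """Result of the cross-day concordance and annotation filters."""

    sig_day4: frozenset[str]
    sig_day5: frozenset[str]
    overlap: frozenset[str]
    consistent_direction: frozenset[str]
    brain_filtered: frozenset[str]
    directions: Mapping[str, int]
    needs_review: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.brain_filtered <= self.consistent_direction <= self.overlap:
            raise ValueError("candidate sets must be nested")
        if self.overlap != self.sig_day4 & self.sig_day5:
            raise ValueError("overlap must equal the intersection of day-wise sets")


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """1-based midranks (ties get the average of their positions)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    return stats.rankdata(arr)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson correlation of the midranks."""
    rx, ry = rank_transform(x), rank_transform(y)
    if len(rx) != len(ry):
        raise ValueError("x and y must have equal length")
    if len(rx) < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1.0, 1.0))


@lru_cache(maxsize=8)
def _perm_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    c = base - base.mean()
    denom = (c * c).sum()
    rho = ((perms - base.mean()) * c).sum(axis=1) / denom
    return np.sort(np.abs(rho))


def spearman_pvalue(rho: float, n: int, method: str = "t_approx") -> float:
    """Two-sided p-value for a Spearman correlation of ``rho`` at sample size n.

    ``t_approx`` uses t = rho * sqrt((n-2)/(1-rho^2)) on Student-t with n-2
    df; ``exact_perm`` (n <= 9) enumerates the tie-free permutation null.
    """
    if not abs(rho) <= 1:
        raise ValueError("|rho| must be <= 1")
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "t_approx":
        if abs(rho) == 1.0:
            return float(np.nextafter(0, 1))
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if method == "exact_perm":
        if n > 9:
            raise ValueError("exact_perm supported only for n <= 9")
        null = _perm_abs_rho(n)
        k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float(k / null.size)
    raise ValueError(f"unknown method {method!r}")


def estimate_pi0(p_values: Sequence[float], config: QvalueConfig = QvalueConfig()) -> float:
    """Estimate the null proportion pi0 from the p-value histogram.

    Smoother mode: evaluate pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    on the lambda grid, fit a cubic polynomial smoother and take its value at
    the largest lambda (Storey's smoother). The result is clamped to
    [pi0_floor, 1] with pi0_floor defaulting to 1/m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    floor = config.pi0_floor if config.pi0_floor is not None else 1.0 / m
    if config.pi0_mode == "fixed":
        return config.pi0_fixed
    if m < 10:
        logger.warning("pi0 smoother needs m >= 10 (got %d); using fixed pi0=%g",
                       m, config.pi0_fixed)
        return config.pi0_fixed
    lam = np.asarray(config.lambda_grid, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lam.max()))
    return float(min(1.0, max(floor, pi0)))


def storey_qvalues(p_values: Sequence[float], pi0: float = 1.0) -> np.ndarray:
    """Storey q-values: step-down minimum of pi0 * m * p(j) / j, capped at 1.

    With pi0 = 1 these coincide exactly with Benjamini-Hochberg adjusted
    p-values. Returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rowwise_spearman(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Spearman rho of every row of ``values`` against ``weights`` (no NaN)."""
    rx = stats.rankdata(values, axis=1)
    ry = stats.rankdata(weights)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=1) / denom
    return np.clip(rho, -1.0, 1.0)


def screen_day(
    abundance: AbundanceMatrix | pd.DataFrame,
    weights: Mapping[str, float],
    p_thresh: float = 0.05,
    q_thresh: float = 0.1,
    qconfig: QvalueConfig = QvalueConfig(),
    day: str | None = None,
) -> list[ScreenRow]:
    """Screen one day's abundance matrix against birth weight.

    Missing abundances (NaN, allowed when a plain DataFrame is passed) are
    handled per protein with complete pairs; proteins with fewer than 4
    complete pairs are excluded from the q-value computation and flagged
    non-significant with q = NaN. q-values are computed across the full
    protein set of the day.
    """
    if isinstance(abundance, AbundanceMatrix):
        frame, day = abundance.values, abundance.day
    else:
        frame = abundance
        day = day or "PND4"
    missing = [s for s in frame.columns if s not in weights]
    if missing:
        raise ValueError(f"samples without a birth weight: {', '.join(map(str, missing))}")
    w = np.array([weights[s] for s in frame.columns], dtype=float)
    vals = frame.to_numpy(dtype=float)
    m, n_samples = vals.shape

    n = np.full(m, n_samples, dtype=int)
    rho = np.full(m, np.nan)
    nan_rows = np.isnan(vals).any(axis=1)
    clean = ~nan_rows
    if clean.any():
        rho[clean] = _rowwise_spearman(vals[clean], w)
    for i in np.flatnonzero(nan_rows):
        ok = ~np.isnan(vals[i])
        n[i] = int(ok.sum())
        if n[i] >= 4:
            rho[i] = _rowwise_spearman(vals[i, ok][None, :], w[ok])[0]

    usable = (n >= 4) & ~np.isnan(rho)
    p = np.full(m, np.nan)
    for nv in np.unique(n[usable]):
        mask = usable & (n == nv)
        r = rho[mask]
        with np.errstate(divide="ignore"):
            t = np.where(np.abs(r) == 1.0, np.inf,
                         r * np.sqrt((nv - 2) / np.maximum(1.0 - r * r, 1e-300)))
        pv = 2.0 * stats.t.sf(np.abs(t), df=nv - 2)
        p[mask] = np.maximum(pv, np.nextafter(0, 1))
    if (~usable).any():
        logger.info("%d/%d proteins excluded (fewer than 4 complete pairs or constant)",
                    int((~usable).sum()), m)

    q = np.full(m, np.nan)
    if usable.any():
        pi0 = estimate_pi0(p[usable], qconfig)
        q[usable] = storey_qvalues(p[usable], pi0)

    rows = []
    for i, pid in enumerate(frame.index):
        sig = bool(usable[i] and p[i] < p_thresh and q[i] < q_thresh)
        rows.append(ScreenRow(str(pid), day, int(n[i]),
                              float(rho[i]), float(p[i]), float(q[i]), sig))
    return rows


def rows_to_frame(rows: Iterable[ScreenRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.day, r.n, r.rho, r.p_value, r.q_value, r.significant) for r in rows],
        columns=["protein_id", "day", "n", "rho", "p_value", "q_value", "significant"],
    )


def concordant_candidates(
    day4: Sequence[ScreenRow], day5: Sequence[ScreenRow]
) -> CandidateSet:
    """Cross the day-wise screens: proteins significant on both days with the
    same (nonzero) sign of correlation. A zero rho carries no direction and is
    never concordant. Proteins screened on only one day are dropped from the
    concordance universe (logged)."""
    by4 = {r.protein_id: r for r in day4}
    by5 = {r.protein_id: r for r in day5}
    universe = set(by4) & set(by5)
    dropped = (set(by4) | set(by5)) - universe
    if dropped:
        logger.info("%d proteins present on only one day excluded from concordance",
                    len(dropped))
    sig4 = frozenset(p for p in universe if by4[p].significant)
    sig5 = frozenset(p for p in universe if by5[p].significant)
    overlap = sig4 & sig5
    consistent = frozenset(
        p for p in overlap
        if np.sign(by4[p].rho) == np.sign(by5[p].rho) and by4[p].rho != 0
    )
    directions = {p: int(np.sign(by4[p].rho)) for p in consistent}
    return CandidateSet(
        sig_day4=sig4, sig_day5=sig5, overlap=frozenset(overlap),
        consistent_direction=consistent, brain_filtered=frozenset(),
        directions=directions,
    )


def brain_expression_filter(
    candidates: CandidateSet,
    annotations: Iterable[BrainAnnotation],
    min_level: str = "medium",
    cell_classes: frozenset[str] | set[str] = frozenset({"neuronal", "glial", "purkinje"}),
) -> CandidateSet:
    """Retain candidates expressed at >= ``min_level`` in at least one allowed
    cell class in any brain region.

    Candidates lacking an annotation record are placed on a needs-review list
    and excluded from ``brain_filtered``.
    """
    if min_level not in LEVEL_ORDER:
        raise ValueError(f"unknown level {min_level!r}")
    unknown = set(cell_classes) - CELL_CLASSES
    if unknown:
        raise ValueError(f"unknown cell classes: {sorted(unknown)}")
    ann_by_id = {a.protein_id: a for a in annotations}
    min_rank = LEVEL_ORDER[min_level]
    retained, review = set(), set()
    for pid in candidates.consistent_direction:
        ann = ann_by_id.get(pid)
        if ann is None:
            review.add(pid)
            logger.warning("candidate %s has no annotation record; needs review", pid)
            continue
        if any(cc in cell_classes and LEVEL_ORDER[lvl] >= min_rank
               for _, cc, lvl in ann.entries):
            retained.add(pid)
    return replace(candidates, brain_filtered=frozenset(retained),
                   needs_review=frozenset(review))


def union_report(n_day4: int, n_day5: int, n_overlap: int) -> int:
    """Size of the union of the two day-wise significant sets."""
    if n_overlap > min(n_day4, n_day5):
        raise ValueError("overlap cannot exceed either day-wise set")
    return n_day4 + n_day5 - n_overlap
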