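"""Nonparametric group comparisons: Steel-Dwass all-pairs test and the
Wilcoxon signed-rank test.

The Steel-Dwass procedure compares every unordered pair of k groups with a
Wilcoxon rank-sum statistic computed on the pooled pair (midranks, with the
tie-corrected variance), and refers sqrt(2) * |standardized statistic| to the
studentized-range distribution Q_{k, inf}. Family-wise error control is
internal to the reference distribution; no further adjustment is applied.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SteelDwassResult",
    "steel_dwass_pair_stat",
    "studentized_range_sf",
    "steel_dwass_test",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class SteelDwassResult:
    """One pairwise comparison: rank-sum W of group_b within the pooled pair,
    its null mean and tie-corrected variance, the standardized statistic and
    (once the family size k is known) the studentized-range p-value."""

    group_a: str
    group_b: str
    W: float
    E_W: float
    Var_W: float
    t_stat: float
    p_value: float | None = None


def steel_dwass_pair_stat(
    a: Sequence[float], b: Sequence[float], group_a: str = "a", group_b: str = "b"
) -> SteelDwassResult:
    """Standardized rank-sum statistic of one group pair (no p-value yet).

    Pools a and b, midranks the pooled sample, and standardizes the rank sum
    of b by its null mean n_b (N+1)/2 and the tie-corrected variance
    n_a n_b / (N (N-1)) * (sum r^2 - N (N+1)^2 / 4). A zero variance (all
    observations tied) yields t_stat = 0 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    W = float(ranks[n_a:].sum())
    E_W = n_b * (N + 1) / 2.0
    var = n_a * n_b / (N * (N - 1.0)) * (float((ranks**2).sum()) - N * (N + 1) ** 2 / 4.0)
    var = max(var, 0.0)
    t = 0.0 if var == 0 else (W - E_W) / math.sqrt(var)
    return SteelDwassResult(group_a, group_b, W, E_W, var, t)


def studentized_range_sf(q: float, k: int) -> float:
    """Upper-tail probability P(Q_{k, inf} >= q) of the studentized range of
    k standard-normal means at infinite degrees of freedom.

    Computed by numerical integration of
    1 - k * int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz over the real line.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    if q == 0:
        return 1.0

    def integrand(z: float) -> float:
        return stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return float(min(1.0, max(0.0, 1.0 - k * cdf)))


def steel_dwass_test(groups: Mapping[str, Sequence[float]]) -> list[SteelDwassResult]:
    """All-pairs Steel-Dwass comparisons over k >= 2 groups.

    For each unordered pair, p = P(Q_{k, inf} >= sqrt(2) |t_stat|).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    k = len(groups)
    results = []
    for ga, gb in itertools.combinations(groups, 2):
        res = steel_dwass_pair_stat(groups[ga], groups[gb], ga, gb)
        p = studentized_range_sf(math.sqrt(2.0) * abs(res.t_stat), k)
        results.append(replace(res, p_value=p))
    return results


def _signed_rank_exact_p(w: float, doubled_ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic via the polynomial
    count of achievable positive-rank sums (handles midranks; ranks doubled
    to integers)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    w2 = 2.0 * w
    mean = total / 2.0
    dev = abs(w2 - mean)
    sums = np.arange(total + 1)
    p = counts[np.abs(sums - mean) >= dev - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (logged). The exact null distribution of
    the positive-rank sum is enumerated for n <= 25 (midranks supported);
    larger n uses the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d != 0
    if (~nz).any():
        logger.info("dropping %d zero differences", int((~nz).sum()))
    d = d[nz]
    n = d.size
    if n == 0:
        logger.warning("all differences are zero; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        doubled = np.rint(2.0 * ranks).astype(int)
        return _signed_rank_exact_p(w_plus, doubled)
    mean = n * (n + 1) / 4.0
    # tie correction subtracts sum(t^3 - t)/48 over tie groups of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(((tie_counts**3) - tie_counts).sum()) / 48.0
    if var == 0:
        return 1.0
    z = (w_plus - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
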