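"""Measurement normalization rules.

Western-blot densitometry is normalized by the albumin band (endogenous
control), then expressed relative to a reference group mean set to 1 — either
the sham group at day 4 globally, or the sham group per time point, depending
on the study design. Immunofluorescence intensities are rescaled affinely so
the background maps to 1 and the panel maximum to 100.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "albumin_normalize",
    "relative_to_reference",
    "fluorescence_rescale",
    "normalize_timecourse",
]


def albumin_normalize(band: float, albumin: float) -> float:
    """Band density divided by the albumin (endogenous-control) density."""
    if not albumin > 0:
        raise ValueError("albumin density must be positive")
    if band < 0:
        raise ValueError("band density must be nonnegative")
    return band / albumin


def relative_to_reference(
    ratios: Sequence[float], reference_ratios: Sequence[float]
) -> np.ndarray:
    """Express ratios relative to the reference group's arithmetic mean.

    The reference group's own mean maps to exactly 1.
    """
    ref = np.asarray(reference_ratios, dtype=float)
    if ref.size == 0:
        raise ValueError("reference group is empty")
    ref_mean = ref.mean()
    if not ref_mean > 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(ratios, dtype=float) / ref_mean


def fluorescence_rescale(
    values: Sequence[float], background: float, maximum: float
) -> np.ndarray:
    """Affine rescale of intensities so background -> 1 and maximum -> 100.

    Values outside [background, maximum] are clamped to the anchors, with the
    clamp count logged (per-image maxima can exceed the panel-wide maximum).
    """
    if not maximum > background:
        raise ValueError("maximum must exceed background")
    v = np.asarray(values, dtype=float)
    clamped = int(((v < background) | (v > maximum)).sum())
    if clamped:
        logger.warning("%d intensity values clamped to the [background, maximum] anchors",
                       clamped)
    v = np.clip(v, background, maximum)
    return 1.0 + 99.0 * (v - background) / (maximum - background)


def normalize_timecourse(
    table: pd.DataFrame,
    reference_group: str = "sham",
    mode: str = "global_day4",
    reference_day: int | None = None,
) -> pd.DataFrame:
    """Append a ``relative_expression`` column to a densitometry table.

    Expects columns analyte, day, group, band_density, albumin_density.
    ``mode='global_day4'`` scales each analyte by the mean albumin-normalized
    ratio of the reference group at the earliest day (or ``reference_day``);
    ``mode='per_day'`` rescales within each analyte x day cell so the
    reference group's mean is 1 at every time point.
    """
    if mode not in ("global_day4", "per_day"):
        raise ValueError("mode must be 'global_day4' or 'per_day'")
    required = {"analyte", "day", "group", "band_density", "albumin_density"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    out["ratio"] = [
        albumin_normalize(b, a) for b, a in zip(out["band_density"], out["albumin_density"])
    ]
    out["relative_expression"] = np.nan
    for analyte, sub in out.groupby("analyte"):
        if mode == "global_day4":
            day0 = reference_day if reference_day is not None else int(sub["day"].min())
            ref = sub.loc[(sub["group"] == reference_group) & (sub["day"] == day0), "ratio"]
            out.loc[sub.index, "relative_expression"] = relative_to_reference(
                sub["ratio"].to_numpy(), ref.to_numpy()
            )
        else:
            for day, cell in sub.groupby("day"):
                ref = cell.loc[cell["group"] == reference_group, "ratio"]
                out.loc[cell.index, "relative_expression"] = relative_to_reference(
                    cell["ratio"].to_numpy(), ref.to_numpy()
                )
    return out.drop(columns=["ratio"])
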