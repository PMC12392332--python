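"""Core record types shared across the simulation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("control", "sham", "hypoperfusion")
TREATMENTS = ("none", "vehicle", "msc")
DAYS = ("PND4", "PND5", "PND7", "PND10", "PND14")


@dataclass(frozen=True)
class PupRecord:
    """One animal: identity, experimental group, treatment arm, birth weight."""

    pup_id: str
    dam_id: str
    group: str
    treatment: str = "none"
    birth_weight_g: float | None = None
    is_fgr: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.treatment == "msc" and self.group != "hypoperfusion":
            raise ValueError("MSC treatment is only defined for hypoperfusion pups")
        if self.birth_weight_g is not None and not self.birth_weight_g > 0:
            raise ValueError("birth_weight_g must be positive")

    def with_fgr(self, flag: bool) -> "PupRecord":
        return replace(self, is_fgr=bool(flag))


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance table for one postnatal day.

    ``values`` is a DataFrame indexed by protein id with sample-id columns;
    all entries must be finite and nonnegative (arbitrary reporter-intensity
    units from isobaric-tag quantification).
    """

    day: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValueError(f"unknown day {self.day!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("abundances must be finite")
        if (arr < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated proteome: which proteins respond to birth
    weight, with what direction (+1/-1) and effect size on the log scale."""

    responder_ids: frozenset[str]
    directions: Mapping[str, int]
    effect_sizes: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.directions) != set(self.responder_ids):
            raise ValueError("directions must be defined exactly on responder_ids")
        if any(d not in (-1, 1) for d in self.directions.values()):
            raise ValueError("directions must be +1 or -1")


@dataclass(frozen=True)
class TimecourseRecord:
    """One densitometry measurement: analyte level for a pup-group at a day."""

    analyte: str
    day: int
    group: str
    band_density: float
    albumin_density: float
    relative_expression: float | None = None


@dataclass(frozen=True)
class BehaviorTrial:
    """One behavioral trial; ``payload`` holds test-specific measurements."""

    pup_id: str
    test: str
    day: int
    group: str
    payload: dict = field(default_factory=dict)
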