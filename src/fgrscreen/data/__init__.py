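"""Packaged reference tables.

``candidate_annotations()`` loads the brain-expression annotation panel
(Human Protein Atlas levels by region and cell class) for the 15 CSF
biomarker candidates of the modelled study; ``CANDIDATE_DIRECTIONS`` gives
each candidate's direction of association with birth weight on postnatal
day 4 (+1: abundance rises with weight, -1: falls).
"""

from importlib.resources import files

from ..io import load_annotations
from ..screen import BrainAnnotation

__all__ = ["candidate_annotations", "CANDIDATE_DIRECTIONS", "CANDIDATE_IDS"]

CANDIDATE_DIRECTIONS: dict[str, int] = {
    "Cd200": -1,
    "A2m": -1,
    "Ubb": -1,
    "Serpini1": -1,
    "Otub1": 1,
    "Ube1": 1,
    "Sned1": 1,
    "Cd93": 1,
    "Fabp3": 1,
    "Serpina3": -1,
    "Eno3": 1,
    "Fetub": -1,
    "Hrg": 1,
    "C4": -1,
    "Ces1": 1,
}

CANDIDATE_IDS: tuple[str, ...] = tuple(CANDIDATE_DIRECTIONS)


def candidate_annotations() -> list[BrainAnnotation]:
    """Annotation records for the 15-candidate reference panel."""
    path = files(__package__) / "candidate_annotations.tsv"
    return load_annotations(str(path))
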