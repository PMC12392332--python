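"""Schema-validated TSV table I/O.

All pipeline tables are UTF-8 TSV with a header row and '.' decimal
separator; "NA" and empty fields are parsed as missing and counted in the
log. Schemas are declared as column -> kind maps with kinds in
{'str', 'float', 'int', 'bool'}.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .screen import BrainAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_table",
    "write_table",
    "load_annotations",
    "SAMPLES_SCHEMA",
    "TIMECOURSE_SCHEMA",
    "ANNOTATIONS_SCHEMA",
]

SAMPLES_SCHEMA = {
    "pup_id": "str",
    "dam_id": "str",
    "group": "str",
    "treatment": "str",
    "birth_weight_g": "float",
}
TIMECOURSE_SCHEMA = {
    "analyte": "str",
    "day": "int",
    "group": "str",
    "band_density": "float",
    "albumin_density": "float",
}
ANNOTATIONS_SCHEMA = {
    "protein_id": "str",
    "region": "str",
    "cell_class": "str",
    "level": "str",
}

_KINDS = {"str": "string", "float": "float64", "int": "int64", "bool": "boolean"}


def read_table(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a TSV table, validating required columns and coercing types."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=True)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required columns: {', '.join(missing)}")
        for col, kind in schema.items():
            if kind not in _KINDS:
                raise ValueError(f"unknown schema kind {kind!r}")
            try:
                if kind in ("float", "int"):
                    df[col] = pd.to_numeric(df[col], errors="raise")
                    if kind == "int":
                        df[col] = df[col].astype("int64")
                elif kind == "bool":
                    df[col] = df[col].astype("boolean")
                else:
                    df[col] = df[col].astype("string")
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path.name}: column {col!r} not parseable as {kind}: {exc}")
        n_missing = int(df[list(schema)].isna().sum().sum())
        if n_missing:
            logger.info("%s: %d missing values across schema columns", path.name, n_missing)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a table as UTF-8 TSV ('.' decimals, 'NA' for missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
    return path


def load_annotations(path: str | Path) -> list[BrainAnnotation]:
    """Read a long-format brain-expression annotation table.

    Columns: protein_id, region, cell_class, level (one row per annotation
    entry; a protein may appear on several rows).
    """
    df = read_table(path, ANNOTATIONS_SCHEMA)
    out: list[BrainAnnotation] = []
    for pid, sub in df.groupby("protein_id", sort=True):
        entries = tuple(
            (str(r.region), str(r.cell_class), str(r.level)) for r in sub.itertuples()
        )
        out.append(BrainAnnotation(protein_id=str(pid), entries=entries))
    return out


def annotations_to_frame(annotations: Iterable[BrainAnnotation]) -> pd.DataFrame:
    rows = [
        (a.protein_id, region, cc, level)
        for a in annotations
        for region, cc, level in a.entries
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATIONS_SCHEMA))
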