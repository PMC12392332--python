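"""End-to-end orchestration of the biomarker-discovery pipeline.

Stages: classify pups against the FGR birth-weight threshold; screen the
day-4 and day-5 CSF proteomes against birth weight; cross the days for
concordant candidates; apply the brain-expression filter; report the funnel
counts. Every stage logs its input/output counts — the analysis is exactly a
sequence of count-annotated filters — and all intermediate tables are
written as TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tableio
from .cohort_types import PupRecord
from .growth_threshold import ThresholdRule, classify_pups, fgr_threshold
from .screen import (
    CandidateSet,
    QvalueConfig,
    brain_expression_filter,
    concordant_candidates,
    rows_to_frame,
    screen_day,
    union_report,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FunnelReport", "run_full_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """File locations and statistical settings of one pipeline run."""

    samples: Path
    abundance_pnd4: Path
    abundance_pnd5: Path
    annotations: Path
    outdir: Path
    reference_group: str = "control"
    k_sd: float = 1.5
    p_thresh: float = 0.05
    q_thresh: float = 0.1
    qvalue: QvalueConfig = field(default_factory=QvalueConfig)
    min_level: str = "medium"
    cell_classes: frozenset[str] = frozenset({"neuronal", "glial", "purkinje"})

    def __post_init__(self) -> None:
        if not 0 < self.p_thresh < 1 or not 0 < self.q_thresh < 1:
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class FunnelReport:
    """Counts at every stage of the screening funnel plus the candidate table."""

    threshold_g: float
    m_quantified: dict[str, int]
    n_sig: dict[str, int]
    n_overlap: int
    n_union: int
    n_consistent: int
    n_brain_filtered: int
    candidates: CandidateSet
    candidate_table: pd.DataFrame

    def __post_init__(self) -> None:
        days = sorted(self.n_sig)
        if len(days) == 2:
            if self.n_union != union_report(self.n_sig[days[0]], self.n_sig[days[1]], self.n_overlap):
                raise ValueError("funnel counts are arithmetically inconsistent")
        if not (self.n_brain_filtered <= self.n_consistent <= self.n_overlap):
            raise ValueError("funnel counts must be nested")

    def summary(self) -> dict:
        return {
            "threshold_g": self.threshold_g,
            "m_quantified": self.m_quantified,
            "n_sig_day4": self.n_sig.get("PND4"),
            "n_sig_day5": self.n_sig.get("PND5"),
            "n_overlap": self.n_overlap,
            "n_union": self.n_union,
            "n_consistent": self.n_consistent,
            "n_brain_filtered": self.n_brain_filtered,
            "brain_filtered": sorted(self.candidates.brain_filtered),
            "needs_review": sorted(self.candidates.needs_review),
        }


def _read_abundance(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "protein_id"
    return df.astype(float)


def _pups_from_frame(df: pd.DataFrame) -> list[PupRecord]:
    return [
        PupRecord(
            pup_id=str(r.pup_id), dam_id=str(r.dam_id), group=str(r.group),
            treatment=str(r.treatment), birth_weight_g=float(r.birth_weight_g),
        )
        for r in df.itertuples()
    ]


def run_full_pipeline(config: PipelineConfig) -> FunnelReport:
    """Execute classify -> screen (both days) -> concordance -> brain filter.

    Writes ``samples_classified.tsv``, ``screen_day4.tsv``, ``screen_day5.tsv``,
    ``candidates.tsv`` and ``summary.json`` into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    samples = tableio.read_table(config.samples, tableio.SAMPLES_SCHEMA)
    pups = _pups_from_frame(samples)
    ref = [p for p in pups if p.group == config.reference_group]
    if not ref:
        raise ValueError(f"no pups in reference group {config.reference_group!r}")
    ref_w = pd.Series([p.birth_weight_g for p in ref])
    rule = ThresholdRule(float(ref_w.mean()), float(ref_w.std(ddof=1)), config.k_sd)
    threshold = fgr_threshold(rule)
    classified = classify_pups(pups, threshold)
    logger.info("classify: %d pups, threshold %.3f g, %d below",
                len(classified), threshold, sum(p.is_fgr for p in classified))
    samples["is_fgr"] = [p.is_fgr for p in classified]
    tableio.write_table(samples, outdir / "samples_classified.tsv")

    weights = {p.pup_id: p.birth_weight_g for p in pups}
    day_rows = {}
    m_quantified = {}
    for day, path in (("PND4", config.abundance_pnd4), ("PND5", config.abundance_pnd5)):
        frame = _read_abundance(Path(path))
        m_quantified[day] = len(frame)
        rows = screen_day(frame, weights, config.p_thresh, config.q_thresh,
                          config.qvalue, day=day)
        day_rows[day] = rows
        n_sig = sum(r.significant for r in rows)
        logger.info("screen %s: %d proteins in, %d significant", day, len(rows), n_sig)
        tableio.write_table(rows_to_frame(rows), outdir / f"screen_{day.lower()}.tsv")

    candidates = concordant_candidates(day_rows["PND4"], day_rows["PND5"])
    logger.info("concordance: %d overlap -> %d direction-consistent",
                len(candidates.overlap), len(candidates.consistent_direction))
    annotations = tableio.load_annotations(config.annotations)
    candidates = brain_expression_filter(candidates, annotations,
                                         config.min_level, config.cell_classes)
    logger.info("brain filter: %d -> %d retained (%d need review)",
                len(candidates.consistent_direction), len(candidates.brain_filtered),
                len(candidates.needs_review))

    by4 = {r.protein_id: r for r in day_rows["PND4"]}
    by5 = {r.protein_id: r for r in day_rows["PND5"]}
    cand_rows = []
    for pid in sorted(candidates.consistent_direction):
        r4, r5 = by4[pid], by5[pid]
        cand_rows.append((pid, candidates.directions[pid],
                          r4.rho, r4.p_value, r4.q_value,
                          r5.rho, r5.p_value, r5.q_value,
                          pid in candidates.brain_filtered))
    candidate_table = pd.DataFrame(
        cand_rows,
        columns=["protein_id", "direction", "rho_day4", "p_day4", "q_day4",
                 "rho_day5", "p_day5", "q_day5", "brain_filtered"],
    )
    tableio.write_table(candidate_table, outdir / "candidates.tsv")

    n_sig = {d: sum(r.significant for r in rows) for d, rows in day_rows.items()}
    report = FunnelReport(
        threshold_g=threshold,
        m_quantified=m_quantified,
        n_sig=n_sig,
        n_overlap=len(candidates.overlap),
        n_union=union_report(n_sig["PND4"], n_sig["PND5"], len(candidates.overlap)),
        n_consistent=len(candidates.consistent_direction),
        n_brain_filtered=len(candidates.brain_filtered),
        candidates=candidates,
        candidate_table=candidate_table,
    )
    (outdir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    return report
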