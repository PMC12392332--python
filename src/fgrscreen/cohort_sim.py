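"""Seeded generators for a synthetic FGR-model rat study.

The generators emulate the tabular outputs of the study design this package
analyzes: group-structured birth weights (control / sham / intrauterine
hypoperfusion), a tandem-mass-tag CSF proteome on postnatal days 4 and 5 with
a planted subset of proteins monotonically associated with birth weight,
longitudinal densitometry-style biomarker measurements, and behavioral
outcomes. Everything is deterministic under a fixed (seed, config) pair; each
generator owns an independent RNG stream derived from the master seed, so
adding one generator never perturbs another's output.

Birth-weight calibration
------------------------
Group weights are normal. The control default (7.01 g, 0.55 g) and sham
default (6.87 g, 0.74 g) are the reference statistics of the modelled study;
the hypoperfusion mean defaults to 5.727 g so that with sigma = 0.74 the
probability of falling below the 6.185 g threshold (control mean - 1.5 SD)
is 0.73, the reported fraction of hypoperfusion offspring classified as FGR.

Proteome model
--------------
Reporter intensities are log-normal (positive, right-skewed). A responder
protein j with direction d_j in {+1, -1} has

    log A_ij = log(baseline_j) + d_j * beta * z_i + eps_ij,

where z_i is the birth-weight z-score within the profiled cohort and
eps ~ N(0, noise_sd^2). Under this bivariate-normal model the population
Spearman correlation is rho_s = (6/pi) * arcsin(r/2) with Pearson
r = beta / sqrt(beta^2 + noise_sd^2); beta is chosen by inverting that
relation so the expected |rho_s| matches ``target_abs_rho``. Null proteins
are independent of weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_types import (
    AbundanceMatrix,
    BehaviorTrial,
    GROUPS,
    PlantedTruth,
    PupRecord,
    TimecourseRecord,
)

__all__ = [
    "SimConfig",
    "gen_cohort",
    "gen_proteome",
    "gen_timecourse",
    "gen_behavior",
    "simulate_study",
    "spearman_to_pearson",
    "effect_size_for_rho",
]

# fixed per-generator offsets for deriving independent RNG streams
_STREAM = {"cohort": 1, "cohort_day5": 2, "proteome": 3, "timecourse": 4, "behavior": 5}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the modelled study's defaults."""

    seed: int = 0
    n_per_group: int = 10
    n_proteins: int = 601
    n_responders: int = 15
    target_abs_rho: float = 0.8
    group_weight_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (7.01, 0.55),
            "sham": (6.87, 0.74),
            "hypoperfusion": (5.727, 0.74),
        }
    )
    noise_sd: float = 0.5
    concordance_prob: float = 1.0
    same_pups_both_days: bool = False
    litter_size: int = 10
    litter_sd: float = 0.0
    # timecourse: relative level by arm; sham is centred at 1
    tc_analytes: tuple[str, ...] = ("Cd200", "A2m", "Ubb", "Serpini1", "Otub1", "Ube1")
    tc_days: tuple[int, ...] = (5, 7, 10, 14)
    tc_elevation: float = 2.0
    tc_attenuation: float = 1.0
    tc_noise_sd: float = 0.3
    tc_n_per_group: int = 10
    # behavior
    beh_deficit: float = 1.0
    beh_msc_rescue: float = 0.8
    beh_alternation_bias: float = 0.75
    beh_n_ymaze_entries: int = 12

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_responders > self.n_proteins:
            raise ValueError("n_responders must not exceed n_proteins")
        if not 0.0 < self.target_abs_rho < 1.0:
            raise ValueError("target_abs_rho must be in (0, 1)")
        if not 0.0 <= self.concordance_prob <= 1.0:
            raise ValueError("concordance_prob must be in [0, 1]")
        if self.noise_sd <= 0 or self.tc_noise_sd < 0:
            raise ValueError("noise SDs must be positive")
        for g, (mu, sd) in self.group_weight_params.items():
            if sd < 0:
                raise ValueError(f"negative weight SD for group {g!r}")
            if mu <= 0:
                raise ValueError(f"non-positive weight mean for group {g!r}")


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson r of a bivariate normal with Spearman correlation ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def effect_size_for_rho(target_abs_rho: float, noise_sd: float) -> float:
    """Slope beta on the weight z-score giving the target |Spearman rho|."""
    r = spearman_to_pearson(target_abs_rho)
    return noise_sd * r / math.sqrt(1.0 - r * r)


def gen_cohort(
    config: SimConfig,
    groups: Sequence[str] = GROUPS,
    stream: str = "cohort",
    prefix: str = "",
) -> list[PupRecord]:
    """Draw a cohort of pups with group-structured normal birth weights.

    Pups are assigned round-robin to dams (litters of at most
    ``config.litter_size``); a shared normal litter effect with SD
    ``config.litter_sd`` (default 0) is added to each litter's weights.
    """
    for g in groups:
        if g not in config.group_weight_params:
            raise ValueError(f"no weight parameters for group {g!r}")
    rng = _rng(config, stream)
    pups: list[PupRecord] = []
    n = config.n_per_group
    for group in groups:
        mu, sd = config.group_weight_params[group]
        n_dams = max(1, math.ceil(n / config.litter_size))
        litter_shift = rng.normal(0.0, config.litter_sd, size=n_dams) if config.litter_sd > 0 else np.zeros(n_dams)
        weights = rng.normal(mu, sd, size=n)
        for i in range(n):
            dam = i % n_dams
            w = max(weights[i] + litter_shift[dam], 1e-3)  # weights are physical masses
            pups.append(
                PupRecord(
                    pup_id=f"{prefix}{group}_{i + 1:04d}",
                    dam_id=f"{prefix}{group}_dam{dam + 1:02d}",
                    group=group,
                    birth_weight_g=float(w),
                )
            )
    return pups


def _profiled(cohort: Sequence[PupRecord]) -> list[PupRecord]:
    """CSF profiling covers the sham and hypoperfusion arms."""
    kept = [p for p in cohort if p.group in ("sham", "hypoperfusion")]
    return kept if kept else list(cohort)


def gen_proteome(
    cohort: Sequence[PupRecord],
    config: SimConfig,
    cohort_day5: Sequence[PupRecord] | None = None,
) -> tuple[AbundanceMatrix, AbundanceMatrix, PlantedTruth]:
    """Simulate day-4 and day-5 CSF abundance matrices with planted responders.

    If ``cohort_day5`` is omitted the same pups are profiled on both days;
    ``simulate_study`` passes an independently drawn cohort by default,
    mirroring a design with distinct pups per day. With probability
    ``1 - concordance_prob`` a responder's direction is flipped on day 5
    (the planted truth records the day-4 direction).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = _rng(config, "proteome")
    m, m1 = config.n_proteins, config.n_responders

    protein_ids = [f"P{i:04d}" for i in range(1, m + 1)]
    responder_idx = rng.choice(m, size=m1, replace=False)
    directions_arr = rng.choice([-1, 1], size=m1)
    beta = effect_size_for_rho(config.target_abs_rho, config.noise_sd)
    log_baseline = rng.normal(14.0, 1.5, size=m)
    flip_day5 = rng.random(m1) >= config.concordance_prob

    day_cohorts = {
        "PND4": _profiled(cohort),
        "PND5": _profiled(cohort_day5 if cohort_day5 is not None else cohort),
    }
    matrices = {}
    for day, pups in day_cohorts.items():
        w = np.array([p.birth_weight_g for p in pups], dtype=float)
        if w.std() == 0:
            z = np.zeros_like(w)
        else:
            z = (w - w.mean()) / w.std()
        n = len(pups)
        log_a = log_baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(m, n))
        dirs = directions_arr.copy()
        if day == "PND5":
            dirs = np.where(flip_day5, -directions_arr, directions_arr)
        log_a[responder_idx, :] += (dirs[:, None] * beta) * z[None, :]
        values = pd.DataFrame(np.exp(log_a), index=protein_ids, columns=[p.pup_id for p in pups])
        matrices[day] = AbundanceMatrix(day=day, values=values)

    responder_ids = [protein_ids[i] for i in responder_idx]
    truth = PlantedTruth(
        responder_ids=frozenset(responder_ids),
        directions={pid: int(d) for pid, d in zip(responder_ids, directions_arr)},
        effect_sizes={pid: float(beta) for pid in responder_ids},
    )
    return matrices["PND4"], matrices["PND5"], truth


def default_timecourse_profiles(config: SimConfig) -> dict[str, dict[int, tuple[float, float]]]:
    """Per-analyte (fgr_level, msc_level) by day.

    FGR-vehicle sits at ``tc_elevation``; the MSC arm is pulled back toward 1
    by ``tc_attenuation`` (1.0 = fully rescued) from day 5 on.
    """
    e, a = config.tc_elevation, config.tc_attenuation
    out: dict[str, dict[int, tuple[float, float]]] = {}
    for analyte in config.tc_analytes:
        out[analyte] = {
            day: (e, 1.0 + (e - 1.0) * (1.0 - a) if day >= 5 else e) for day in config.tc_days
        }
    return out


def gen_timecourse(
    config: SimConfig,
    profiles: Mapping[str, Mapping[int, tuple[float, float]]] | None = None,
) -> list[TimecourseRecord]:
    """Densitometry-style analyte levels by group x day with multiplicative noise.

    Emits raw band and albumin densities whose ratio equals the configured
    relative level times log-normal noise (exactly the level when
    ``tc_noise_sd`` is 0); normalization to the sham reference is left to the
    quantify module, as for real blots.
    """
    if profiles is None:
        profiles = default_timecourse_profiles(config)
    rng = _rng(config, "timecourse")
    records: list[TimecourseRecord] = []
    arms = ("sham", "fgr_vehicle", "fgr_msc")
    for analyte, by_day in profiles.items():
        for day, (fgr_level, msc_level) in sorted(by_day.items()):
            levels = {"sham": 1.0, "fgr_vehicle": fgr_level, "fgr_msc": msc_level}
            for arm in arms:
                albumin = rng.lognormal(mean=math.log(100.0), sigma=0.2, size=config.tc_n_per_group)
                noise = (
                    np.exp(rng.normal(0.0, config.tc_noise_sd, size=config.tc_n_per_group))
                    if config.tc_noise_sd > 0
                    else np.ones(config.tc_n_per_group)
                )
                for j in range(config.tc_n_per_group):
                    records.append(
                        TimecourseRecord(
                            analyte=analyte,
                            day=day,
                            group=arm,
                            band_density=float(levels[arm] * noise[j] * albumin[j]),
                            albumin_density=float(albumin[j]),
                        )
                    )
    return records


def _behavior_arm(pup: PupRecord, threshold_g: float) -> str:
    if pup.group in ("control", "sham"):
        return "sham"
    if pup.treatment == "msc":
        return "fgr_msc"
    is_fgr = pup.is_fgr if pup.is_fgr is not None else pup.birth_weight_g < threshold_g
    return "fgr_vehicle" if is_fgr else "non_fgr_vehicle"


def _ymaze_sequence(rng: np.random.Generator, n_entries: int, bias: float) -> list[int]:
    """Markov arm-entry sequence: with probability ``bias`` the pup enters the
    arm not visited in the last two entries (a perfect alternation step)."""
    seq = list(rng.permutation([1, 2, 3])[:2])
    while len(seq) < n_entries:
        prev2, prev1 = seq[-2], seq[-1]
        novel = ({1, 2, 3} - {prev2, prev1}).pop()
        if rng.random() < bias:
            seq.append(novel)
        else:
            options = [a for a in (1, 2, 3) if a != prev1]
            seq.append(int(rng.choice(options)))
    return seq


def gen_behavior(cohort: Sequence[PupRecord], config: SimConfig) -> list[BehaviorTrial]:
    """Behavioral outcomes with configured deficits in the FGR-vehicle arm.

    Deficits (scaled by ``beh_deficit``; 0 = null configuration): longer
    negative-geotaxis latency, shorter rota-rod fall latency, lower Y-maze
    alternation bias, weaker novel-object preference. The MSC arm recovers a
    fraction ``beh_msc_rescue`` of each deficit.
    """
    rng = _rng(config, "behavior")
    mu_c, sd_c = config.group_weight_params["control"]
    threshold = mu_c - 1.5 * sd_c
    trials: list[BehaviorTrial] = []
    for pup in cohort:
        arm = _behavior_arm(pup, threshold)
        d = {
            "sham": 0.0,
            "non_fgr_vehicle": 0.0,
            "fgr_vehicle": config.beh_deficit,
            "fgr_msc": config.beh_deficit * (1.0 - config.beh_msc_rescue),
        }[arm]
        # negative geotaxis: baseline ~10 s, deficit adds up to 25 s
        lat = max(0.5, rng.normal(10.0 + 25.0 * d, 3.0))
        trials.append(
            BehaviorTrial(pup.pup_id, "geotaxis", 7, arm,
                          {"latency_s": float(lat), "reacted": True, "fell": False})
        )
        # rota-rod: two trials, motor learning adds ~40 s; deficit removes up to 60 s
        t1 = float(np.clip(rng.normal(120.0 - 60.0 * d, 20.0), 1.0, 300.0))
        t2 = float(np.clip(t1 + rng.normal(40.0 * (1.0 - d), 15.0), 1.0, 300.0))
        trials.append(
            BehaviorTrial(pup.pup_id, "rotarod", 28, arm,
                          {"trial1_latency_s": t1, "trial2_latency_s": t2})
        )
        # Y-maze spontaneous alternation
        bias = float(np.clip(config.beh_alternation_bias - 0.35 * d, 0.0, 1.0))
        seq = _ymaze_sequence(rng, config.beh_n_ymaze_entries, bias)
        trials.append(BehaviorTrial(pup.pup_id, "ymaze", 28, arm, {"arm_sequence": seq}))
        # novel-object recognition: preference 0.70 eroded toward chance 0.5
        pref = 0.70 - 0.20 * d
        total = max(rng.normal(40.0, 8.0), 5.0)
        t_novel = float(np.clip(total * rng.normal(pref, 0.05), 0.0, total))
        trials.append(
            BehaviorTrial(pup.pup_id, "nor", 29, arm,
                          {"t_novel_s": t_novel, "t_familiar_s": float(total - t_novel)})
        )
    return trials


def simulate_study(config: SimConfig) -> dict:
    """Run every generator coherently and return all tables of one study.

    Returns a dict with keys ``cohort``, ``cohort_day5`` (distinct pups per
    day unless ``same_pups_both_days``), ``abundance_pnd4``,
    ``abundance_pnd5``, ``truth``, ``timecourse``, ``behavior``.
    """
    cohort = gen_cohort(config)
    if config.same_pups_both_days:
        cohort5 = None
    else:
        cohort5 = gen_cohort(config, stream="cohort_day5", prefix="d5_")
    a4, a5, truth = gen_proteome(cohort, config, cohort_day5=cohort5)
    # behavioral cohort: hypoperfusion pups split vehicle/MSC alternately
    beh_cohort = []
    k = 0
    for p in cohort:
        if p.group == "hypoperfusion":
            beh_cohort.append(replace(p, treatment="msc" if k % 2 else "vehicle"))
            k += 1
        else:
            beh_cohort.append(p)
    return {
        "cohort": cohort,
        "cohort_day5": cohort5 if cohort5 is not None else cohort,
        "abundance_pnd4": a4,
        "abundance_pnd5": a5,
        "truth": truth,
        "timecourse": gen_timecourse(config),
        "behavior": gen_behavior(beh_cohort, config),
    }
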