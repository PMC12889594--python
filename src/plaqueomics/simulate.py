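"""Synthetic paired plaque / non-plaque cohorts with known planted truth.

The generator emulates the statistical structure of a laser-capture
DIA proteomics study of single amyloid plaques:

* paired captures — each plaque sample has an adjacent non-plaque
  control sharing a capture-level intensity offset (so a paired test has
  genuine power advantage over an unpaired one);
* log2-scale intensities with left-censored (MNAR) missingness — the
  probability of detection follows a logistic curve in latent intensity,
  so low-abundance observations are preferentially missing;
* planted plaque-enriched proteins with temporal classes
  (early/constant, late accumulation, decline over time);
* an amyloid-beta tracer protein whose plaque signal strictly increases
  with age, plus optional "follower" proteins sharing its age profile
  (positives for the tracer-correlation screen);
* block-correlated protein groups (latent-factor model) for the
  co-expression network stages, optionally carrying the plaque effect so
  module–trait analysis has a planted positive;
* contaminant-style identifiers to exercise the QC filter.

Every random draw flows from the single ``seed`` through one
``numpy.random.Generator``, so identical configs reproduce the matrix
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import IntensityMatrix, PLAQUE, NONPLAQUE
from .ranking import DatasetRanking, ranking_from_scores

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "generate_cohort",
    "generate_rank_studies",
    "score_dap_recovery",
    "score_temporal_recovery",
    "write_truth",
    "write_config",
]

EARLY = "early_constant"
LATE = "late"
DECLINE = "decline"


@dataclass
class CohortConfig:
    """Parameters of the synthetic paired-capture cohort.

    Defaults mirror the profiled study design: three ages (3, 8, 14
    months), ~20 replicate pairs per age, ~2,000 quantified protein
    groups on a log2 scale, 5% plaque-enriched proteins at a 2-fold-log2
    effect, logistic left-censoring, and five correlated 20-protein
    blocks of which one is plaque-linked.
    """

    n_proteins: int = 2000
    n_pairs_per_age: int = 20
    ages: tuple = (3, 8, 14)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    pair_offset_sd: float | None = None  # default: 0.5 * baseline_sd
    effect_size: float = 2.0
    frac_dap: float = 0.05
    frac_late: float = 0.13
    frac_decline: float = 0.015
    missing_midpoint: float = 17.0
    missing_slope: float = 1.0
    n_blocks: int = 5
    block_size: int = 20
    block_rho: float = 0.8
    plaque_linked_blocks: int = 1
    frac_contaminant: float = 0.01
    n_tracer_followers: int = 10
    tracer_id: str = "ABETA_TRACER"
    model: str = "5xFAD"
    seed: int = 0

    def __post_init__(self) -> None:
        self.ages = tuple(self.ages)
        if self.pair_offset_sd is None:
            self.pair_offset_sd = 0.5 * self.baseline_sd
        numeric = [
            self.baseline_mean, self.baseline_sd, self.noise_sd,
            self.pair_offset_sd, self.effect_size, self.frac_dap,
            self.frac_late, self.frac_decline, self.missing_slope,
            self.block_rho, self.frac_contaminant,
        ]
        if any(not math.isfinite(v) for v in numeric):
            raise ValueError("non-finite config value")
        if math.isnan(self.missing_midpoint) or self.missing_midpoint == math.inf:
            raise ValueError("missing_midpoint must be finite or -inf")
        if not 0 <= self.frac_dap <= 1 or self.frac_dap + self.frac_contaminant > 1:
            raise ValueError("frac_dap + frac_contaminant must lie in [0, 1]")
        if self.frac_late + self.frac_decline > 1:
            raise ValueError("frac_late + frac_decline must be <= 1")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.missing_slope < 0:
            raise ValueError("missing_slope must be >= 0")
        if self.n_blocks * self.block_size > self.n_proteins:
            raise ValueError("n_blocks * block_size exceeds n_proteins")
        if not 0 <= self.plaque_linked_blocks <= self.n_blocks:
            raise ValueError("plaque_linked_blocks must be <= n_blocks")
        if len(self.ages) < 2 and (self.frac_late > 0 or self.frac_decline > 0):
            raise ValueError("late/decline trajectories need at least two ages")


@dataclass
class PlantedTruth:
    """Generator-side ground truth for scoring downstream recovery."""

    #: per-age true plaque-minus-control log2 fold change, one row per
    #: protein carrying any planted effect (columns are the ages)
    effects: pd.DataFrame
    temporal_class: dict  # protein -> early_constant | late | decline
    block_assignment: dict  # protein -> block index
    tracer_profile: dict  # age -> true plaque-sample tracer mean
    contaminants: set

    @property
    def dap_ids(self) -> set:
        return set(self.effects.index)

    def true_logfc(self, protein: str, age) -> float:
        if protein in self.effects.index:
            return float(self.effects.loc[protein, age])
        return 0.0


def _class_multipliers(cls: str, n_ages: int) -> np.ndarray:
    """Per-age effect multipliers: early/constant is flat, late rises
    from zero to full, decline starts full and falls to zero."""
    if cls == EARLY or n_ages == 1:
        return np.ones(n_ages)
    if cls == LATE:
        # still near-absent at intermediate ages, full at the last age
        ramp = np.full(n_ages, 0.1)
        ramp[0], ramp[-1] = 0.0, 1.0
    elif cls == DECLINE:
        ramp = np.full(n_ages, 0.5)
        ramp[0], ramp[-1] = 1.0, 0.0
    else:
        raise ValueError(cls)
    return ramp


def _tracer_effects(n_ages: int) -> np.ndarray:
    """Plaque enrichment of the tracer, strictly increasing with age."""
    if n_ages == 1:
        return np.array([2.5])
    return 1.0 + 3.0 * np.arange(n_ages) / (n_ages - 1)


def generate_cohort(config: CohortConfig) -> tuple[IntensityMatrix, PlantedTruth]:
    """Simulate a paired plaque/control cohort with planted structure."""
    rng = np.random.default_rng(config.seed)
    ages = sorted(config.ages)
    n_ages = len(ages)
    n_pairs_total = config.n_pairs_per_age * n_ages
    n_samples = 2 * n_pairs_total

    # --- protein identifiers -----------------------------------------
    n_cont = int(round(config.frac_contaminant * config.n_proteins))
    n_regular = config.n_proteins - n_cont - 1  # minus tracer
    if n_regular < 0:
        raise ValueError("n_proteins too small for contaminants plus tracer")
    regular_ids = [f"P{i:05d}" for i in range(n_regular)]
    cont_ids = [f"CON__KRT{i:03d}" for i in range(n_cont)]
    protein_ids = regular_ids + cont_ids + [config.tracer_id]

    # --- role assignment (followers, blocks, DAPs; mutually disjoint) --
    pool = np.array(regular_ids)
    rng.shuffle(pool)
    cursor = 0
    followers = list(pool[cursor:cursor + config.n_tracer_followers])
    cursor += len(followers)
    block_assignment: dict = {}
    for b in range(config.n_blocks):
        for pid in pool[cursor:cursor + config.block_size]:
            block_assignment[pid] = b
        cursor += config.block_size
    n_dap = int(round(config.frac_dap * config.n_proteins))
    dap_pool = pool[cursor:cursor + n_dap]
    if len(dap_pool) < n_dap:
        raise ValueError("not enough proteins for the requested DAP fraction")
    n_late = int(round(config.frac_late * n_dap))
    n_decline = int(round(config.frac_decline * n_dap))
    temporal_class = {}
    for i, pid in enumerate(dap_pool):
        if i < n_late:
            temporal_class[pid] = LATE
        elif i < n_late + n_decline:
            temporal_class[pid] = DECLINE
        else:
            temporal_class[pid] = EARLY

    # --- samples ------------------------------------------------------
    sample_ids, meta_rows = [], []
    age_idx_of_sample, is_plaque, pair_index = [], [], []
    pair_counter = 0
    for ai, age in enumerate(ages):
        for p in range(config.n_pairs_per_age):
            pair = f"{config.model}_{age}m_pr{p:02d}"
            for region, suffix in ((PLAQUE, "plq"), (NONPLAQUE, "ctl")):
                sid = f"{pair}_{suffix}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, model=config.model, age_months=age,
                         region=region, pair_id=pair, replicate=p)
                )
                age_idx_of_sample.append(ai)
                is_plaque.append(region == PLAQUE)
                pair_index.append(pair_counter)
            pair_counter += 1
    age_idx_of_sample = np.array(age_idx_of_sample)
    is_plaque = np.array(is_plaque)
    pair_index = np.array(pair_index)

    # --- latent intensities -------------------------------------------
    n_prot = len(protein_ids)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_prot)
    tracer_row = n_prot - 1
    baselines[tracer_row] = config.baseline_mean + 2.0  # abundant positive control

    pair_offsets = rng.normal(0.0, config.pair_offset_sd, n_pairs_total)
    sample_offsets = pair_offsets[pair_index]

    block_factors = rng.standard_normal((max(config.n_blocks, 1), n_samples))
    eps = rng.standard_normal((n_prot, n_samples))

    noise = config.noise_sd * eps
    if config.n_blocks and config.block_rho > 0:
        sq_rho = math.sqrt(config.block_rho)
        sq_res = math.sqrt(1.0 - config.block_rho)
        row_of = {pid: i for i, pid in enumerate(protein_ids)}
        for pid, b in block_assignment.items():
            r = row_of[pid]
            noise[r] = config.noise_sd * (sq_rho * block_factors[b] + sq_res * eps[r])

    # planted effects: rows = proteins with any effect, cols = ages
    tracer_eff = _tracer_effects(n_ages)
    effect_rows: dict = {}
    for pid, cls in temporal_class.items():
        effect_rows[pid] = config.effect_size * _class_multipliers(cls, n_ages)
    for b in range(config.plaque_linked_blocks):
        for pid, blk in block_assignment.items():
            if blk == b:
                effect_rows[pid] = config.effect_size * np.ones(n_ages)
                temporal_class[pid] = EARLY
    for pid in followers:
        effect_rows[pid] = tracer_eff.copy()
        temporal_class[pid] = _rule_class(tracer_eff)
    effect_rows[config.tracer_id] = tracer_eff.copy()
    temporal_class[config.tracer_id] = _rule_class(tracer_eff)

    latent = baselines[:, None] + sample_offsets[None, :] + noise
    row_of = {pid: i for i, pid in enumerate(protein_ids)}
    for pid, eff in effect_rows.items():
        latent[row_of[pid], is_plaque] += eff[age_idx_of_sample[is_plaque]]

    # --- MNAR detection ----------------------------------------------
    if config.missing_midpoint == -math.inf:
        detect_p = np.ones_like(latent)
    else:
        detect_p = expit((latent - config.missing_midpoint) * config.missing_slope)
    detected = rng.random(latent.shape) < detect_p
    values = np.where(detected, latent, np.nan)

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        pd.DataFrame(meta_rows).set_index("sample_id"),
    )
    effects = pd.DataFrame(
        {age: [effect_rows[p][ai] for p in effect_rows] for ai, age in enumerate(ages)},
        index=list(effect_rows),
    )
    truth = PlantedTruth(
        effects=effects,
        temporal_class=temporal_class,
        block_assignment=block_assignment,
        tracer_profile={age: float(baselines[tracer_row] + tracer_eff[ai])
                        for ai, age in enumerate(ages)},
        contaminants=set(cont_ids),
    )
    return matrix, truth


def _rule_class(effects: np.ndarray, tau: float = 0.5) -> str:
    """Temporal class implied by a noiseless effect profile (same rule
    as the temporal stage: deltas relative to the first age)."""
    if len(effects) < 3:
        return EARLY
    d_mid = effects[1] - effects[0]
    d_last = effects[-1] - effects[0]
    if d_last <= -tau:
        return DECLINE
    if d_last >= tau and d_mid < tau:
        return LATE
    return EARLY


# ----------------------------------------------------------------------
# Multi-study ranking fixtures
# ----------------------------------------------------------------------


def generate_rank_studies(
    n_studies: int,
    n_proteins: int,
    n_core: int,
    noise_sd: float,
    seed: int,
    p_core_absent: float = 0.1,
    p_other_absent: float = 0.05,
) -> tuple[list[DatasetRanking], set]:
    """Simulate independent study rankings sharing a planted core.

    Core proteins draw half-normal scores with scale ``noise_sd`` (so at
    ``noise_sd = 0`` every core protein outranks every non-core protein
    in every study where it appears); non-core scores are Uniform(0,1).
    Each protein is randomly absent from a minority of studies to
    exercise the missing-dataset policy downstream.
    """
    if n_core <= 0:
        raise ValueError("n_core must be positive")
    if n_core > n_proteins or n_studies < 1:
        raise ValueError("need n_core <= n_proteins and n_studies >= 1")
    rng = np.random.default_rng(seed)
    ids = np.array([f"P{i:05d}" for i in range(n_proteins)])
    core = set(ids[:n_core])
    is_core = np.zeros(n_proteins, bool)
    is_core[:n_core] = True

    studies = []
    for s in range(n_studies):
        absent_p = np.where(is_core, p_core_absent, p_other_absent)
        present = rng.random(n_proteins) >= absent_p
        if n_studies == 1:
            present[:] = True
        scores = rng.random(n_proteins)
        scores[is_core] = np.abs(rng.normal(0.0, 1.0, n_core)) * noise_sd
        sel = pd.Series(scores[present], index=ids[present])
        studies.append(ranking_from_scores(f"study{s + 1}", sel, ascending=True))
    return studies, core


# ----------------------------------------------------------------------
# Recovery scoring against the planted truth
# ----------------------------------------------------------------------


def score_dap_recovery(
    dap_table: pd.DataFrame, truth: PlantedTruth, full_effect: float
) -> dict:
    """Sensitivity and empirical FDR of DAP calls against planted truth.

    A (protein, age) combination counts as a positive target when its
    planted |log2FC| is at least ``full_effect``, and as a null when the
    planted effect is exactly zero; partial-effect combinations (e.g. a
    late-accumulating protein at an intermediate age) are excluded from
    both denominators.
    """
    n_true = n_hit = n_called = n_false = 0
    for _, row in dap_table.iterrows():
        e = abs(truth.true_logfc(row["protein_id"], row["age_months"]))
        if e >= full_effect:
            n_true += 1
            if row["is_dap"]:
                n_hit += 1
        if row["is_dap"]:
            n_called += 1
            if e == 0.0:
                n_false += 1
    return {
        "sensitivity": n_hit / n_true if n_true else float("nan"),
        "fdr": n_false / n_called if n_called else 0.0,
        "n_true": n_true,
        "n_called": n_called,
    }


def score_temporal_recovery(assignments: Mapping[str, str], truth: PlantedTruth) -> float:
    """Fraction of planted trajectory classes recovered (proteins
    present in both the assignment and the truth)."""
    common = [p for p in assignments if p in truth.temporal_class]
    if not common:
        return float("nan")
    hits = sum(assignments[p] == truth.temporal_class[p] for p in common)
    return hits / len(common)


# ----------------------------------------------------------------------
# Plain-text export of truth and config
# ----------------------------------------------------------------------


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Tab-separated truth table: one row per protein with any role."""
    proteins = sorted(
        set(truth.effects.index)
        | set(truth.block_assignment)
        | truth.contaminants
    )
    ages = list(truth.effects.columns)
    with open(path, "w") as fh:
        cols = ["protein_id", "temporal_class", "block"] + [f"lfc_{a}m" for a in ages]
        fh.write("\t".join(cols) + "\t" + "is_contaminant\n")
        for pid in proteins:
            cls = truth.temporal_class.get(pid, "null")
            blk = truth.block_assignment.get(pid, "")
            lfcs = [f"{truth.true_logfc(pid, a):.6g}" for a in ages]
            fh.write(
                "\t".join([pid, cls, str(blk)] + lfcs)
                + f"\t{int(pid in truth.contaminants)}\n"
            )


def write_config(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in asdict(config).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k}={v}\n")
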