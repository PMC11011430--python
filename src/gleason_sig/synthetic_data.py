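"""Synthetic graded-cohort generator.

Emulates the statistical structure the downstream analysis relies on:
non-negative continuous FPKM_UQ-like expression with log-scale Gaussian
noise, a subset of "planted" genes whose log2 expression trends linearly with
the Gleason grade group (normal tissue sits at grade 0 on the same latent
axis, matching the observed normal -> low-grade -> high-grade expression
trajectory), and blocks of genes sharing a latent factor, which creates the
inter-gene redundancy that the decorrelation-network candidate filter is
designed to remove.

Log2 expression of gene g in sample s:

    log2 x_gs = baseline + effect_g * grade_s + loading_g * f_{b(g),s} + eps_gs

with eps ~ Normal(0, noise_sd); expression is 2 ** log2x, so marginal
expression is log-normal.  Clinical covariates (age, ethnicity, pathologic
T/N, clinical M) are drawn per grade group from the published cohort
frequencies in :mod:`gleason_sig.table1`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import table1
from .expression_io import ExpressionMatrix

#: Gleason pattern pairs consistent with each grade group
_PATTERNS = {1: [(3, 3)], 2: [(3, 4)], 3: [(4, 3)], 4: [(4, 4)], 5: [(4, 5), (5, 4), (5, 5)]}


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the published cohort: 52 normals and 45/146/101/64/141
    tumors across grade groups 1-5.  ``effect_size`` is the per-grade-group
    increment of planted genes on the log2 scale; ``noise_sd`` is the log2
    residual standard deviation (1.0 is a typical dispersion for bulk FPKM);
    ``n_blocks`` blocks of ``block_size`` genes share a latent factor with
    loading ``rho`` and no grade effect, so redundancy is separable from
    signal.
    """

    n_per_group: tuple[int, ...] = (52, 45, 146, 101, 64, 141)  # normal, groups 1-5
    n_genes: int = 2000
    n_planted: int = 40
    effect_size: float = 0.35
    n_blocks: int = 5
    block_size: int = 10
    rho: float = 0.8
    noise_sd: float = 1.0
    baseline_log2_mean: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 6:
            raise ValueError("n_per_group must list normal plus grade groups 1-5")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("all group counts must be positive")
        if self.n_planted + self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("planted plus block genes exceed n_genes")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be non-negative")


@dataclass
class GroundTruth:
    """Which genes carry planted structure, and how strongly."""

    planted_sign: dict[str, int]
    block_of: dict[str, int]
    target_r: pd.Series = field(repr=False)

    @property
    def planted_gene_ids(self) -> list[str]:
        return list(self.planted_sign)

    def __post_init__(self) -> None:
        if set(self.planted_sign) & set(self.block_of):
            raise ValueError("planted and block gene sets must be disjoint")


def sample_clinical(grade_group: int, rng: np.random.Generator) -> dict:
    """Draw one tumor sample's clinical fields from the published frequencies.

    Frequencies are conditional on the field being observed, so e.g. for
    grade group 5 P(T3b) = 86/140.
    """
    if grade_group not in table1.GROUPS:
        raise ValueError(f"grade_group must be 1-5, got {grade_group}")
    mean, sd = table1.AGE[grade_group]
    out = {"age_years": rng.normal(mean, sd)}
    for var, counts in table1.CATEGORICAL.items():
        col = counts[grade_group]
        p = col.to_numpy(float)
        out[var] = col.index[rng.choice(len(col), p=p / p.sum())]
    return out


def _sample_normal_clinical(rng: np.random.Generator) -> dict:
    mean, sd = table1.AGE["normal"]
    col = table1.ETHNICITY["normal"]
    p = col.to_numpy(float)
    return {
        "age_years": rng.normal(mean, sd),
        "ethnicity": col.index[rng.choice(len(col), p=p / p.sum())],
        "path_t": pd.NA,
        "path_n": pd.NA,
        "clin_m": pd.NA,
    }


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate (expression, annotations, ground truth); bit-identical per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_normal, *n_tumor = config.n_per_group
    grades = np.concatenate([np.zeros(n_normal, int)] + [np.full(n, g) for g, n in enumerate(n_tumor, start=1)])
    n_samples = grades.size

    gene_ids = [f"ENSG{i:011d}" for i in range(config.n_genes)]
    n_block_genes = config.n_blocks * config.block_size

    effect = np.zeros(config.n_genes)
    signs = np.where(np.arange(config.n_planted) % 2 == 0, 1, -1)
    effect[: config.n_planted] = signs * config.effect_size

    loading = np.zeros(config.n_genes)
    block_index = np.full(config.n_genes, -1)
    start = config.n_planted
    for b in range(config.n_blocks):
        sl = slice(start + b * config.block_size, start + (b + 1) * config.block_size)
        loading[sl] = config.rho
        block_index[sl] = b

    log2x = config.baseline_log2_mean + effect[:, None] * grades[None, :]
    if config.n_blocks:
        factors = rng.standard_normal((config.n_blocks, n_samples))
        block_genes = block_index >= 0
        log2x[block_genes] += loading[block_genes, None] * factors[block_index[block_genes]]
    log2x += rng.standard_normal((config.n_genes, n_samples)) * config.noise_sd

    # tumors first per patient numbering; normals are paired to the first
    # n_normal patients (same patient_id, distinct sample)
    n_patients = sum(n_tumor)
    tumor_ids = [f"SYN-{i:04d}-T" for i in range(n_patients)]
    normal_ids = [f"SYN-{i:04d}-N" for i in range(n_normal)]
    sample_ids = normal_ids + tumor_ids

    records = []
    for i in range(n_normal):
        records.append(
            {
                "sample_id": normal_ids[i],
                "patient_id": f"SYNP-{i:04d}",
                "tissue_type": "normal",
                "gleason_primary": pd.NA,
                "gleason_secondary": pd.NA,
                "grade_group": pd.NA,
                **_sample_normal_clinical(rng),
            }
        )
    patient = 0
    for g, n in enumerate(n_tumor, start=1):
        for _ in range(n):
            prim, sec = _PATTERNS[g][rng.integers(len(_PATTERNS[g]))]
            records.append(
                {
                    "sample_id": tumor_ids[patient],
                    "patient_id": f"SYNP-{patient:04d}",
                    "tissue_type": "tumor",
                    "gleason_primary": prim,
                    "gleason_secondary": sec,
                    "grade_group": g,
                    **sample_clinical(g, rng),
                }
            )
            patient += 1
    ann = pd.DataFrame(records)
    for col in ("gleason_primary", "gleason_secondary", "grade_group"):
        ann[col] = ann[col].astype("Int64")
    ann["class3"] = "normal"
    ann.loc[ann["grade_group"].isin([1, 2, 3]), "class3"] = "low"
    ann.loc[ann["grade_group"].isin([4, 5]), "class3"] = "high"

    expr = ExpressionMatrix(gene_ids, sample_ids, np.power(2.0, log2x))

    var_grade = np.var(grades)
    denom = np.sqrt(effect**2 * var_grade + loading**2 + config.noise_sd**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        target = np.where(denom > 0, effect * np.sqrt(var_grade) / denom, np.sign(effect))
    truth = GroundTruth(
        planted_sign={gene_ids[i]: int(signs[i]) for i in range(config.n_planted)},
        block_of={gene_ids[i]: int(block_index[i]) for i in np.flatnonzero(block_index >= 0)},
        target_r=pd.Series(target, index=gene_ids, name="target_r"),
    )
    return expr, ann, truth
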