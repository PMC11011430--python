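"""Reproducible end-to-end simulation studies.

Two canned experiments exercise the whole pipeline under controlled
conditions: recovery of a planted eight-gene signature by the two-route
combinatorial search, and calibration under the global null.  Problem sizes
are reduced relative to a full cohort analysis (about 600 samples by 500
genes, candidate pools of 12 and 40) so a study of ten replicates completes
in minutes; the planted structure is what the method consumes, so recovery
behaviour is informative at this scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._knn import KNNConfig
from .classification_eval import evaluate_gene_set
from .grade_correlation import correlate_with_grade
from .signature_selection import SelectionConfig, evaluate_combination, run_selection_pipeline
from .synthetic_data import SyntheticConfig, generate_cohort

#: cohort proportions of the published study scaled to ~600 samples
RECOVERY_N_PER_GROUP = (57, 49, 160, 110, 70, 154)


def recovery_config(seed: int) -> SyntheticConfig:
    """Planted-signature study conditions: 8 planted genes at effect 0.5."""
    return SyntheticConfig(
        n_per_group=RECOVERY_N_PER_GROUP,
        n_genes=500,
        n_planted=8,
        effect_size=0.5,
        n_blocks=4,
        block_size=8,
        rho=0.8,
        noise_sd=1.0,
        seed=seed,
    )


def reduced_selection_config(seed: int) -> SelectionConfig:
    """Selection protocol with candidate pools capped at 12/40 for speed."""
    return SelectionConfig(
        top_k_primary=12,
        top_k_network=40,
        max_network_candidates=12,
        degree_min=10,
        knn=KNNConfig(seed=seed),
    )


def planted_recovery_experiment(n_seeds: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Run the full selection pipeline on replicate planted cohorts.

    For each replicate: simulate a cohort, rank genes by grade correlation,
    run the two-route combinatorial search, count how many of the 8 planted
    genes the final signature recovers, and measure the signature's
    accuracy and one-vs-rest AUROCs on an independently simulated held-out
    cohort of the same conditions.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        expr, ann, truth = generate_cohort(recovery_config(seed))
        records = correlate_with_grade(expr, ann)
        report = run_selection_pipeline(expr, ann, records, reduced_selection_config(seed))
        planted = set(truth.planted_gene_ids)

        held_expr, held_ann, _ = generate_cohort(recovery_config(seed + 20011))
        held = evaluate_gene_set(report.final_signature, held_expr, held_ann, KNNConfig(seed=seed))
        rows.append(
            {
                "seed": seed,
                "signature_size": len(report.final_signature),
                "n_recovered": len(planted & set(report.final_signature)),
                "train_accuracy": report.final_accuracy,
                "heldout_accuracy": held["accuracy"],
                "heldout_auroc_normal": held["auroc"]["normal"],
                "heldout_auroc_low": held["auroc"]["low"],
                "heldout_auroc_high": held["auroc"]["high"],
            }
        )
    return pd.DataFrame(rows)


def null_calibration_experiment(n_seeds: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Discovery rates under the global null.

    For each replicate: a cohort with no planted grade effects (correlated
    blocks kept) gives the fraction of genes called at q < 0.05 in the
    grade-correlation ranking, and a kNN run on randomly permuted, balanced
    class labels gives the chance-level accuracy.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SyntheticConfig(
            n_per_group=RECOVERY_N_PER_GROUP,
            n_genes=300,
            n_planted=0,
            n_blocks=4,
            block_size=8,
            seed=seed,
        )
        expr, ann, _ = generate_cohort(cfg)
        records = correlate_with_grade(expr, ann)
        q_frac = float((records["q"] < 0.05).mean())

        rng = np.random.default_rng(seed + 50021)
        n = expr.n_samples
        labels = np.array((["normal", "low", "high"] * (n // 3 + 1))[:n])
        rng.shuffle(labels)
        ann_null = ann.copy()
        ann_null["class3"] = labels
        genes = expr.gene_ids[:8]
        result = evaluate_combination(genes, expr, labels.tolist(), KNNConfig(seed=seed))
        rows.append({"seed": seed, "q_lt_05_fraction": q_frac, "permuted_accuracy": result.accuracy})
    return pd.DataFrame(rows)
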