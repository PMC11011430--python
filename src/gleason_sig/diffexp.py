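"""Tumor-vs-normal differential expression.

Per gene: unpaired Welch t-test (a pooled-variance option exists), log2 fold
change of raw group means with a small pseudocount, and Benjamini-Hochberg
adjusted q-values over all tested genes.  Genes with zero variance in both
groups are retained with p = 1 and a degeneracy flag so gene counts stay
stable across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

#: pseudocount added to group means before the fold-change ratio
PSEUDOCOUNT = 1e-3

RECORD_COLUMNS = ["gene_id", "mean_tumor", "mean_normal", "log2_fc", "t_stat", "p", "q", "zero_variance"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    tissue_type: pd.Series | np.ndarray,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal statistics, one row per gene.

    ``tissue_type`` gives 'tumor'/'normal' per sample, aligned with the
    expression columns.  Welch's unequal-variance t-test is the default;
    ``equal_var=True`` restores the pooled-variance test.
    """
    labels = np.asarray(tissue_type)
    if labels.shape[0] != expr.n_samples:
        raise ValueError("tissue_type length must match the number of samples")
    tumor = expr.values[:, labels == "tumor"]
    normal = expr.values[:, labels == "normal"]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")

    mean_t = tumor.mean(axis=1)
    mean_n = normal.mean(axis=1)
    log2_fc = np.log2((mean_t + PSEUDOCOUNT) / (mean_n + PSEUDOCOUNT))

    zero_var = (tumor.var(axis=1) == 0) & (normal.var(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=equal_var)
    t_stat = np.where(zero_var, 0.0, t_stat)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)

    records = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p": p,
            "q": bh_adjust(p),
            "zero_variance": zero_var,
        }
    )
    return records


def count_regulated(
    records: pd.DataFrame, fc_threshold: float = 2.0, q_threshold: float = 0.05
) -> tuple[int, int]:
    """(n_down, n_up) at a fold-change and FDR threshold.

    Up: q < q_threshold and fold change > fc_threshold; down symmetric with
    fold change < 1/fc_threshold.
    """
    if len(records) == 0:
        return (0, 0)
    sig = records["q"] < q_threshold
    log2_thr = np.log2(fc_threshold)
    n_up = int((sig & (records["log2_fc"] > log2_thr)).sum())
    n_down = int((sig & (records["log2_fc"] < -log2_thr)).sum())
    return (n_down, n_up)


def write_diffexp(records: pd.DataFrame, path, volcano_path=None) -> None:
    """Write the differential-expression TSV and a volcano-ready companion."""
    records.to_csv(path, sep="\t", index=False)
    if volcano_path is not None:
        volcano = pd.DataFrame(
            {
                "gene_id": records["gene_id"],
                "log2_fc": records["log2_fc"],
                "neg_log10_q": -np.log10(records["q"].clip(lower=np.finfo(float).tiny)),
            }
        )
        volcano.to_csv(volcano_path, sep="\t", index=False)
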