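"""Ranking genes by Pearson correlation with the Gleason grade group.

The grade group is treated as an equally spaced integer score 1-5 (0 for
normal tissue when normals are included).  Correlation is computed on raw
FPKM_UQ values by default; a ``log2p1`` transform option is available since
raw-scale Pearson is sensitive to the log-normal tail of expression data.
Genes are ranked by |r| descending, so strong negative correlates rank as
high as strong positive ones; a signed ordering is also exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .expression_io import ExpressionMatrix

RECORD_COLUMNS = ["gene_id", "pearson_r", "p", "q", "rank", "degenerate"]


def _pearson_vs_score(values: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row Pearson r and two-sided p against one score vector."""
    n = score.size
    xc = values - values.mean(axis=1, keepdims=True)
    yc = score - score.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    degenerate = (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(np.where(degenerate, 0.0, r), -1.0, 1.0)
    # two-sided p from the exact t distribution of r under the null
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p, degenerate


def correlate_with_grade(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    include_normals: bool = False,
    transform: str = "raw",
    rank_by: str = "abs",
) -> pd.DataFrame:
    """Per-gene Pearson correlation with grade group, BH-adjusted, ranked.

    Tumor samples only by default (normals carry no grade group);
    ``include_normals=True`` codes normal tissue as grade 0.  Constant genes
    get r = 0, p = 1 and a ``degenerate`` flag.  ``rank_by`` is ``"abs"``
    (default) or ``"signed"``.
    """
    ann = annotations.set_index("sample_id").loc[expr.sample_ids]
    if include_normals:
        score = ann["grade_group"].fillna(0).to_numpy(float)
        mask = np.ones(expr.n_samples, bool)
    else:
        mask = (ann["tissue_type"] == "tumor").to_numpy()
        score = ann.loc[mask.tolist(), "grade_group"].to_numpy(float)
    if np.isnan(score).any():
        raise ValueError("tumor samples without grade_group")
    if score.size < 3:
        raise ValueError("need at least 3 samples for correlation")

    values = expr.values[:, mask]
    if transform == "log2p1":
        values = np.log2(values + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")

    r, p, degenerate = _pearson_vs_score(values, score)
    records = pd.DataFrame(
        {"gene_id": expr.gene_ids, "pearson_r": r, "p": p, "q": bh_adjust(p), "degenerate": degenerate}
    )
    key = -np.abs(records["pearson_r"]) if rank_by == "abs" else -records["pearson_r"]
    if rank_by not in ("abs", "signed"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    order = np.lexsort((records["gene_id"].to_numpy(), key.to_numpy()))
    records = records.iloc[order].reset_index(drop=True)
    records["rank"] = np.arange(1, len(records) + 1)
    return records[RECORD_COLUMNS]


def top_k(records: pd.DataFrame, k: int) -> list[str]:
    """First k gene IDs by rank (ties already broken lexicographically)."""
    if k > len(records):
        raise ValueError(f"k={k} exceeds {len(records)} ranked genes")
    if k < 0:
        raise ValueError("k must be non-negative")
    return records.sort_values("rank")["gene_id"].head(k).tolist()


def write_correlation(records: pd.DataFrame, path) -> None:
    """TSV mirroring the published appendix: gene, Pearson R, adjusted p."""
    records[["gene_id", "pearson_r", "q"]].to_csv(path, sep="\t", index=False)


def anova_by_group(expr: ExpressionMatrix, annotations: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """One-way ANOVA of expression across grade groups (normals as group 0)."""
    ann = annotations.set_index("sample_id").loc[expr.sample_ids]
    score = ann["grade_group"].fillna(0).to_numpy(float)
    sub = expr.subset_genes(genes)
    rows = []
    for gene, vals in zip(sub.gene_ids, sub.values):
        groups = [vals[score == g] for g in np.unique(score)]
        f, p = stats.f_oneway(*groups)
        rows.append({"gene_id": gene, "f_stat": float(f), "p": float(p)})
    return pd.DataFrame(rows)
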