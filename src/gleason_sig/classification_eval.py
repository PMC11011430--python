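"""Evaluation of gene sets as three-class predictors.

Covers the probability-output kNN, one-vs-rest ROC/AUROC per class
(normal / low-Gleason / high-Gleason), side-by-side comparison of named gene
sets under an identical split, and a PCA-silhouette separation score that
quantifies how well a gene subset separates the classes in its first two
principal axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve, silhouette_score

from ._knn import (
    CLASS_ORDER,
    KNNConfig,
    canonical_order,
    encode_labels,
    fit_transform,
    pairwise_euclidean,
    vote_probabilities,
)
from .expression_io import ExpressionMatrix
from .signature_selection import evaluate_combination

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    """One-vs-rest ROC curve and area for one class."""

    class_name: str
    thresholds: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    auroc: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("ROC curve must be monotone non-decreasing")
        if not 0 <= self.auroc <= 1:
            raise ValueError("auroc must be in [0, 1]")


def knn_predict_proba(
    train_values: np.ndarray,
    train_labels: Sequence[str],
    test_values: np.ndarray,
    config: KNNConfig | None = None,
) -> pd.DataFrame:
    """Class-probability triples for test samples (rows sum to 1).

    Inputs are samples x genes on the raw expression scale; the configured
    transform is fit on the training rows.  The probability of a class is
    the fraction of the k nearest training neighbors with that label.
    Training samples are reordered canonically first, so the output does not
    depend on their input order even under exact distance ties.
    """
    config = config or KNNConfig()
    y = encode_labels(train_labels)
    if len(y) < config.k_neighbors:
        raise ValueError(f"fewer training samples ({len(y)}) than k={config.k_neighbors}")
    x_train, x_test = fit_transform(np.asarray(train_values, float), np.asarray(test_values, float), config.transform)
    order = canonical_order(x_train, y)
    dist = pairwise_euclidean(x_test, x_train[order])
    proba, _ = vote_probabilities(dist, y[order], config.k_neighbors)
    return pd.DataFrame(proba, columns=CLASS_ORDER)


def roc_auc_ovr(
    true_labels: Sequence[str], proba: pd.DataFrame | np.ndarray
) -> dict[str, ROCResult | None]:
    """One-vs-rest ROC and trapezoidal AUROC for each class.

    Score ties are handled by the ROC convention equivalent to midranks, so
    the area equals the normalized Mann-Whitney U statistic.  A class absent
    from the truth is reported as None.
    """
    proba = np.asarray(proba, float)
    labels = np.asarray(true_labels)
    out: dict[str, ROCResult | None] = {}
    for i, name in enumerate(CLASS_ORDER):
        truth = labels == name
        if truth.all() or not truth.any():
            logger.warning("class %s absent from truth (or is the only class); no ROC", name)
            out[name] = None
            continue
        fpr, tpr, thr = roc_curve(truth, proba[:, i])
        out[name] = ROCResult(name, thr, tpr, fpr, auroc=float(np.trapezoid(tpr, fpr)))
    return out


def evaluate_gene_set(
    genes: Sequence[str],
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: KNNConfig | None = None,
) -> dict:
    """Accuracy and per-class AUROC of one gene set on the validation half."""
    config = config or KNNConfig()
    ann = annotations.set_index("sample_id").loc[expr.sample_ids]
    result = evaluate_combination(tuple(genes), expr, ann["class3"].tolist(), config, with_auroc=True)
    return {"accuracy": result.accuracy, "auroc": result.per_class_auroc}


def compare_gene_sets(
    sets: Mapping[str, Sequence[str]],
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: KNNConfig | None = None,
) -> pd.DataFrame:
    """Evaluate named gene sets under the identical split and seed.

    Genes missing from the matrix are dropped with a warning; a fully
    absent set is an error naming it.  Returns one row per set with global
    accuracy and the three one-vs-rest AUROCs.
    """
    config = config or KNNConfig()
    available = set(expr.gene_ids)
    rows = []
    for name, genes in sets.items():
        present = [g for g in genes if g in available]
        dropped = sorted(set(genes) - set(present))
        if not present:
            raise KeyError(f"gene set {name!r} has no genes in the expression matrix")
        if dropped:
            logger.warning("gene set %r: dropping %d absent genes %s", name, len(dropped), dropped[:5])
        res = evaluate_gene_set(present, expr, annotations, config)
        rows.append(
            {
                "set": name,
                "n_genes": len(present),
                "accuracy": res["accuracy"],
                **{f"auroc_{c}": res["auroc"][c] for c in CLASS_ORDER},
            }
        )
    return pd.DataFrame(rows)


def separation_score(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> float:
    """Silhouette score of the three classes on the first two principal axes.

    Expression of the chosen subset (all genes when None) is log2(x+1)
    transformed and per-gene z-scored before PCA.  Higher is better
    separated; around zero means the classes overlap.
    """
    sub = expr if genes is None else expr.subset_genes(list(genes))
    if sub.n_genes < 2:
        raise ValueError("need at least 2 genes for a 2-component projection")
    ann = annotations.set_index("sample_id").loc[sub.sample_ids]
    labels = encode_labels(ann["class3"].tolist())
    counts = np.bincount(labels, minlength=3)
    if (counts < 3).any():
        raise ValueError("need at least 3 samples per class")
    x = np.log2(sub.values.T + 1.0)
    sd = x.std(axis=0)
    x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    return float(silhouette_score(coords, labels))


def anova_signature(expr: ExpressionMatrix, annotations: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """One-way ANOVA of each signature gene across grade groups."""
    from .grade_correlation import anova_by_group

    return anova_by_group(expr, annotations, list(genes))
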