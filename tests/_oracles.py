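"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops over definitions, no shared code with the
package.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the literal step-up recipe."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def mann_whitney_auc(scores, positive):
    """AUROC as the normalized pairwise-comparison count (ties count 1/2)."""
    scores = np.asarray(scores, float)
    positive = np.asarray(positive, bool)
    pos = scores[positive]
    neg = scores[~positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_chi2(counts):
    """Pearson chi-squared statistic and dof from margins, by definition."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, dof


def pearson_r(x, y):
    """Pearson correlation straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def oneway_f(groups):
    """One-way ANOVA F statistic from the sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def knn_proba_bruteforce(x_train, y_codes, x_test, k, n_classes=3):
    """Vote fractions by an all-pairs distance scan and explicit sort."""
    proba = np.zeros((len(x_test), n_classes))
    for t, xt in enumerate(x_test):
        d = np.sqrt(((x_train - xt) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        for i in nearest:
            proba[t, y_codes[i]] += 1.0 / k
    return proba
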