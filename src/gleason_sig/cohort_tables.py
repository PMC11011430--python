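"""Cohort composition summaries and chi-squared association tests.

Reproduces demographics-and-staging style tables: per grade group sample
counts, age mean +/- sd, and category counts with percentages computed within
each group over the non-missing values of each variable (clinical stage is
not recorded for every patient, so variable totals may be smaller than group
sizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORICAL_VARIABLES = ["ethnicity", "path_t", "path_n", "clin_m"]
_ADVANCED_T = ["T3a", "T3b", "T4"]


@dataclass
class ContingencyTable:
    """Category-by-grade-group count table."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class CohortSummary:
    """Per-group cohort summary: n, age, and per-variable counts/percentages."""

    n: pd.Series
    age_mean: pd.Series
    age_sd: pd.Series
    counts: pd.DataFrame = field(repr=False)    # (variable, category) x group
    percents: pd.DataFrame = field(repr=False)  # same shape, % within group, 1 decimal

    def percent(self, group, variable: str, category: str) -> float:
        return float(self.percents.loc[(variable, category), group])

    def count(self, group, variable: str, category: str) -> int:
        return int(self.counts.loc[(variable, category), group])

    def advanced_t_percent(self, group) -> dict[str, float]:
        """Percent of patients at stage T3a or higher, under both readings.

        ``including_t4`` counts T3a+T3b+T4 in the numerator; ``t3_only``
        counts T3a+T3b only.  The denominator is all staged patients either
        way.  Both are reported because published summaries are ambiguous
        about whether T4 is counted.
        """
        t_counts = self.counts.loc["path_t"][group]
        total = t_counts.sum()
        if total == 0:
            return {"including_t4": float("nan"), "t3_only": float("nan")}
        t3 = t_counts.get("T3a", 0) + t_counts.get("T3b", 0)
        t4 = t_counts.get("T4", 0)
        return {
            "including_t4": float(round(100 * (t3 + t4) / total, 1)),
            "t3_only": float(round(100 * t3 / total, 1)),
        }

    def contingency(self, variable: str, groups=None) -> ContingencyTable:
        """Category x grade-group contingency table for one variable."""
        block = self.counts.loc[variable]
        if groups is not None:
            block = block[groups]
        return ContingencyTable(list(block.index), list(block.columns), block.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        """Printable table: 'count (pct%)' cells plus n and age rows."""
        cells = self.counts.astype(int).astype(str) + " (" + self.percents.round(1).astype(str) + "%)"
        head = pd.DataFrame(
            [self.n.astype(str), self.age_mean.round(1).astype(str) + " +/- " + self.age_sd.round(1).astype(str)],
            index=pd.MultiIndex.from_tuples([("cohort", "n"), ("cohort", "age")]),
        )
        return pd.concat([head, cells])


def summarize_cohort(
    annotations: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "grade_group",
) -> CohortSummary:
    """Summarize a cohort by grade group (normal tissue as its own column).

    Percentages are within-group over non-missing values of each variable,
    rounded to one decimal.  An empty group is reported as n=0 with NaN
    statistics.
    """
    variables = variables or [v for v in CATEGORICAL_VARIABLES if v in annotations.columns]
    ann = annotations.copy()
    group = ann[group_col].astype(object)
    group[ann["tissue_type"] == "normal"] = "normal"
    observed = {g for g in group.dropna().unique() if g != "normal"}
    if group_col == "grade_group":
        observed |= {1, 2, 3, 4, 5}  # an empty grade group is reported as n=0
    groups = ["normal"] + sorted(observed)

    n = pd.Series({g: int((group == g).sum()) for g in groups}, name="n")
    age_mean = pd.Series({g: ann.loc[group == g, "age_years"].mean() for g in groups})
    age_sd = pd.Series({g: ann.loc[group == g, "age_years"].std(ddof=1) for g in groups})

    count_rows, index = [], []
    for var in variables:
        levels = sorted(ann[var].dropna().unique())
        for level in levels:
            row = [int(((group == g) & (ann[var] == level)).sum()) for g in groups]
            count_rows.append(row)
            index.append((var, level))
    counts = pd.DataFrame(count_rows, index=pd.MultiIndex.from_tuples(index, names=["variable", "category"]), columns=groups)

    percents = counts.copy().astype(float)
    for var in variables:
        block = counts.loc[var]
        totals = block.sum(axis=0).replace(0, np.nan)
        percents.loc[(var, slice(None)), :] = (100 * block / totals).round(1).to_numpy()
    return CohortSummary(n, age_mean, age_sd, counts, percents)


def chi_squared(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on a contingency table.

    Rows or columns with a zero margin are dropped with a warning before
    testing; expected counts come from the row/column margins.
    """
    counts = table.counts
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        dropped_r = [l for l, k in zip(table.row_labels, row_keep) if not k]
        dropped_c = [l for l, k in zip(table.col_labels, col_keep) if not k]
        logger.warning("dropping zero-margin rows %s / columns %s", dropped_r, dropped_c)
        counts = counts[np.ix_(row_keep, col_keep)]
    if counts.shape[0] < 2 or counts.shape[1] < 2 or counts.sum() <= 0:
        raise ValueError("need at least a 2x2 table with a positive total")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)
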