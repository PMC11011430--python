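"""Published TCGA-PRAD cohort composition used as the reference for simulation.

These are the clinical characteristics of the 497 prostate-adenocarcinoma
patients (and 52 matched normal tissues) of the study cohort, stratified by
ISUP Gleason grade group.  The synthetic-cohort generator draws clinical
covariates from these empirical frequencies, and the cohort summarizer is
validated against the printed percentages.

Counts are per grade group (columns "1".."5"); normal tissues carry only age
and ethnicity.  Variable totals can be smaller than the group size because
some patients lack a recorded stage; frequencies are therefore conditional on
the value being observed.
"""

from __future__ import annotations

import pandas as pd

GROUPS = [1, 2, 3, 4, 5]
CLASS3_LEVELS = ["normal", "low", "high"]

#: number of tumor samples per grade group, and matched normal tissues
N_PER_GROUP = {"normal": 52, 1: 45, 2: 146, 3: 101, 4: 64, 5: 141}

#: age in years, (mean, sd) per group
AGE = {
    "normal": (60.3, 7.3),
    1: (58.2, 7.6),
    2: (59.8, 6.8),
    3: (61.4, 6.5),
    4: (61.7, 7.0),
    5: (62.7, 6.3),
}

_ETHNICITY_ROWS = {
    "asian": [0, 0, 3, 3, 1, 5],
    "african_american": [7, 11, 26, 12, 2, 6],
    "caucasian": [44, 30, 116, 82, 59, 126],
    "other": [1, 4, 1, 4, 2, 4],
}

_PATH_T_ROWS = {
    "T2a": [5, 7, 1, 0, 0],
    "T2b": [2, 4, 0, 3, 1],
    "T2c": [25, 84, 31, 16, 8],
    "T3a": [11, 40, 45, 23, 39],
    "T3b": [1, 8, 21, 19, 86],
    "T4": [0, 1, 2, 1, 6],
}

_PATH_N_ROWS = {
    "N0": [23, 112, 83, 47, 80],
    "N1": [0, 5, 9, 14, 51],
}

_CLIN_M_ROWS = {
    "M0": [38, 136, 93, 58, 130],
    "M1a": [0, 0, 0, 1, 0],
    "M1b": [0, 0, 0, 0, 1],
    "M1c": [0, 0, 0, 0, 1],
}


def _frame(rows: dict, columns) -> pd.DataFrame:
    return pd.DataFrame(rows, index=columns).T


#: ethnicity counts, columns normal + grade groups
ETHNICITY = _frame(_ETHNICITY_ROWS, ["normal", *GROUPS])
#: pathologic T / N and clinical M counts, columns grade groups 1-5
PATH_T = _frame(_PATH_T_ROWS, GROUPS)
PATH_N = _frame(_PATH_N_ROWS, GROUPS)
CLIN_M = _frame(_CLIN_M_ROWS, GROUPS)

#: categorical clinical variables keyed by annotation column name
CATEGORICAL = {"ethnicity": ETHNICITY, "path_t": PATH_T, "path_n": PATH_N, "clin_m": CLIN_M}


def reference_annotations() -> pd.DataFrame:
    """Expand the printed counts into a per-sample annotation table.

    Each categorical variable is assigned within each group so that the
    per-variable marginal counts equal the printed table exactly; patients
    beyond a variable's printed total get a missing value for that variable.
    The joint distribution across variables is arbitrary (the source table
    reports marginals only), which is irrelevant for marginal summaries and
    contingency tests.
    """
    records = []
    for group in ["normal", *GROUPS]:
        n = N_PER_GROUP[group]
        for i in range(n):
            gname = "N" if group == "normal" else f"G{group}"
            records.append(
                {
                    "sample_id": f"REF-{gname}-{i:03d}",
                    "patient_id": f"REFP-{gname}-{i:03d}",
                    "tissue_type": "normal" if group == "normal" else "tumor",
                    "grade_group": pd.NA if group == "normal" else group,
                    "age_years": AGE[group][0],
                }
            )
    ann = pd.DataFrame(records)
    ann["grade_group"] = ann["grade_group"].astype("Int64")
    ann["class3"] = "normal"
    ann.loc[ann["grade_group"].isin([1, 2, 3]), "class3"] = "low"
    ann.loc[ann["grade_group"].isin([4, 5]), "class3"] = "high"

    for var, counts in CATEGORICAL.items():
        ann[var] = pd.NA
        for group in counts.columns:
            mask = (
                ann["tissue_type"] == "normal"
                if group == "normal"
                else ann["grade_group"] == group
            )
            idx = ann.index[mask]
            pos = 0
            for level, k in counts[group].items():
                ann.loc[idx[pos : pos + int(k)], var] = level
                pos += int(k)
    return ann
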