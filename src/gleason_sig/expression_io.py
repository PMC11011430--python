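"""Reading, writing and assembly of GDC-dialect expression and clinical tables.

The on-disk dialects are the ones the GDC portal hands out for bulk RNA-seq
quantifications: either one wide tab-separated table (first column Ensembl
gene ID, one numeric column per sample) or one two-column (gene, value) file
per sample tied together by a manifest TSV with columns ``sample_id`` and
``file_path``.  Gene identifiers are Ensembl stable IDs; version suffixes
(".12") are stripped before any matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")

ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue_type",
    "gleason_primary",
    "gleason_secondary",
    "grade_group",
    "class3",
    "age_years",
    "ethnicity",
    "path_t",
    "path_n",
    "clin_m",
]


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of non-negative FPKM_UQ-like values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit_label: str = "FPKM_UQ"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit_label: str = "FPKM_UQ") -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(float), unit_label)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows], self.unit_label)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols], self.unit_label)


def strip_gene_version(gene_id: str) -> str:
    """Drop an Ensembl ``.N`` version suffix if present."""
    return _VERSION_RE.sub("", gene_id)


def _dedupe_by_mean(frame: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate post-strip gene IDs, keeping the highest-mean row."""
    if frame.index.is_unique:
        return frame
    dup = frame.index[frame.index.duplicated()].unique().tolist()
    logger.warning("duplicate gene IDs after version stripping: %s; keeping highest-mean row", dup)
    order = frame.mean(axis=1).to_numpy()
    keep = (
        pd.DataFrame({"gene": frame.index, "mean": order})
        .groupby("gene", sort=False)["mean"]
        .idxmax()
    )
    return frame.iloc[sorted(keep.to_numpy())]


def read_expression(
    files: str | Path | Mapping[str, str | Path] | None = None,
    manifest: str | Path | pd.DataFrame | None = None,
    allowlist: Iterable[str] | None = None,
    unit_label: str = "FPKM_UQ",
) -> ExpressionMatrix:
    """Assemble an expression matrix from GDC-style quantification tables.

    Parameters
    ----------
    files
        Either a path to one wide TSV (gene rows, sample columns) or a
        mapping ``sample_id -> per-sample two-column file``.
    manifest
        Alternative to the mapping form: a TSV (or DataFrame) with columns
        ``sample_id`` and ``file_path``.
    allowlist
        Optional iterable of gene IDs (version-insensitive) to restrict to,
        e.g. a protein-coding list; when absent all genes pass.

    Genes are restricted to the intersection present in all per-sample
    files.  Duplicate post-strip identifiers are resolved by keeping the row
    with the highest mean expression.
    """
    if manifest is not None:
        if not isinstance(manifest, pd.DataFrame):
            manifest = pd.read_csv(manifest, sep="\t", dtype=str)
        if not {"sample_id", "file_path"} <= set(manifest.columns):
            raise ValueError("manifest needs columns sample_id, file_path")
        files = dict(zip(manifest["sample_id"], manifest["file_path"]))

    if isinstance(files, Mapping):
        columns = {}
        for sample_id, path in files.items():
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"expression file for sample {sample_id!r} not found: {path}")
            col = pd.read_csv(path, sep="\t", header=None, index_col=0, comment="#").iloc[:, 0]
            _check_numeric(col, path)
            columns[sample_id] = col
        frame = pd.concat(columns, axis=1, join="inner")
        frame.columns = list(columns)
    elif files is not None:
        frame = pd.read_csv(files, sep="\t", index_col=0)
        _check_numeric(frame, files)
    else:
        raise ValueError("provide either files or a manifest")

    frame.index = [strip_gene_version(str(g)) for g in frame.index]
    frame = _dedupe_by_mean(frame)
    if allowlist is not None:
        allowed = {strip_gene_version(g) for g in allowlist}
        frame = frame.loc[[g in allowed for g in frame.index]]
    return ExpressionMatrix.from_frame(frame.astype(float), unit_label)


def _check_numeric(values, source) -> None:
    arr = pd.DataFrame(values).apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        bad = pd.DataFrame(values)[arr.isna().any(axis=1)].index[:3].tolist()
        raise ValueError(f"non-numeric expression value in {source} at rows {bad}")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the wide TSV dialect (gene rows, sample columns)."""
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV; unknown columns are preserved but ignored."""
    ann = pd.read_csv(path, sep="\t")
    if "sample_id" not in ann.columns:
        raise ValueError("clinical table needs a sample_id column")
    for col in ("gleason_primary", "gleason_secondary", "grade_group"):
        if col in ann.columns:
            ann[col] = ann[col].astype("Int64")
    return ann


def write_clinical(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def assign_grade_group(gleason_primary: int, gleason_secondary: int) -> int:
    """Map a Gleason pattern pair to the ISUP grade group (1-5).

    Grade group 1: GS <= 6; 2: 3+4; 3: 4+3; 4: GS 8; 5: GS 9-10.
    """
    p, s = int(gleason_primary), int(gleason_secondary)
    if not (3 <= p <= 5 and 3 <= s <= 5):
        raise ValueError(f"Gleason patterns must be in 3-5, got ({p}, {s})")
    total = p + s
    if total <= 6:
        return 1
    if total == 7:
        return 2 if (p, s) == (3, 4) else 3
    if total == 8:
        return 4
    return 5


def assign_grade_groups(ann: pd.DataFrame) -> pd.DataFrame:
    """Fill ``grade_group`` for tumor rows from the Gleason pattern columns."""
    ann = ann.copy()
    tumor = ann["tissue_type"] == "tumor"
    groups = [
        assign_grade_group(p, s)
        for p, s in zip(ann.loc[tumor, "gleason_primary"], ann.loc[tumor, "gleason_secondary"])
    ]
    ann.loc[tumor, "grade_group"] = pd.array(groups, dtype="Int64")
    ann["grade_group"] = ann["grade_group"].astype("Int64")
    ann.loc[~tumor, "grade_group"] = pd.NA
    return ann


def label_class3(ann: pd.DataFrame) -> pd.DataFrame:
    """Fill the three-class label: normal, low (groups 1-3), high (groups 4-5)."""
    ann = ann.copy()
    tumor = ann["tissue_type"] == "tumor"
    missing = ann.loc[tumor & ann["grade_group"].isna(), "sample_id"].tolist()
    if missing:
        raise ValueError(f"tumor samples without grade_group: {missing}")
    ann["class3"] = "normal"
    ann.loc[ann["grade_group"].isin([1, 2, 3]), "class3"] = "low"
    ann.loc[ann["grade_group"].isin([4, 5]), "class3"] = "high"
    counts = ann["class3"].value_counts()
    logger.info(
        "class labels: normal=%d low=%d high=%d",
        counts.get("normal", 0), counts.get("low", 0), counts.get("high", 0),
    )
    return ann


@dataclass
class Cohort:
    """Integrated expression + clinical database, aligned on sample IDs."""

    expression: ExpressionMatrix
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.annotations["sample_id"]) != list(self.expression.sample_ids):
            raise ValueError("annotation rows must align with expression columns")


def build_cohort(expr: ExpressionMatrix, clinical: pd.DataFrame) -> Cohort:
    """Integrate expression and clinical tables into one aligned database.

    One tumor sample is kept per patient (lexicographically smallest
    sample_id, so repeat aliquots resolve deterministically); matched normal
    samples are all kept.  Grade groups and three-class labels are derived.
    """
    ann = clinical[clinical["sample_id"].isin(expr.sample_ids)].copy()
    tumors = ann[ann["tissue_type"] == "tumor"].sort_values("sample_id")
    n_dropped = tumors.duplicated("patient_id").sum()
    if n_dropped:
        logger.warning("dropping %d extra tumor aliquots (one per patient kept)", n_dropped)
    tumors = tumors.drop_duplicates("patient_id", keep="first")
    ann = pd.concat([tumors, ann[ann["tissue_type"] == "normal"]]).sort_values("sample_id")
    if "grade_group" not in ann.columns or ann.loc[ann["tissue_type"] == "tumor", "grade_group"].isna().any():
        ann = assign_grade_groups(ann)
    ann = label_class3(ann)
    ann = ann.reset_index(drop=True)
    return Cohort(expr.subset_samples(list(ann["sample_id"])), ann)
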