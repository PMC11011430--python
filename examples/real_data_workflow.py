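"""Ingesting GDC-portal-style files: manifest, per-sample tables, clinical TSV.

No download happens here: the script writes a miniature synthetic cohort in
the GDC on-disk dialect to a temporary directory and then runs the same
ingestion path a real FPKM_UQ download would use — per-sample two-column
quantification files tied together by a manifest, plus a clinical table with
Gleason patterns from which grade groups and the three-class labels are
derived.
"""

import tempfile
from pathlib import Path

import pandas as pd

from gleason_sig import build_cohort, read_clinical, read_expression

workdir = Path(tempfile.mkdtemp(prefix="gdc_demo_"))

# two-column (gene, value) file per sample, Ensembl IDs with version suffixes
samples = {
    "TCGA-XX-0001-01A": {"ENSG00000000001.12": 10.0, "ENSG00000000002.4": 1.0},
    "TCGA-XX-0001-11A": {"ENSG00000000001.12": 5.0, "ENSG00000000002.4": 2.0},
    "TCGA-XX-0002-01A": {"ENSG00000000001.12": 20.0, "ENSG00000000002.4": 0.5},
}
for sample_id, genes in samples.items():
    with open(workdir / f"{sample_id}.tsv", "w") as fh:
        fh.writelines(f"{g}\t{v}\n" for g, v in genes.items())
manifest = pd.DataFrame(
    {"sample_id": list(samples), "file_path": [str(workdir / f"{s}.tsv") for s in samples]}
)

clinical = pd.DataFrame(
    {
        "sample_id": list(samples),
        "patient_id": ["P1", "P1", "P2"],
        "tissue_type": ["tumor", "normal", "tumor"],
        "gleason_primary": [3, None, 4],
        "gleason_secondary": [4, None, 5],
        "age_years": [61, 61, 67],
    }
)
clinical_path = workdir / "clinical.tsv"
clinical.to_csv(clinical_path, sep="\t", index=False)

expr = read_expression(manifest=manifest)
cohort = build_cohort(expr, read_clinical(clinical_path))
print("expression matrix (gene versions stripped, genes intersected):")
print(cohort.expression.to_frame())
print("\nderived labels:")
print(cohort.annotations[["sample_id", "tissue_type", "grade_group", "class3"]].to_string(index=False))
print("\nGleason 3+4 maps to grade group 2 (low); 4+5 to group 5 (high);")
print("the matched normal sample carries no grade group")
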