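import numpy as np
import pandas as pd
import pytest

from gleason_sig import ExpressionMatrix, SyntheticConfig, generate_cohort


def expr_from_log2(log2_values, gene_ids=None, sample_ids=None):
    """Build an ExpressionMatrix from a log2-scale array."""
    log2_values = np.asarray(log2_values, float)
    n_genes, n_samples = log2_values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, np.power(2.0, log2_values))


def annotations_for(sample_ids, class3, grade_group=None):
    """Minimal annotation table for constructed fixtures."""
    ann = pd.DataFrame({"sample_id": list(sample_ids), "class3": list(class3)})
    ann["tissue_type"] = np.where(ann["class3"] == "normal", "normal", "tumor")
    if grade_group is None:
        grade_group = [0 if c == "normal" else (2 if c == "low" else 4) for c in class3]
    ann["grade_group"] = pd.array(
        [pd.NA if c == "normal" else g for c, g in zip(class3, grade_group)], dtype="Int64"
    )
    ann["age_years"] = 60.0
    return ann


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_per_group=(30, 20, 50, 40, 25, 45),
        n_genes=300,
        n_planted=20,
        effect_size=0.5,
        n_blocks=3,
        block_size=8,
        seed=11,
    )
    return generate_cohort(cfg)
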