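import numpy as np
import pytest

from tipdnb.io_core import ExpressionMatrix, SampleDesign


def make_matrix(values, groups_per_sample, group_order, gene_ids=None, scale="log2"):
    """Build a small ExpressionMatrix from an array and a per-column group list."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    design = SampleDesign(
        sample_to_group=dict(zip(sample_ids, groups_per_sample)),
        group_order=tuple(group_order),
    )
    return ExpressionMatrix(gene_ids, sample_ids, values, design, scale=scale)


@pytest.fixture
def two_group_matrix():
    """4 genes × 6 samples (3 reference + 3 treatment), log2 scale."""
    rng = np.random.default_rng(42)
    vals = rng.normal(8.0, 1.0, size=(4, 6))
    return make_matrix(vals, ["sham"] * 3 + ["IR18"] * 3, ["sham", "IR18"])


@pytest.fixture
def timecourse_matrix():
    """Deterministic 6-group log2 matrix, 30 genes × 18 samples."""
    rng = np.random.default_rng(7)
    groups = ["sham", "IR16", "IR18", "IR22", "IR26", "IR30"]
    vals = rng.normal(8.0, 1.0, size=(30, 18))
    per_sample = [g for g in groups for _ in range(3)]
    return make_matrix(vals, per_sample, groups)
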