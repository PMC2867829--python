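import numpy as np
import pandas as pd
import pytest

from hepacore import ExpressionMatrix, SyntheticSpec, generate_null_matrix


def make_matrix(values, groups, gene_ids=None, sample_ids=None):
    """Build a small ExpressionMatrix from a 2-D array and group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n_samples)]
    reps = {}
    design_rows = []
    for s, g in zip(sample_ids, groups):
        reps[g] = reps.get(g, 0) + 1
        design_rows.append({"sample_id": s, "group": g, "replicate": str(reps[g])})
    design = pd.DataFrame(design_rows).set_index("sample_id")
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), design
    )


@pytest.fixture
def four_group_design():
    """Sample -> group labels of the canonical 4 x 3 time-course design."""
    return ["control"] * 3 + ["1h"] * 3 + ["3h"] * 3 + ["6h"] * 3


@pytest.fixture(scope="session")
def null_matrix_small():
    """A 300-gene null matrix under the default variance prior."""
    matrix, truth = generate_null_matrix(SyntheticSpec(n_genes=300, seed=11))
    return matrix, truth
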