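import numpy as np
import pandas as pd
import pytest

from balanceselect.formats_io import ExpressionMatrix


def make_matrix(gene_rows: dict[str, list[float]], n_case: int,
                n_control: int) -> ExpressionMatrix:
    """Build a small two-class matrix; the first n_case columns are cases."""
    n = n_case + n_control
    samples = [f"s{i+1}" for i in range(n)]
    labels = ["case"] * n_case + ["control"] * n_control
    values = pd.DataFrame(
        {s: [float(gene_rows[g][i]) for g in gene_rows]
         for i, s in enumerate(samples)},
        index=list(gene_rows))
    return ExpressionMatrix(
        values=values, classes=pd.Series(labels, index=samples),
        case_label="case", control_label="control")


@pytest.fixture
def complementary_matrix() -> ExpressionMatrix:
    """Two features that each perfectly order a disjoint half of the
    between-class pairs and tie elsewhere; their union covers all pairs."""
    return make_matrix(
        {"gA": [2, 1, 1, 1], "gB": [1, 2, 1, 1]}, n_case=2, n_control=2)


def random_matrix(rng: np.random.Generator, n_genes: int, n_case: int,
                  n_control: int, n_levels: int | None = 4) -> ExpressionMatrix:
    """Random small matrix; few value levels force plenty of ties."""
    n = n_case + n_control
    if n_levels:
        vals = rng.integers(0, n_levels, size=(n_genes, n)).astype(float)
    else:
        vals = rng.standard_normal((n_genes, n))
    return make_matrix(
        {f"g{i:02d}": list(vals[i]) for i in range(n_genes)}, n_case, n_control)
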