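import numpy as np
import pandas as pd
import pytest

from trisomap import synthetic_data as sd
from trisomap.expression import ExpressionMatrix


@pytest.fixture(scope="session")
def genome():
    return sd.generate_genome(1000, 3, seed=1)


@pytest.fixture(scope="session")
def big_genome():
    return sd.generate_genome(10000, 3, seed=1)


@pytest.fixture(scope="session")
def panel(genome):
    return sd.generate_model_panel(genome)


def make_matrix(values: np.ndarray, n_control: int, gene_ids=None) -> ExpressionMatrix:
    """Wrap a raw array (genes x samples) with control-first column labels."""
    m, n = values.shape
    n_test = n - n_control
    cols = [f"wt_{i+1}" for i in range(n_control)] + [f"tg_{j+1}" for j in range(n_test)]
    groups = pd.Series(["control"] * n_control + ["trisomic"] * n_test, index=cols)
    idx = gene_ids if gene_ids is not None else [f"g{i:05d}" for i in range(m)]
    return ExpressionMatrix(values=pd.DataFrame(values, index=idx, columns=cols), groups=groups)
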