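import numpy as np
import pandas as pd
import pytest

from atomicregulons import (
    ExpressionMatrix,
    infer_atomic_regulons,
    make_dataset,
)


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 experiments with known values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0], [4.0, 3.0, 2.0, 1.0]],
        index=["gA", "gB", "gC"],
        columns=["e1", "e2", "e3", "e4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_dataset():
    """Strong-signal planted study: 5 blocks x 8 genes, 100 experiments."""
    return make_dataset(seed=1)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    expr, features, roles, truth = default_dataset
    with np.errstate(all="ignore"):
        return infer_atomic_regulons(expr, features, roles, truth.always_on)
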