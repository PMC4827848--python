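import numpy as np
import pandas as pd
import pytest

from cider.data import ExpressionMatrix


def make_expression(columns: dict, roles: dict) -> ExpressionMatrix:
    """ExpressionMatrix from raw column arrays (helper for tests)."""
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    values.index = [f"s{k}" for k in range(len(values))]
    return ExpressionMatrix(values=values, roles=roles)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def chain_data(rng):
    """n=5000 samples from the chain A -> B -> C with weights 0.8."""
    n = 5000
    a = rng.normal(size=n)
    b = 0.8 * a + rng.normal(size=n)
    c = 0.8 * b + rng.normal(size=n)
    return make_expression(
        {"A": a, "B": b, "C": c},
        {"A": "mirna", "B": "mrna", "C": "mrna"},
    )
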