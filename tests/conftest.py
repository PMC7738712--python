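import numpy as np
import pandas as pd
import pytest

from pubernet import ExpressionMatrix, SimulationConfig, generate_expression


@pytest.fixture
def small_counts():
    """Tiny counts matrix with known RPKM arithmetic."""
    data = pd.DataFrame(
        {"s1": [10, 990_000 - 10 + 9_990, 0], "s2": [5, 100, 20]},
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(data, scale="counts")


@pytest.fixture
def default_study():
    """One default synthetic study, shared across tests."""
    cfg = SimulationConfig(seed=7)
    expr, meta, truth = generate_expression(cfg)
    return cfg, expr, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
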