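import numpy as np
import pytest

from tjkit import ExpressionSimConfig, simulate_expression_table


@pytest.fixture(scope="session")
def expression_table():
    """A well-separated bimodal gene table with truth labels (fixed seed)."""
    cfg = ExpressionSimConfig(
        n_genes=20000,
        active_fraction=0.5,
        mu_active=6.0,
        sd_active=1.0,
        mu_inactive=0.0,
        sd_inactive=1.0,
        zero_fraction=0.0,
        seed=11,
    )
    return simulate_expression_table(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
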