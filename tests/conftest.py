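import numpy as np
import pytest

import cellcodes as cc


@pytest.fixture(scope="session")
def tiny_design():
    return cc.SyntheticDesign(
        n_genes=120,
        n_types=4,
        samples_per_type=12,
        n_modules=6,
        n_conditions_per_type=4,
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_design):
    """A small planted-module compendium shared across tests."""
    return cc.generate(tiny_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix(rng):
    values = rng.normal(8.0, 1.0, size=(50, 20))
    return cc.ExpressionMatrix(
        values,
        [f"g{i}" for i in range(50)],
        [f"s{j}" for j in range(20)],
    )
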