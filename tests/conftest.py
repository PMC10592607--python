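import numpy as np
import pytest

from cascadeqtl import simulate


@pytest.fixture(scope="session")
def genotypes_185():
    """185-sample, 200-variant panel with 10-variant LD blocks (rho 0.4)."""
    return simulate.simulate_genotypes(
        185, 200, ld_block_size=10, ld_rho=0.4, seed=11
    )


@pytest.fixture(scope="session")
def shared_cascade(genotypes_185):
    """Fully shared cascade (lambda=1, gamma=0) with hidden confounding."""
    truth = simulate.make_cascade_truth(
        genotypes_185, 20, seed=12, eqtl_effect=0.6, factor_sd=0.3
    )
    layers = simulate.simulate_cascade(genotypes_185, truth, seed=13)
    return truth, layers


@pytest.fixture
def rng():
    return np.random.default_rng(0)
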