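import dataclasses

import numpy as np
import pytest

import modkin as mk


@pytest.fixture(scope="session")
def truths():
    return mk.reference_truths()


@pytest.fixture(scope="session")
def designs():
    return mk.reference_designs()


@pytest.fixture(scope="session")
def arg_params(truths):
    """Strong specific-inhibition parameter set (high alpha, low beta)."""
    return truths["arg-pna"]


@pytest.fixture(scope="session")
def ala_params(truths):
    """Catalytic-activation parameter set (alpha < 1, beta >> 1)."""
    return truths["ala-pna"]


@pytest.fixture(scope="session")
def pro_params(truths):
    """Coupled alpha = beta (purely catalytic) parameter set."""
    return truths["pro-pna"]


def noise_free(design):
    return dataclasses.replace(design, noise_cv=0.0)


@pytest.fixture(scope="session")
def noise_free_grids(designs, truths):
    """Noise-free velocity grids for all three pNA designs."""
    return {name: mk.generate_velocity_grid(noise_free(designs[name]), truths[name], seed=0)
            for name in ("arg-pna", "ala-pna", "pro-pna")}


@pytest.fixture(scope="session")
def random_params():
    """A deterministic batch of random modifier parameter draws."""
    rng = np.random.default_rng(42)
    draws = []
    for _ in range(20):
        draws.append(mk.KineticParameters(
            kcat=float(rng.uniform(0.1, 50)),
            km=float(rng.uniform(0.2, 30)),
            kx=float(rng.uniform(1, 500)),
            alpha=float(np.exp(rng.uniform(np.log(0.05), np.log(50)))),
            beta=float(np.exp(rng.uniform(np.log(0.05), np.log(50)))),
        ))
    return draws
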