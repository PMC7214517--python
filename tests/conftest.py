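import numpy as np
import pytest

from barebones import ModelParams, derive_constants

# reference parameter set used throughout: a1 = a2 = 1, gamma = 1/3, rho = 3/2
P0 = ModelParams(1.0, 1.0, 1.0 / 3.0)


@pytest.fixture(scope="session")
def p0():
    return P0


@pytest.fixture(scope="session")
def p0K():
    return ModelParams(1.0, 1.0, 1.0 / 3.0, K=10_000)


@pytest.fixture(scope="session")
def d0(p0):
    return derive_constants(p0)


def random_valid_params(rng: np.random.Generator, n: int) -> list[ModelParams]:
    """Random parameter sets satisfying the coexistence condition."""
    out = []
    while len(out) < n:
        a1 = rng.uniform(0.2, 3.0)
        a2 = rng.uniform(0.2, 3.0)
        g = rng.uniform(0.05, 0.95)
        if a1 - g * a2 > 1e-3 and a2 - g * a1 > 1e-3:
            out.append(ModelParams(a1, a2, g))
    return out
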