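import numpy as np
import pytest

from alleepred import ModelParams, make_allee


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(params=["monod", "ivlev", "tanh"])
def allee_name(request):
    return request.param


@pytest.fixture
def monod01():
    return make_allee("monod", 0.1)


@pytest.fixture
def fig2_params():
    """Nullcline-geometry slice (saddle-node in delta at 0.31154)."""
    return ModelParams(1.8, 0.8, 0.5)


@pytest.fixture
def fig8_params():
    """Base case of the sensitivity study (Hopf in beta at 0.98189)."""
    return {"alpha": 7.1, "beta": 0.9, "m": 1.8, "delta": 0.12}


def random_admissible_params(rng, n):
    """Random parameter/Allee draws with alpha > m (the only regime where
    interior equilibria can exist)."""
    out = []
    names = ["monod", "ivlev", "tanh"]
    while len(out) < n:
        alpha = rng.uniform(0.5, 8.0)
        beta = rng.uniform(0.05, 1.5)
        m = rng.uniform(0.1, 0.95) * alpha
        delta = rng.uniform(0.005, 0.5)
        name = names[rng.integers(3)]
        out.append((ModelParams(alpha, beta, m), make_allee(name, delta)))
    return out
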