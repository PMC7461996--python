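import numpy as np
import pytest

from echodraw import ReservoirParams, WeightSet, init_weights


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_params():
    """A tiny reservoir for fast unit tests."""
    return ReservoirParams(
        n_res=20,
        n_in=5,
        n_out=2,
        tau=20.0,
        leak=0.8,
        dt=1.0,
        spectral_radius=1.5,
        sensory_ms=50.0,
        motor_ms=50.0,
        seed=7,
    )


@pytest.fixture
def small_weights(small_params):
    return init_weights(small_params, rng_seed=7, n_patterns=2)


def zero_weights(params: ReservoirParams, n_patterns: int = 1) -> WeightSet:
    """All-zero weights (decoupled neurons) for analytic dynamics tests."""
    return WeightSet(
        np.zeros((params.n_in, params.n_res)),
        np.zeros((params.n_res, params.n_res)),
        [np.zeros((params.n_res, params.n_out)) for _ in range(n_patterns)],
    )
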