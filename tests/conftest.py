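import numpy as np
import pytest

from twobud import DEFAULT_PARAMS, ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The calibrated slice's parameter set at its default (v0, mu) cell."""
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def det_params() -> ModelParameters:
    """Calibrated parameters with noise switched off."""
    return DEFAULT_PARAMS.with_updates(eta=0.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_params(rng: np.random.Generator, integer_n: bool = True) -> ModelParameters:
    """A random but dynamically reasonable parameter set for property tests."""
    n = float(rng.integers(2, 7)) if integer_n else float(rng.uniform(1.5, 6.0))
    return ModelParameters(
        v0=float(rng.uniform(0.005, 0.2)),
        v=float(rng.uniform(0.5, 1.5)),
        S=float(rng.uniform(0.8, 2.5)),
        n=n,
        K=float(rng.uniform(0.05, 0.5)),
        D=float(rng.uniform(0.1, 0.8)),
        mu=float(rng.uniform(0.2, 3.0)),
        Q=float(rng.uniform(0.1, 0.5)),
        m=float(rng.integers(2, 12)),
        eta=0.0,
    )
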