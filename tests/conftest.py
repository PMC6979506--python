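import numpy as np
import pytest

import lro


@pytest.fixture(scope="session")
def tsuga():
    """Bundled six-size-class hemlock model with Poisson rewards."""
    return lro.load_tsuga()


@pytest.fixture(scope="session")
def tsuga_chain(tsuga):
    return lro.build_markov_chain(tsuga)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_models(count, taus=(1, 2, 3, 4, 5), seed0=100, fertility_model="poisson"):
    """Deterministic battery of random valid life cycles."""
    models = []
    for i in range(count):
        tau = taus[i % len(taus)]
        models.append(
            lro.generate_synthetic_model(
                tau, seed=seed0 + i, profile="stage_like", fertility_model=fertility_model
            )
        )
    return models
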