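import numpy as np
import pytest

import dasig


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    config = dasig.CohortConfig(n_genes=600, n_samples=80, n_modules=3,
                                genes_per_module=30, n_ribosome_decoys=20,
                                seed=11)
    X, metadata, structure = dasig.generate_cohort(config)
    return config, X, metadata, structure


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    _, X, _, _ = small_cohort
    return dasig.preprocess(X)


@pytest.fixture(scope="session")
def small_trained(small_cohort, small_scaled):
    """A DAE trained on the compact cohort (reduced epochs, scaled lr)."""
    params = dasig.DAEParams(n_hidden=20, epochs=20, learning_rate=0.01,
                             corruption_rate=0.001, seed=11)
    model, trace = dasig.train(small_scaled, params)
    return model, trace


@pytest.fixture(scope="session")
def small_embedding(small_trained, small_scaled):
    model, _ = small_trained
    return dasig.embed(model, small_scaled)


@pytest.fixture
def toy_model():
    """A tiny fixed model for hand-checkable encoder/decoder cases."""
    rng = np.random.default_rng(7)
    params = dasig.DAEParams(n_hidden=3, epochs=1, seed=7)
    W = rng.normal(0, 0.3, (3, 5))
    b = rng.normal(0, 0.1, 3)
    b_prime = rng.normal(0, 0.1, 5)
    return dasig.DAEModel(W, b, b_prime, params, [f"G{i}" for i in range(5)])
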