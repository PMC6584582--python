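import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 16-D: the separable SVM fixture."""
    rng = np.random.default_rng(42)
    n = 100
    X0 = rng.normal(-2.0, 0.5, size=(n, 16))
    X1 = rng.normal(2.0, 0.5, size=(n, 16))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y


@pytest.fixture(scope="session")
def blob_model(blob_data):
    from agonalert.detector import train

    X, y = blob_data
    return train(X, y, seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    """Compact synthetic clip corpus (20 sources/class) for CV-path tests."""
    from agonalert.synthgen import build_clip_corpus

    return build_clip_corpus(n_sources_per_class=20, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """Featurizer + detector trained once on a compact corpus."""
    from agonalert.evaluate import train_reference_bundle

    return train_reference_bundle(n_sources_per_class=20, n_components=128, seed=11)
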