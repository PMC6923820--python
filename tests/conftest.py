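import numpy as np
import pytest

from mvfae import model_core, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small two-view bundle for fast training-path tests."""
    spec = synthdata.SyntheticSpec(
        N=60,
        views=(synthdata.ViewGenSpec(20, 0.05), synthdata.ViewGenSpec(15, 0.05)),
        k_true=3,
        n_clusters=5,
        network_density=0.05,
        seed=7,
    )
    return synthdata.generate(spec)


@pytest.fixture(scope="session")
def default_bundle():
    return synthdata.generate(synthdata.SyntheticSpec(seed=0))


@pytest.fixture
def tiny_model(tiny_bundle):
    specs = tuple(
        model_core.ViewSpec(f"v{i}", v.n_features, (8, 4))
        for i, v in enumerate(tiny_bundle.views)
    )
    return model_core.build_model(specs, class_count=2, seed=11)


def random_symmetric_nonnegative(rng, p):
    a = rng.random((p, p))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a
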