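import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_cluster_2d():
    """Seeded three-cluster 2-d data with 10% uniform noise."""
    from cepel.synthetic import gen_clustered
    pts, labels = gen_clustered(d=2, n=500, seed=11)
    return pts, labels
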