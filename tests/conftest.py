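import numpy as np
import pytest

import dnafrag as d

L = 850.0
MU = 5.83


@pytest.fixture(scope="session")
def uniform_sample_20k():
    """Uniform-breakage sample, 20k plasmids, mu = 5.83, seed 1."""
    return d.simulate_sample(d.UniformBreakModel(MU), n_plasmids=20000, seed=1)


@pytest.fixture(scope="session")
def clustered_sample_20k():
    """Clustered sample matched to the uniform fixture's total break rate (seed 1)."""
    law = d.ClusterSizeLaw.geometric(3.0)
    model = d.ClusteredBreakModel(
        track_rate=MU / law.mean, cluster_size_law=law, cluster_span_nm=50.0
    )
    return d.simulate_sample(model, n_plasmids=20000, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
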