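import numpy as np
import pytest

import hypermass as hm


@pytest.fixture
def toy_hypergraph() -> hm.Hypergraph:
    """Seven nodes, mixed cardinalities, connected at the full level."""
    return hm.Hypergraph([(0, 1), (1, 2, 3), (3, 4, 5, 6), (0, 2)], node_count=7)


@pytest.fixture
def default_params() -> hm.DynamicsParameters:
    return hm.DynamicsParameters(lam=0.1, delta=1.0, theta_star=0.5)


@pytest.fixture(scope="session")
def small_blob() -> hm.Hypergraph:
    """Hyperblob on 20 nodes, pairwise degree 4."""
    return hm.make_hyperblob(20, 4, seed=11)


@pytest.fixture(scope="session")
def community_small() -> hm.Hypergraph:
    """Small two-block community hypergraph for mean-field tests."""
    cfg = hm.CommunityConfig(node_count=60, m_in=(60, 30), m_out=6, mu=6.0)
    return hm.make_community_hypergraph(cfg, seed=3)


def blob_modulation(lam_pair: float, lam_star: float):
    """Modulation giving pairwise rate ``lam_pair`` (relative to lam) = 1
    and a bare global-hyperedge rate ``lam_star``."""
    def mod(c: int) -> float:
        return 1.0 if c == 2 else lam_star / lam_pair

    return mod
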