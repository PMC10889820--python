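import numpy as np
import pytest

from scmgcn.preprocess import PreprocessConfig, preprocess_pair
from scmgcn.simulate import SimConfig, make_ref_query_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small, easily learnable reference/query pair (3 types, mild batch effect)."""
    cfg = SimConfig(
        n_types=3, n_genes=300, n_marker_per_type=30,
        n_ref_cells=120, n_query_cells=120, batch_effect_sigma=0.3, seed=7,
    )
    return make_ref_query_pair(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_pair):
    ref, query = small_pair
    cfg = PreprocessConfig(n_hvg=200, seed=7)
    ref_p, query_p, hvg = preprocess_pair(ref, query, cfg)
    return ref_p, query_p, hvg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
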