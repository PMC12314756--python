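import numpy as np
import pytest

from treescreen.catalog import build_feature_catalog
from treescreen.cohort import CohortConfig, simulate_cohort
from treescreen.embedding import EmbeddingConfig
from treescreen.graph import build_semantic_graph


@pytest.fixture(scope="session")
def catalog():
    return build_feature_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A small but realistically imbalanced cohort (~7.5:1)."""
    cfg = CohortConfig(n_subjects=120, n_high=14, seed=7)
    return simulate_cohort(cfg, catalog)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    return build_semantic_graph(small_cohort.Z, labels=small_cohort.labels)


@pytest.fixture(scope="session")
def tiny_embedding_cfg():
    return EmbeddingConfig(
        k=8, walks_per_node=2, walk_length=10, window=3, epochs=1, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
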