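import numpy as np
import pytest

from mogsa import (
    SimulationConfig,
    fit_mfa,
    preprocess_block,
    simulate_project,
    table_weights,
)
from mogsa.io_formats import AnnotationMatrix, OmicsBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_block(rng, name, p, n, sample_ids=None, center=False):
    values = rng.normal(size=(p, n))
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    return OmicsBlock(
        name=name,
        feature_ids=[f"{name}_f{i}" for i in range(p)],
        sample_ids=sample_ids or [f"s{j}" for j in range(n)],
        values=values,
    )


@pytest.fixture
def block_factory():
    return make_block


@pytest.fixture
def tiny_config():
    """A scaled-down triplet design that keeps every structural constraint."""
    return SimulationConfig(
        K=2, p_k=60, n=12, n_sets=6, set_size=10, n_clusters=4,
        cluster_size=3, de_sets_per_cluster=2, n_deg=3, seed=11,
    )


@pytest.fixture
def tiny_project(tiny_config):
    return simulate_project(tiny_config)


@pytest.fixture(scope="session")
def default_project():
    """One full-size benchmark project (3 x 1000 x 30), shared per session."""
    return simulate_project(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def default_model(default_project):
    centered = [preprocess_block(b) for b in default_project.blocks]
    w = table_weights(centered, "mfa")
    return fit_mfa(centered, w, n_components=5), centered


def random_annotation(rng, block, n_sets, set_size, set_names=None):
    names = set_names or [f"set{j}" for j in range(n_sets)]
    G = np.zeros((block.n_features, n_sets), dtype=np.int8)
    for j in range(n_sets):
        G[rng.choice(block.n_features, set_size, replace=False), j] = 1
    return AnnotationMatrix(block.name, list(block.feature_ids), names, G)


@pytest.fixture
def annotation_factory():
    return random_annotation
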