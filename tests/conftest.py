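import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctbench

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_synth():
    """A small generated dataset with ground truth, shared across tests."""
    spec = ctbench.SyntheticSpec(
        n_clusters=3, cluster_sizes=[16, 32, 64], markers_per_cluster=3,
        n_graded_genes=10, n_sparse_genes=20, n_baseline_genes=10,
        dropout_rate=0.1, seed=7,
    )
    matrix, truth = ctbench.generate(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def small_filtered(small_synth):
    _, matrix, _ = small_synth
    return ctbench.preprocess_counts(matrix)


def make_separable_matrix(n_clusters=3, cells_per_cluster=40, noise=0.05, seed=0):
    """A linearly separable log-space toy: one exclusive high feature per
    cluster plus small Gaussian noise."""
    rng = np.random.default_rng(seed)
    n_cells = n_clusters * cells_per_cluster
    values = rng.normal(0.0, noise, size=(n_clusters + 2, n_cells)).clip(min=0)
    labels = np.empty(n_cells, dtype=object)
    for k in range(n_clusters):
        cols = slice(k * cells_per_cluster, (k + 1) * cells_per_cluster)
        labels[cols] = f"type{k}"
        values[k, cols] += 6.0
    return ctbench.LogNormalizedMatrix(
        gene_ids=[f"g{i}" for i in range(n_clusters + 2)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        values=values,
        labels=labels,
    )


@pytest.fixture()
def separable_matrix():
    return make_separable_matrix()
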