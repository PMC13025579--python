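import warnings

import numpy as np
import pytest

from hetspot import io as hio
from hetspot import heterograph as hg
from hetspot.encoder import BipartiteOperator, spatial_operator, init_embeddings
from hetspot.synthetic import SyntheticSpec, generate_multislice

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_dataset():
    """20-spot, 30-gene, 2-domain single slice, fully preprocessed."""
    spec = SyntheticSpec(
        grid=(5, 4), n_genes=30, markers_per_domain=5, n_domains=2, seed=7
    )
    ds = generate_multislice(spec)
    return hio.preprocess(ds, n_hvg=2000, pca_d=10, seed=7)


@pytest.fixture(scope="session")
def tiny_graphs(tiny_dataset):
    """Heterograph, spatial operator and edge subgraphs of the tiny slice."""
    ds = tiny_dataset
    spatial = hio.build_spatial_graphs(ds, k=3)
    A = spatial_operator(spatial)
    graph = hg.assemble_adjacency(
        hg.binarize_edges([s.raw_counts for s in ds.slices])
    )
    sub = hg.sample_edge_subgraphs(graph, fraction=0.10, seed=7)
    return graph, A, sub


@pytest.fixture(scope="session")
def two_slice_dataset():
    """Two small slices with batch effects, preprocessed."""
    spec = SyntheticSpec(
        n_slices=2, grid=(8, 6), n_genes=60, markers_per_domain=10,
        n_domains=2, batch_scale_sd=0.5, seed=11,
    )
    ds = generate_multislice(spec)
    return hio.preprocess(ds, n_hvg=2000, pca_d=20, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
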