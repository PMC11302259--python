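import io

import numpy as np
import pytest
from skbio import TreeNode

from ecoassembly.containers import CommunityTable, SampleMetadata
from ecoassembly.simulate import simulate_tree


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — A-B patristic 2, A-C and B-C patristic 4."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    counts = np.array([[5, 0], [0, 3], [2, 2]])
    return CommunityTable(counts, ["A", "B", "C"], ["s1", "s2"])


@pytest.fixture(scope="session")
def reference_fixture():
    """Deterministic 8-taxon x 5-sample community + Yule tree.

    The exact fixture cross-checked against R picante/vegan; frozen oracle
    values in the tests refer to this dataset.
    """
    tree = simulate_tree(8, seed=3)
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 20, size=(8, 5))
    mask = rng.random((8, 5)) < 0.5
    counts = counts * mask
    table = CommunityTable(counts, [t.name for t in tree.tips()],
                           [f"s{i}" for i in range(5)])
    return table, tree


@pytest.fixture
def grouped_metadata():
    import pandas as pd

    df = pd.DataFrame(
        {
            "group": ["A", "A", "A", "B", "B"],
            "latitude": [29.0, 29.5, 30.0, 31.0, 32.0],
            "longitude": [114.0] * 5,
            "ph": [6.5, 6.8, 7.0, 7.8, 8.1],
            "ec": [120.0, 150.0, 140.0, 300.0, 310.0],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"),
    )
    return SampleMetadata(df)


def random_table(rng, n_taxa, n_samples, max_count=20, sparsity=0.5):
    """Random sparse community table with no empty samples."""
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts *= rng.random((n_taxa, n_samples)) < sparsity
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1 + rng.integers(max_count)
    return CommunityTable(counts, [f"OTU{i + 1}" for i in range(n_taxa)],
                          [f"s{j + 1}" for j in range(n_samples)])


def random_distance_matrix(rng, n, dim=3):
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    pts = rng.normal(size=(n, dim))
    return DistanceMatrix(squareform(pdist(pts), checks=False),
                          ids=[f"s{i + 1}" for i in range(n)])
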