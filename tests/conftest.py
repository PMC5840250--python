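import numpy as np
import pytest
from scipy.spatial.distance import squareform

from biosyndist import (
    DistanceMatrix,
    SampleCompoundMatrix,
    dendrogram_to_tree,
    hierarchical_cluster,
)
from biosyndist.synthetic_fixtures import (
    make_hypothetical_dataset,
    make_two_species_dataset,
)


@pytest.fixture(scope="session")
def hypothetical():
    """The deterministic 13-profile example dataset."""
    return make_hypothetical_dataset()


@pytest.fixture(scope="session")
def two_species():
    return make_two_species_dataset(seed=1)


def random_distance_matrix(rng, n, low=0.05, high=1.0, ids=None):
    ids = ids if ids is not None else [f"x{i}" for i in range(n)]
    cond = rng.uniform(low, high, n * (n - 1) // 2)
    return DistanceMatrix(ids, squareform(cond))


def random_tree(rng, n_leaves, linkage="average"):
    """Random ultrametric tree built through the clustering pipeline."""
    ids = [f"L{i}" for i in range(n_leaves)]
    d = random_distance_matrix(rng, n_leaves, ids=ids)
    z = hierarchical_cluster(d, linkage)
    return dendrogram_to_tree(z, ids)


def random_profiles(rng, ids, n_samples=2, sparsity=0.35, integer=False):
    """Random non-degenerate sample × compound quantities over ``ids``."""
    n = len(ids)
    vals = rng.uniform(0.5, 9.0, (n_samples, n)) * (rng.random((n_samples, n)) > sparsity)
    if integer:
        vals = np.ceil(vals)
    for i in range(n_samples):  # every profile must contain something
        if vals[i].sum() == 0:
            vals[i, rng.integers(n)] = 1.0
    names = [f"s{i}" for i in range(n_samples)]
    return SampleCompoundMatrix(names, list(ids), vals)


def brute_force_gunifrac(tree, m, alpha):
    """Edge-enumeration oracle: leaf sets below each edge found by descent.

    Independent of the package's postorder mass accumulation: subtree
    leaf sets are recomputed per edge and proportions re-summed from the
    raw matrix.
    """
    rel = m.values / m.values.sum(axis=1, keepdims=True)
    col = {c: j for j, c in enumerate(m.compound_ids)}

    def leaves_below(node):
        if node.is_leaf:
            return [node.name]
        out = []
        for ch in node.children:
            out.extend(leaves_below(ch))
        return out

    edges = [(e.length, leaves_below(e)) for e in tree.edges()]
    n = m.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for b, leaf_set in edges:
                pa = sum(rel[i, col[c]] for c in leaf_set if c in col)
                pb = sum(rel[j, col[c]] for c in leaf_set if c in col)
                if pa + pb == 0:
                    continue
                w = b * (pa + pb) ** alpha
                num += w * abs(pa - pb) / (pa + pb)
                den += w
            out[i, j] = out[j, i] = num / den if den else 0.0
    return out
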