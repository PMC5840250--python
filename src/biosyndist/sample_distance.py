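"""Distances between sample profiles: generalized UniFrac and Bray–Curtis.

The biosynthetically informed distance between two samples is a weighted
generalized UniFrac over the biosynthesis tree: each tree edge carries, per
sample, the summed relative abundance of the compounds below it, and the
distance is the branch-length-weighted imbalance of those proportions,

    d(A, B) = Σ_i b_i (p_iA + p_iB)^α |p_iA − p_iB| / (p_iA + p_iB)
              ─────────────────────────────────────────────────────
              Σ_i b_i (p_iA + p_iB)^α

summed over edges with p_iA + p_iB > 0.  The exponent α ∈ [0, 1] controls
how strongly abundant lineages dominate; α = 1 recovers classical
(normalized) weighted UniFrac, while the default α = 0.5 gives neither rare
nor dominant compounds excessive weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .biosyn_tree import BiosynTree, dendrogram_to_tree, hierarchical_cluster
from .compound_similarity import sorensen_matrix
from .io_matrices import (
    CompoundFeatureMatrix,
    DistanceMatrix,
    SampleCompoundMatrix,
    ValidationError,
    align_compounds,
)

__all__ = [
    "relative_abundance",
    "generalized_unifrac",
    "bray_curtis",
    "biosyn_dist",
    "BioSynDistResult",
]


def relative_abundance(m: SampleCompoundMatrix) -> SampleCompoundMatrix:
    """Normalize each sample's quantities to proportions summing to 1."""
    sums = m.values.sum(axis=1, keepdims=True)
    # an all-zero sample is already rejected by the type's validation
    return SampleCompoundMatrix(m.sample_ids, m.compound_ids, m.values / sums)


def _edge_masses(tree: BiosynTree, m: SampleCompoundMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths b_i and per-sample proportions p_i^S for every edge.

    Proportions are accumulated bottom-up: an edge carries the summed
    relative abundance of every compound in the subtree below it.
    """
    rel = relative_abundance(m)
    leaf_index = {c: j for j, c in enumerate(rel.compound_ids)}
    tree_leaves = set(tree.leaf_names())
    missing = [c for c in rel.compound_ids if c not in tree_leaves]
    if missing:
        raise ValidationError(
            f"compounds not present as tree leaves: {missing}"
        )

    nodes = list(tree.postorder())
    n_samples = rel.n_samples
    mass: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf:
            j = leaf_index.get(node.name)
            mass[id(node)] = (
                rel.values[:, j].copy() if j is not None else np.zeros(n_samples)
            )
        else:
            mass[id(node)] = np.sum(
                [mass[id(ch)] for ch in node.children], axis=0
            )

    edges = list(tree.edges())
    b = np.array([e.length for e in edges])
    p = np.stack([mass[id(e)] for e in edges], axis=0)  # (n_edges, n_samples)
    return b, p


def generalized_unifrac(
    tree: BiosynTree, m: SampleCompoundMatrix, alpha: float = 0.5
) -> DistanceMatrix:
    """Weighted generalized UniFrac distance between all sample pairs.

    ``m`` may hold absolute quantities or presence/absence; samples are
    normalized to proportions internally.  Edges carrying no abundance in
    either sample of a pair drop out of both sums (0/0 convention).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    b, p = _edge_masses(tree, m)
    if b.size == 0 or np.all(b == 0):
        raise ValidationError("degenerate tree: all edge lengths are zero")

    n = m.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = p[:, i], p[:, j]
            tot = pa + pb
            occ = tot > 0
            w = b[occ] * tot[occ] ** alpha
            denom = w.sum()
            if denom == 0:
                # samples confined to zero-length branches: no signal
                d = 0.0
            else:
                d = float((w * np.abs(pa[occ] - pb[occ]) / tot[occ]).sum() / denom)
            out[i, j] = out[j, i] = min(d, 1.0)
    return DistanceMatrix(m.sample_ids, out)


def bray_curtis(m: SampleCompoundMatrix) -> DistanceMatrix:
    """Bray–Curtis dissimilarity on the (raw) quantitative composition."""
    condensed = pdist(m.values, metric="braycurtis")
    return DistanceMatrix(m.sample_ids, squareform(condensed))


@dataclass
class BioSynDistResult:
    """End-to-end result with all intermediates available for inspection."""

    distances: DistanceMatrix  # samples × samples, the biosynthetic d
    tree: BiosynTree  # biosynthesis tree over compounds
    compound_distances: DistanceMatrix  # compound Sørensen matrix


def biosyn_dist(
    m: SampleCompoundMatrix,
    f: CompoundFeatureMatrix,
    linkage: str = "complete",
    alpha: float = 0.5,
    height_scale: float = 0.5,
    drop_missing: bool = False,
) -> BioSynDistResult:
    """Biosynthetically informed distance between all sample profiles.

    Composition of the three pipeline stages: Sørensen dissimilarities
    between compounds from shared features, hierarchical clustering into a
    biosynthesis tree, and weighted generalized UniFrac between samples
    over that tree.
    """
    m, f = align_compounds(m, f, drop_missing=drop_missing)
    compound_d = sorensen_matrix(f)
    if len(compound_d) < 2:
        raise ValidationError("need at least 2 compounds for the pipeline")
    merges = hierarchical_cluster(compound_d, linkage=linkage)
    tree = dendrogram_to_tree(merges, compound_d.ids, height_scale=height_scale)
    distances = generalized_unifrac(tree, m, alpha=alpha)
    return BioSynDistResult(distances=distances, tree=tree, compound_distances=compound_d)
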