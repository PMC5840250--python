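"""Hierarchical clustering of compounds and the resulting biosynthesis tree.

The compound Sørensen matrix is clustered agglomeratively; the dendrogram is
then treated as a rooted ultrametric tree whose tips are compounds and whose
branch lengths encode biosynthetic divergence, playing the role the
phylogeny plays in microbial UniFrac analyses.

Heights are rescaled by ``height_scale`` (default 0.5) when the dendrogram
is converted, so that the tip-to-tip (patristic) path length through the
first common ancestor of two compounds equals their cophenetic merge
height.  UniFrac distances are invariant under uniform rescaling of branch
lengths, so this is purely a presentation choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .io_matrices import DistanceMatrix, ValidationError

__all__ = [
    "TreeNode",
    "BiosynTree",
    "hierarchical_cluster",
    "dendrogram_to_tree",
    "cophenetic_distances",
]

LINKAGES = ("complete", "average", "single", "ward")


@dataclass
class TreeNode:
    """Node of a rooted tree; ``length`` is the edge to the parent (root: 0)."""

    name: str | None = None
    height: float = 0.0
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


@dataclass
class BiosynTree:
    """Rooted tree with branch lengths whose leaves are compounds."""

    root: TreeNode

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if any(n is None for n in names):
            raise ValidationError("tree has unnamed leaves")
        return names  # type: ignore[return-value]

    def edges(self) -> Iterator[TreeNode]:
        """Every non-root node, i.e. every edge (identified by its child)."""
        for node in self.preorder():
            if node is not self.root:
                yield node

    @property
    def total_branch_length(self) -> float:
        return float(sum(n.length for n in self.edges()))

    def rescaled(self, factor: float) -> "BiosynTree":
        """Copy with every height and edge length multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("rescaling factor must be positive")

        def copy(node: TreeNode) -> TreeNode:
            new = TreeNode(
                name=node.name,
                height=node.height * factor,
                length=node.length * factor,
            )
            for ch in node.children:
                new.add_child(copy(ch))
            return new

        return BiosynTree(copy(self.root))

    # -- Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        import dendropy

        tree = self._to_dendropy()
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    def _to_dendropy(self):
        import dendropy

        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: TreeNode, dnode) -> None:
            dnode.edge.length = node.length if node.parent is not None else None
            if node.is_leaf:
                dnode.taxon = taxa.new_taxon(label=node.name)
            for ch in node.children:
                build(ch, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    @classmethod
    def from_newick(cls, text: str) -> "BiosynTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")

        def build(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else None
            node = TreeNode(name=name, length=float(dnode.edge.length or 0.0))
            for ch in dnode.child_nodes():
                node.add_child(build(ch))
            return node

        root = build(dtree.seed_node)
        root.length = 0.0
        _assign_heights(root)
        return cls(root)


def _assign_heights(root: TreeNode) -> None:
    """Recompute node heights from edge lengths (leaves anchored at 0)."""

    def depth_assign(node: TreeNode, depth: float) -> float:
        if node.is_leaf:
            node.height = 0.0
            return depth
        max_below = max(depth_assign(ch, depth + ch.length) for ch in node.children)
        node.height = max_below - depth
        return max_below

    depth_assign(root, 0.0)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> np.ndarray:
    """Agglomerative clustering of a compound distance matrix.

    Returns the merge sequence in scipy linkage format: row ``k`` merges the
    clusters with indices ``Z[k, 0]`` and ``Z[k, 1]`` at height ``Z[k, 2]``
    (indices ≥ n refer to the cluster formed at step ``index − n``).  Equal
    Sørensen dissimilarities (zero-height merges from multi-product enzymes
    included) are resolved deterministically given the input compound order.
    """
    if linkage not in LINKAGES:
        raise ValidationError(
            f"unknown linkage {linkage!r}; choose one of {LINKAGES}"
        )
    if len(d) < 2:
        raise ValidationError("need at least 2 compounds to cluster")
    z = hierarchy.linkage(d.condensed(), method=linkage)
    # guard against negative merge heights from floating-point fuzz
    z[:, 2] = np.maximum(z[:, 2], 0.0)
    return z


def dendrogram_to_tree(
    merges: np.ndarray,
    leaf_ids: Sequence[str],
    height_scale: float = 0.5,
) -> BiosynTree:
    """Convert a merge sequence into a rooted ultrametric tree.

    Internal nodes sit at ``merge height × height_scale``; leaves at height
    0; each edge length is parent height minus child height.  With the
    default ``height_scale=0.5`` the patristic distance between two leaves
    reproduces their cophenetic merge height exactly.
    """
    merges = np.asarray(merges, dtype=float)
    n = len(leaf_ids)
    if merges.ndim != 2 or merges.shape[0] != n - 1 or merges.shape[1] < 3:
        raise ValidationError(
            f"merge sequence has shape {merges.shape}, expected ({n - 1}, 4)"
        )
    if (merges[:, 2] < 0).any():
        raise ValidationError("negative merge height")
    if height_scale <= 0:
        raise ValidationError("height_scale must be positive")

    nodes: list[TreeNode] = [TreeNode(name=str(lab), height=0.0) for lab in leaf_ids]
    for row in merges:
        a, b, h = row[0], row[1], row[2]
        parent = TreeNode(height=float(h) * height_scale)
        for idx in (int(a), int(b)):
            child = nodes[idx]
            child.length = max(parent.height - child.height, 0.0)
            parent.add_child(child)
        nodes.append(parent)
    root = nodes[-1]
    root.length = 0.0
    return BiosynTree(root)


def cophenetic_distances(tree: BiosynTree) -> DistanceMatrix:
    """Patristic (summed branch length) distances between every leaf pair."""
    leaves = tree.leaves()
    names = tree.leaf_names()
    n = len(leaves)

    # depth of every node from the root, then LCA via parent chains
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for ch in node.children:
            depth[id(ch)] = depth[id(node)] + ch.length

    def ancestors(node: TreeNode) -> list[TreeNode]:
        chain = []
        cur: TreeNode | None = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent
        return chain

    chains = [ancestors(leaf) for leaf in leaves]
    out = np.zeros((n, n))
    for i in range(n):
        anc_i = {id(x) for x in chains[i]}
        for j in range(i + 1, n):
            lca = next(x for x in chains[j] if id(x) in anc_i)
            dist = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[id(lca)]
            out[i, j] = out[j, i] = dist
    return DistanceMatrix(names, out)
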