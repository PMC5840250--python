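import io as _io

import numpy as np
import pytest

from biosyndist import (
    SampleCompoundMatrix,
    ValidationError,
    biosyn_dist,
    bray_curtis,
    dendrogram_to_tree,
    generalized_unifrac,
    relative_abundance,
)
from biosyndist.biosyn_tree import BiosynTree, TreeNode
from biosyndist.merge_weights import standardize

from conftest import brute_force_gunifrac, random_profiles, random_tree


def _chain_tree():
    # ((A:0.1,B:0.1):0.3,C:0.4);
    root = TreeNode(height=0.4)
    inner = TreeNode(height=0.1, length=0.3)
    for n in "AB":
        inner.add_child(TreeNode(name=n, length=0.1))
    root.add_child(inner)
    root.add_child(TreeNode(name="C", length=0.4))
    return BiosynTree(root)


def test_relative_abundance_rows_sum_to_one(hypothetical):
    m = relative_abundance(hypothetical["samples"])
    assert np.allclose(m.values.sum(axis=1), 1.0, atol=1e-12)
    simple = relative_abundance(
        SampleCompoundMatrix(["s"], ["a", "b", "c"], np.array([[2.0, 2.0, 0.0]]))
    )
    assert simple.values.tolist() == [[0.5, 0.5, 0.0]]


class TestGeneralizedUnifrac:
    def test_identical_profiles_are_zero(self):
        tree = _chain_tree()
        m = SampleCompoundMatrix(
            ["s1", "s2"], ["A", "B", "C"], np.array([[1.0, 2, 3], [2.0, 4, 6]])
        )
        d = generalized_unifrac(tree, m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 1.0])
    def test_disjoint_clades_are_one(self, alpha):
        tree = _chain_tree()
        m = SampleCompoundMatrix(
            ["s1", "s2"], ["A", "B", "C"], np.array([[1.0, 1, 0], [0.0, 0, 1]])
        )
        assert generalized_unifrac(tree, m, alpha=alpha).values[0, 1] == pytest.approx(1.0)

    def test_three_leaf_alpha_one_hand_check(self):
        tree = _chain_tree()
        m = SampleCompoundMatrix(
            ["s1", "s2"], ["A", "B", "C"], np.array([[0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
        )
        # edges: A(0.1): .5/0; B(0.1): 0/.5; AB(0.3): .5/.5; C(0.4): .5/.5
        # num = 0.1*0.5*2 = 0.1 ; den = 0.1*0.5*2 + 0.3 + 0.4 = 0.8
        assert generalized_unifrac(tree, m, alpha=1.0).values[0, 1] == pytest.approx(0.125)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, alpha, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(3, 9)))
        m = random_profiles(rng, tree.leaf_names(), n_samples=3)
        got = generalized_unifrac(tree, m, alpha=alpha).values
        want = brute_force_gunifrac(tree, m, alpha)
        assert np.max(np.abs(got - want)) <= 1e-10

    def test_alpha_one_matches_skbio_weighted_unifrac(self):
        """Classical normalized weighted UniFrac limit, independent library."""
        import skbio
        from skbio.diversity.beta import weighted_unifrac

        rng = np.random.default_rng(11)
        for _ in range(4):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            ids = tree.leaf_names()
            m = random_profiles(rng, ids, integer=True)  # skbio wants counts
            ours = generalized_unifrac(tree, m, alpha=1.0).values[0, 1]
            sk_tree = skbio.TreeNode.read(_io.StringIO(tree.to_newick()))
            ref = weighted_unifrac(
                m.values[0], m.values[1], taxa=ids, tree=sk_tree, normalized=True
            )
            assert ours == pytest.approx(float(ref), abs=1e-10)

    def test_branch_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        tree = random_tree(rng, 7)
        m = random_profiles(rng, tree.leaf_names(), n_samples=4)
        base = generalized_unifrac(tree, m).values
        for factor in (0.1, 3.0, 250.0):
            scaled = generalized_unifrac(tree.rescaled(factor), m).values
            assert np.allclose(base, scaled, atol=1e-12)

    def test_varies_continuously_in_alpha(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 6)
        m = random_profiles(rng, tree.leaf_names())
        alphas = np.linspace(0, 1, 21)
        vals = [generalized_unifrac(tree, m, alpha=a).values[0, 1] for a in alphas]
        assert max(abs(np.diff(vals))) < 0.1  # no jumps on a fine grid

    def test_compound_missing_from_tree_rejected(self):
        tree = _chain_tree()
        m = SampleCompoundMatrix(["s"], ["A", "Z"], np.array([[1.0, 1.0]]))
        with pytest.raises(ValidationError, match="Z"):
            generalized_unifrac(tree, m)

    def test_degenerate_zero_length_tree_rejected(self):
        root = TreeNode(height=0.0)
        for n in "AB":
            root.add_child(TreeNode(name=n, length=0.0))
        m = SampleCompoundMatrix(["s1", "s2"], ["A", "B"], np.array([[1.0, 0], [0.0, 1]]))
        with pytest.raises(ValidationError, match="degenerate"):
            generalized_unifrac(BiosynTree(root), m)


class TestBrayCurtis:
    def test_examples(self):
        m = SampleCompoundMatrix(
            ["s1", "s2", "s3", "s4"],
            ["a", "b", "c"],
            np.array([[1.0, 2, 0], [0.0, 2, 3], [1.0, 2, 0], [5.0, 0, 0]]),
        )
        d = bray_curtis(m).to_frame()
        assert d.loc["s1", "s2"] == pytest.approx(0.5)  # (1+0+3)/(1+4+3)
        assert d.loc["s1", "s3"] == 0.0  # identical rows
        assert d.loc["s2", "s4"] == 1.0  # disjoint supports
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestBioSynDist:
    def test_single_sample_gives_zero_matrix(self, hypothetical):
        m = hypothetical["samples"]
        one = SampleCompoundMatrix(m.sample_ids[:1], m.compound_ids, m.values[:1])
        res = biosyn_dist(one, hypothetical["enzymes"])
        assert res.distances.values.shape == (1, 1)
        assert res.distances.values[0, 0] == 0.0

    def test_pinene_swap_is_invisible(self, hypothetical):
        """Profiles differing only in two products of one terpene synthase
        are biosynthetically indistinguishable."""
        res = biosyn_dist(hypothetical["samples"], hypothetical["enzymes"])
        assert res.distances.to_frame().loc["E", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_shared_pathways_beat_shared_compounds(self, hypothetical):
        """C and D share no compound but the same two pathways: the
        biosynthetic distance is small where Bray-Curtis is maximal."""
        res = biosyn_dist(hypothetical["samples"], hypothetical["enzymes"])
        bio = standardize(res.distances).to_frame()
        conv = standardize(bray_curtis(hypothetical["samples"])).to_frame()
        assert conv.loc["C", "D"] == pytest.approx(1.0)
        assert bio.loc["C", "D"] < conv.loc["C", "D"]

    def test_intermediates_are_consistent(self, hypothetical):
        res = biosyn_dist(hypothetical["samples"], hypothetical["enzymes"])
        assert sorted(res.tree.leaf_names()) == sorted(hypothetical["samples"].compound_ids)
        assert res.compound_distances.ids == hypothetical["enzymes"].compound_ids
        assert res.tree.total_branch_length > 0
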