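"""Distances, NJ/UPGMA trees and PCoA: exactness and invariance properties."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix as SkDM
from skbio import TreeNode
from skbio.stats.ordination import pcoa as sk_pcoa
from skbio.tree import nj as sk_nj

from citrosat.diversity import (
    DistanceMatrix,
    distance_matrix,
    nj_tree,
    pcoa,
    upgma_tree,
)
from citrosat.stats import AlleleMatrix
from oracles import random_additive_distances


def _tip_distances(newick: str) -> dict:
    tree = TreeNode.read([newick])
    tips = [t.name for t in tree.tips()]
    out = {}
    dm = tree.tip_tip_distances()
    for a in tips:
        for b in tips:
            if a < b:
                out[(a, b)] = dm[a, b]
    return out


class TestDistanceMatrix:
    def _toy(self):
        genotypes = {
            ("L1", "a"): (1, 2), ("L1", "b"): (1, 2), ("L1", "c"): (3, 3),
            ("L2", "a"): (1, 1), ("L2", "b"): (1, 2), ("L2", "c"): (2, 2),
        }
        return AlleleMatrix(["L1", "L2"], ["a", "b", "c"], genotypes)

    def test_identical_samples_distance_zero(self):
        m = self._toy()
        D = distance_matrix(m)
        assert D["a", "a"] == 0.0

    def test_fully_disjoint_samples_distance_one(self):
        genotypes = {("L1", "x"): (1, 1), ("L1", "y"): (2, 2),
                     ("L2", "x"): (3, 3), ("L2", "y"): (4, 4)}
        D = distance_matrix(AlleleMatrix(["L1", "L2"], ["x", "y"], genotypes))
        assert D["x", "y"] == 1.0

    def test_hand_computed_shared_allele_proportions(self):
        D = distance_matrix(self._toy())
        # a vs b: L1 shares both alleles (1.0); L2 shares one of two (0.5)
        assert D["a", "b"] == pytest.approx(1 - (1.0 + 0.5) / 2)
        # a vs c: L1 shares none; L2 shares none
        assert D["a", "c"] == pytest.approx(1.0)
        # b vs c: L1 none; L2 shares one 2-allele
        assert D["b", "c"] == pytest.approx(1 - (0.0 + 0.5) / 2)

    def test_no_comparable_loci_rejected(self):
        genotypes = {("L1", "x"): (1, 1), ("L1", "y"): None,
                     ("L2", "x"): None, ("L2", "y"): (2, 2)}
        m = AlleleMatrix(["L1", "L2"], ["x", "y"], genotypes)
        with pytest.raises(ValueError, match="share no scored"):
            distance_matrix(m)

    def test_binary_metrics(self):
        genotypes = {("L1", "x"): 1, ("L1", "y"): 1,
                     ("L2", "x"): 1, ("L2", "y"): 0,
                     ("L3", "x"): 0, ("L3", "y"): 0}
        m = AlleleMatrix(["L1", "L2", "L3"], ["x", "y"], genotypes, mode="binary")
        assert distance_matrix(m, "simple_matching")["x", "y"] == pytest.approx(1 / 3)
        assert distance_matrix(m, "jaccard")["x", "y"] == pytest.approx(1 - 1 / 2)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


class TestNeighborJoining:
    def test_three_point_branch_lengths(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        newick = nj_tree(D).newick
        tree = TreeNode.read([newick])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_recovery_of_additive_ten_leaf_distances(self, seed):
        ids, M = random_additive_distances(np.random.default_rng(seed), 10)
        result = nj_tree(DistanceMatrix(ids, M))
        tips = _tip_distances(result.newick)
        for (a, b), d in tips.items():
            i, j = ids.index(a), ids.index(b)
            assert d == pytest.approx(M[i, j], abs=1e-9)

    def test_sample_order_invariance(self):
        ids, M = random_additive_distances(np.random.default_rng(99), 8)
        t1 = nj_tree(DistanceMatrix(ids, M))
        perm = [3, 0, 7, 2, 6, 1, 5, 4]
        t2 = nj_tree(DistanceMatrix([ids[i] for i in perm], M[np.ix_(perm, perm)]))
        assert t1.newick == t2.newick

    def test_topology_agrees_with_skbio(self):
        rng = np.random.default_rng(5)
        M = rng.random((9, 9))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"s{i}" for i in range(9)]
        mine = TreeNode.read([nj_tree(DistanceMatrix(ids, M)).newick])
        theirs = sk_nj(SkDM(M, ids))
        assert mine.compare_rfd(theirs) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))


def _node_depths(newick: str):
    tree = TreeNode.read([newick])
    depths = []
    for tip in tree.tips():
        depths.append(tip.accumulate_to_ancestor(tree))
    return depths


class TestUPGMA:
    def test_two_samples_cherry(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]], float))
        tree = TreeNode.read([upgma_tree(D).newick])
        assert {t.name: t.length for t in tree.tips()} == {"a": 0.2, "b": 0.2}

    def test_ultrametric_input_recovered_exactly(self):
        # heights: (a,b) join at 0.1, ((a,b),c) at 0.25, (((a,b),c),d) at 0.4
        ids = ["a", "b", "c", "d"]
        M = np.array(
            [
                [0.0, 0.2, 0.5, 0.8],
                [0.2, 0.0, 0.5, 0.8],
                [0.5, 0.5, 0.0, 0.8],
                [0.8, 0.8, 0.8, 0.0],
            ]
        )
        tree = TreeNode.read([upgma_tree(DistanceMatrix(ids, M)).newick])
        dm = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                assert dm[a, ids[j]] == pytest.approx(M[i, j], abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_output_is_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.random((7, 7))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"s{i}" for i in range(7)]
        depths = _node_depths(upgma_tree(DistanceMatrix(ids, M)).newick)
        assert max(depths) - min(depths) < 1e-9

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(17)
        M = rng.random((8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"s{i}" for i in range(8)]
        depths = _node_depths(upgma_tree(DistanceMatrix(ids, M)).newick)
        Z = average(squareform(M))
        assert max(depths) == pytest.approx(Z[-1, 2] / 2, abs=1e-9)

    def test_deterministic_tie_break(self):
        M = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        t1 = upgma_tree(DistanceMatrix(["b", "a", "c"], M)).newick
        t2 = upgma_tree(DistanceMatrix(["c", "b", "a"], M)).newick
        assert t1 == t2


class TestPCoA:
    def test_collinear_points_single_axis(self):
        # points at 0, 1, 3 on a line
        M = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], M), 3)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((12, 2)) * 10
        M = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        res = pcoa(DistanceMatrix(ids, M), 2)
        got = res.coordinates.to_numpy()
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, got)
        assert disparity < 1e-8
        back = np.sqrt(((got[:, None, :] - got[None, :, :]) ** 2).sum(-1))
        assert np.allclose(back, M, atol=1e-8)

    def test_duplicated_sample_identical_coordinates(self):
        M = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], float)
        res = pcoa(DistanceMatrix(["a", "a2", "b"], M), 2)
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["a2"])

    def test_eigenvalue_sum_equals_centered_inertia(self, rng):
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = DistanceMatrix([f"s{i}" for i in range(6)], M)
        res = pcoa(D, 5)
        n = 6
        A = -0.5 * M**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ A @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-9)

    def test_percent_variance_matches_skbio(self, rng):
        pts = rng.random((8, 3))
        M = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        res = pcoa(DistanceMatrix(ids, M), 3)
        theirs = sk_pcoa(SkDM(M, ids), number_of_dimensions=3)
        pct_theirs = 100 * theirs.proportion_explained.to_numpy()[:3]
        assert np.allclose(res.percent_variance, pct_theirs, atol=1e-6)
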