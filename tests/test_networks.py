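"""Neighbour-Net, fit statistics and Z-closure supernetworks."""

import subprocess

import numpy as np
import pytest

from conftest import canon_side

from plastophylo.io import Alignment, read_newick
from plastophylo.networks import (
    DistanceMatrix,
    fit_statistics,
    neighbor_net,
    p_distance_matrix,
    zclosure_supernetwork,
)
from plastophylo.simulate import random_tree
from plastophylo.splits import Split, SplitSystem, splits_from_tree


def tree_distance_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return DistanceMatrix(tuple(t.label for t in taxa), d)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(list("abcd"), ["ACGTACGT"] * 4)
        assert np.all(p_distance_matrix(aln).d == 0)

    def test_two_diffs_over_eight_comparable(self):
        aln = Alignment(["a", "b", "c", "d"],
                        ["ACGTACGTNN", "ACGAACGANN",
                         "ACGTACGTAC", "ACGTACGTAC"])
        dm = p_distance_matrix(aln)
        assert dm.d[0, 1] == pytest.approx(2 / 8)

    def test_agrees_with_marker_statistics(self):
        from plastophylo.markers import locus_stats
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        dm = p_distance_matrix(aln)
        iu = np.triu_indices(5, 1)
        assert float(dm.d[iu].mean()) == pytest.approx(
            locus_stats(aln).p_bar)

    def test_no_comparable_sites_raises(self):
        aln = Alignment(list("abcd"),
                        ["AC--", "--GT", "ACGT", "ACGT"])
        with pytest.raises(ValueError):
            p_distance_matrix(aln)


class TestNeighborNet:
    def test_quartet_tree_metric_recovers_exact_splits(self, tree_metric_case):
        taxa, d = tree_metric_case
        ss = neighbor_net(DistanceMatrix(taxa, d))
        weights = {canon_side(s.side, taxa): s.weight for s in ss.splits}
        expected = {
            frozenset("A"): 1.0, frozenset("B"): 2.0, frozenset("C"): 3.0,
            frozenset("D"): 4.0, frozenset(("A", "B")): 3.0,
        }
        assert set(weights) == set(expected)
        for k, v in expected.items():
            assert weights[k] == pytest.approx(v, abs=1e-8)

    def test_star_metric_keeps_only_trivial_splits(self):
        taxa = tuple("ABCDE")
        d = np.full((5, 5), 2.0)
        np.fill_diagonal(d, 0.0)
        ss = neighbor_net(DistanceMatrix(taxa, d))
        assert all(s.is_trivial(5) for s in ss.splits)

    def test_conflicting_quartet_produces_box(self):
        taxa = tuple("ABCD")
        d = np.array([[0, 4, 5, 7], [4, 0, 7, 5],
                      [5, 7, 0, 4], [7, 5, 4, 0]], float)
        ss = neighbor_net(DistanceMatrix(taxa, d))
        nontrivial = {canon_side(s.side, taxa): s.weight
                      for s in ss.nontrivial()}
        ab_cd = canon_side(("A", "B"), taxa)
        ac_bd = canon_side(("A", "C"), taxa)
        assert set(nontrivial) == {ab_cd, ac_bd}  # two incompatible splits
        assert nontrivial[ab_cd] == pytest.approx(3.0, abs=1e-8)
        assert nontrivial[ac_bd] == pytest.approx(2.0, abs=1e-8)

    def test_agrees_with_phangorn_reference_implementation(self):
        d = np.array([[0, 4, 5, 7], [4, 0, 7, 5],
                      [5, 7, 0, 4], [7, 5, 4, 0]], float)
        taxa = tuple("ABCD")
        ss = neighbor_net(DistanceMatrix(taxa, d))
        mine = {tuple(sorted(canon_side(s.side, taxa))): round(s.weight, 6)
                for s in ss.splits}
        r_code = (
            'suppressMessages(library(phangorn));'
            'd <- matrix(c(0,4,5,7,4,0,7,5,5,7,0,4,7,5,4,0),4,4);'
            'rownames(d) <- colnames(d) <- c("A","B","C","D");'
            'nn <- neighborNet(as.dist(d));'
            'w <- attr(nn$splits, "weights");'
            'labs <- attr(nn$splits, "labels");'
            'for (i in seq_along(nn$splits)) '
            'cat(paste(sort(labs[nn$splits[[i]]]), collapse=","), w[i], "\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", r_code],
                              capture_output=True, text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        theirs = {}
        for line in proc.stdout.strip().splitlines():
            side, w = line.strip().rsplit(" ", 1)
            theirs[tuple(sorted(canon_side(side.split(","), taxa)))] = \
                round(float(w), 6)
        assert mine == theirs

    @pytest.mark.parametrize("seed", range(6))
    def test_tree_metric_recovery_random_trees(self, seed):
        tree = random_tree(5 + seed, seed=500 + seed, height=1.0)
        dm = tree_distance_matrix(tree)
        ss = neighbor_net(dm)
        true = {canon_side(s, dm.taxa): w
                for s, w in splits_from_tree(tree).items()}
        got = {canon_side(s.side, dm.taxa): s.weight for s in ss.splits}
        assert set(got) == set(true)
        for k in true:
            assert got[k] == pytest.approx(true[k], abs=1e-6)
        assert ss.is_circular()
        fr = fit_statistics(dm, ss)
        assert fr.fit == pytest.approx(100.0, abs=1e-6)
        assert fr.lsfit == pytest.approx(100.0, abs=1e-6)

    def test_all_weights_nonnegative(self):
        rng = np.random.default_rng(77)
        d = rng.random((7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ss = neighbor_net(DistanceMatrix(tuple("ABCDEFG"), d))
        assert all(s.weight >= 0 for s in ss.splits)

    def test_dimension_filter_never_increases_lsfit(self):
        rng = np.random.default_rng(13)
        d = rng.random((8, 8)) + 0.5
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(tuple("ABCDEFGH"), d)
        unfiltered = neighbor_net(dm, max_dim=None)
        filtered = neighbor_net(dm, max_dim=2)
        assert fit_statistics(dm, unfiltered).lsfit >= \
            fit_statistics(dm, filtered).lsfit - 1e-9

    def test_rejects_asymmetric_input(self):
        d = np.zeros((4, 4))
        d[0, 1] = 1.0
        with pytest.raises(ValueError):
            DistanceMatrix(tuple("ABCD"), d)


class TestFitStatistics:
    def test_exact_representation_scores_100(self, tree_metric_case):
        taxa, d = tree_metric_case
        dm = DistanceMatrix(taxa, d)
        fr = fit_statistics(dm, neighbor_net(dm))
        assert fr.fit == pytest.approx(100.0)
        assert fr.lsfit == pytest.approx(100.0)

    def test_empty_system_scores_zero(self, tree_metric_case):
        taxa, d = tree_metric_case
        dm = DistanceMatrix(taxa, d)
        empty = SplitSystem(taxa, [Split(frozenset("A"), 0.0)])
        fr = fit_statistics(dm, empty)
        assert fr.fit == pytest.approx(0.0)

    def test_hand_computed_partial_system(self):
        # taxa A..D; only trivial splits with weight 1; d from the full tree
        taxa = tuple("ABCD")
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], float)
        splits = [Split(frozenset([t]), 1.0) for t in taxa]
        fr = fit_statistics(DistanceMatrix(taxa, d), SplitSystem(taxa, splits))
        # induced p = 2 for every pair; residuals: 4 pairs at 1, 2 at 0
        fit = 100 * (1 - 4 / 16)
        lsfit = 100 * (1 - 4 / (4 * 9 + 2 * 4))
        assert fr.fit == pytest.approx(fit)
        assert fr.lsfit == pytest.approx(lsfit)

    def test_all_zero_matrix_flagged_undefined(self):
        taxa = tuple("ABCD")
        dm = DistanceMatrix(taxa, np.zeros((4, 4)))
        fr = fit_statistics(dm, SplitSystem(taxa,
                                            [Split(frozenset("A"), 1.0)]))
        assert not fr.defined and fr.fit is None


class TestSupernetwork:
    def test_single_tree_returns_its_own_splits(self):
        t = read_newick("((A:1,B:2):1.5,(C:3,D:4):0.5,E:2);")
        ss = zclosure_supernetwork([t], seed=0)
        true = splits_from_tree(t)
        got = {canon_side(s.side, ss.taxa): s.weight for s in ss.splits}
        want = {canon_side(s, ss.taxa): w for s, w in true.items()}
        assert got == pytest.approx(want)

    def test_same_tree_twice_idempotent(self):
        t = read_newick("((A:1,B:2):1.5,(C:3,D:4):0.5,E:2);")
        one = zclosure_supernetwork([t], seed=0)
        two = zclosure_supernetwork([t, t], seed=0)
        assert {(s.side, round(s.weight, 9)) for s in one.splits} == \
            {(s.side, round(s.weight, 9)) for s in two.splits}

    def test_conflicting_partial_trees_make_a_box(self):
        t1 = read_newick("(((A,B),C),(D,P1));")
        t2 = read_newick("(((A,C),B),(D,P2));")
        ss = zclosure_supernetwork([t1, t2], orderings=10, seed=3)
        sides = {canon_side(s.side, ss.taxa) for s in ss.splits}
        taxa = set(ss.taxa)
        # both conflicting quartet splits completed to full splits
        assert canon_side(taxa - {"A", "B"}, ss.taxa) in sides
        assert canon_side(taxa - {"A", "C"}, ss.taxa) in sides

    def test_brute_force_closure_confirms_derivable_splits(self):
        # order-free closure: keep extending copies of all pairs to a fixpoint
        t1 = read_newick("(((A,B),C),(D,P1));")
        t2 = read_newick("(((A,C),B),(D,P2));")
        partials = []
        for t in (t1, t2):
            leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
            for side in splits_from_tree(t):
                partials.append((frozenset(side), leaves - side))
        pool = set(partials)
        changed = True
        while changed:
            changed = False
            for a1, b1 in list(pool):
                for a2, b2 in list(pool):
                    for x2, y2 in ((a2, b2), (b2, a2)):
                        if (a1 & x2) and (b1 & y2) and not (a1 & y2):
                            for cand in ((a1, b1 | y2), (a1 | x2, y2)):
                                if cand not in pool:
                                    pool.add(cand)
                                    changed = True
        taxa = frozenset(["A", "B", "C", "D", "P1", "P2"])
        full = {frozenset(a) for a, b in pool if a | b == taxa}
        assert {"C", "D", "P1", "P2"} in full or {"A", "B"} in full
        assert {"B", "D", "P1", "P2"} in full or {"A", "C"} in full

    def test_tree_order_invariance_with_many_orderings(self):
        t1 = read_newick("(((A,B),C),(D,E));")
        t2 = read_newick("((A,(B,F)),(C,D));")
        s12 = zclosure_supernetwork([t1, t2], orderings=30, seed=5)
        s21 = zclosure_supernetwork([t2, t1], orderings=30, seed=5)
        assert {s.side for s in s12.splits} == {s.side for s in s21.splits}
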