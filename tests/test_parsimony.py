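"""Mixed-character parsimony: scoring oracles, search, support, mapping."""

import numpy as np
import pytest

from conftest import (
    all_unrooted_adjacencies,
    brute_force_continuous_steps,
    brute_force_discrete_steps,
    canon_side,
)

from plastophylo.parsimony import (
    assemble_mixed_matrix,
    exact_search,
    map_synapomorphies,
    resample_support,
    strict_consensus_splits,
    tree_length,
)
from plastophylo.simulate import random_tree, simulate_mixed_dataset
from plastophylo.splits import splits_from_tree


class TestAssembly:
    def test_continuous_rescaled_to_unit_range(self):
        m = assemble_mixed_matrix(
            [("q", "continuous", {"A": [2.0], "B": [4.5], "C": [7.0]})],
            dummy_outgroup=False)
        col = m.columns[0]
        assert col.values == pytest.approx([0.0, 0.5, 1.0])
        assert m.partitions[0].ranges == [(2.0, 7.0)]

    def test_zero_range_character_excluded(self):
        m = assemble_mixed_matrix(
            [("q", "continuous", {"A": [3.0, 1.0], "B": [3.0, 2.0]})],
            dummy_outgroup=False)
        assert m.n_chars == 1  # the constant character is dropped

    def test_molecular_partition_widths_sum(self):
        parts = [
            (f"p{i}", "dna", {"t1": "A" * w, "t2": "C" * w})
            for i, w in enumerate([7727, 689, 813, 473])
        ]
        m = assemble_mixed_matrix(parts, dummy_outgroup=False)
        assert m.n_chars == 9702

    def test_absent_taxon_block_filled_with_missing(self):
        m = assemble_mixed_matrix(
            [("a", "binary", {"A": "01", "B": "10"}),
             ("b", "binary", {"A": "11"})],
            dummy_outgroup=False)
        b_row = [c.values[m.taxa.index("B")] for c in m.columns[2:]]
        assert b_row == [None, None]

    def test_dummy_outgroup_is_all_missing_by_default(self):
        m = assemble_mixed_matrix([("a", "binary", {"A": "01", "B": "10"})])
        og = m.taxa.index("outgroup")
        assert all(c.values[og] is None for c in m.columns)

    def test_gap_fifth_state_changes_scoring(self):
        vals = {"A": "A-", "B": "A-", "C": "AC", "D": "AC"}
        with_gap = assemble_mixed_matrix([("d", "dna", vals, True)],
                                         dummy_outgroup=False)
        without = assemble_mixed_matrix([("d", "dna", vals, False)],
                                        dummy_outgroup=False)
        t = "((A,B),(C,D));"
        assert tree_length(t, with_gap) == pytest.approx(1.0)
        assert tree_length(t, without) == pytest.approx(0.0)


class TestTreeLength:
    def test_fitch_textbook_patterns(self):
        m1 = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "1", "D": "1"})],
            dummy_outgroup=False)
        m2 = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "1", "C": "0", "D": "1"})],
            dummy_outgroup=False)
        t = "((A,B),(C,D));"
        assert tree_length(t, m1) == pytest.approx(1.0)
        assert tree_length(t, m2) == pytest.approx(2.0)

    def test_continuous_farris_collapse(self):
        m = assemble_mixed_matrix(
            [("c", "continuous",
              {"A": [0.0], "B": [0.0], "C": [1.0], "D": [1.0]})],
            dummy_outgroup=False)
        assert tree_length("((A,B),(C,D));", m) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_discrete_scores_match_state_enumeration(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        taxa = [chr(65 + i) for i in range(n_taxa)]
        states = ("0", "1", "2", "3", "4")[: rng.integers(2, 6)]
        vals = {t: "".join(rng.choice(list(states), 3)) for t in taxa}
        # plant a missing entry
        vals[taxa[0]] = "?" + vals[taxa[0]][1:]
        m = assemble_mixed_matrix([("u", "unordered", vals)],
                                  dummy_outgroup=False)
        trees = all_unrooted_adjacencies(n_taxa)
        for adj in trees[:: max(1, len(trees) // 7)]:
            total = tree_length(adj, m)
            expected = 0.0
            for j in range(3):
                leaf_states = {
                    i: set(states) if vals[taxa[i]][j] == "?"
                    else {vals[taxa[i]][j]}
                    for i in range(n_taxa)
                }
                expected += brute_force_discrete_steps(
                    adj, n_taxa, leaf_states, states)
            assert total == pytest.approx(expected)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_continuous_scores_match_grid_brute_force(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        taxa = [chr(65 + i) for i in range(n_taxa)]
        vals = {t: [float(np.round(rng.random(), 3))] for t in taxa}
        vals[taxa[-1]] = [None]
        m = assemble_mixed_matrix([("c", "continuous", vals)],
                                  dummy_outgroup=False)
        # recover the standardized leaf values used by the scorer
        col = m.columns[0]
        trees = all_unrooted_adjacencies(n_taxa)
        for adj in trees[:: max(1, len(trees) // 5)]:
            got = tree_length(adj, m)
            want = brute_force_continuous_steps(adj, n_taxa, col.values)
            assert got == pytest.approx(want, abs=1e-6)

    def test_multifurcating_tree_continuous_exact(self):
        # sequential interval merging is wrong on stars; the grid DP is used
        vals = {"A": [0.0], "B": [0.05], "C": [1.0], "D": [1.0]}
        m = assemble_mixed_matrix([("c", "continuous", vals)],
                                  dummy_outgroup=False)
        star = {0: {4}, 1: {4}, 2: {4}, 3: {4}, 4: {0, 1, 2, 3}}
        want = brute_force_continuous_steps(star, 4, m.columns[0].values)
        assert tree_length(star, m) == pytest.approx(want, abs=1e-9)

    def test_missing_leaf_never_forces_steps(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "0", "D": "?"})],
            dummy_outgroup=False)
        assert tree_length("((A,B),(C,D));", m) == pytest.approx(0.0)


class TestExactSearch:
    def test_homoplasy_free_matrix_recovers_generating_tree(self):
        tree = random_tree(8, seed=21)
        matrix, _, _ = simulate_mixed_dataset(
            tree, n_binary=15, n_continuous=0, seed=22, dummy_outgroup=False)
        res = exact_search(matrix)
        assert res.ci == pytest.approx(1.0)
        assert len(res.trees) == 1
        got = {canon_side(s, matrix.taxa)
               for s in strict_consensus_splits(res, matrix)}
        want = {canon_side(side, matrix.taxa)
                for side in splits_from_tree(tree)
                if 1 < len(side) < len(matrix.taxa) - 1}
        assert got == want

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(55)
        taxa = list("ABCDEF")
        for _ in range(5):
            vals = {t: "".join(rng.choice(list("01"), 8)) for t in taxa}
            cvals = {t: [float(np.round(rng.random(), 3))] for t in taxa}
            m = assemble_mixed_matrix(
                [("b", "binary", vals), ("c", "continuous", cvals)],
                dummy_outgroup=False)
            res = exact_search(m)
            best = min(tree_length(adj, m)
                       for adj in all_unrooted_adjacencies(6))
            assert res.score == pytest.approx(best)

    def test_invariant_characters_flag_undefined_ci(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {t: "000" for t in "ABCDE"})],
            dummy_outgroup=False)
        res = exact_search(m)
        assert res.score == pytest.approx(0.0)
        assert res.ci is None

    def test_score_invariant_to_taxon_and_character_order(self):
        rng = np.random.default_rng(17)
        taxa = list("ABCDEFG")
        vals = {t: "".join(rng.choice(list("01"), 10)) for t in taxa}
        m = assemble_mixed_matrix([("b", "binary", vals)],
                                  dummy_outgroup=False)
        res = exact_search(m)
        flipped_vals = {t: vals[t][::-1] for t in reversed(taxa)}
        m2 = assemble_mixed_matrix([("b", "binary", flipped_vals)],
                                   dummy_outgroup=False)
        assert exact_search(m2).score == pytest.approx(res.score)

    def test_duplicated_character_preserves_ci_ri(self):
        rng = np.random.default_rng(31)
        taxa = list("ABCDEF")
        vals = {t: "".join(rng.choice(list("01"), 6)) for t in taxa}
        m = assemble_mixed_matrix([("b", "binary", vals)],
                                  dummy_outgroup=False)
        doubled = assemble_mixed_matrix(
            [("b", "binary", {t: v + v for t, v in vals.items()})],
            dummy_outgroup=False)
        r1, r2 = exact_search(m), exact_search(doubled)
        assert r2.score == pytest.approx(2 * r1.score)
        assert r2.ci == pytest.approx(r1.ci)
        assert r2.ri == pytest.approx(r1.ri)

    def test_too_many_taxa_refused(self):
        vals = {f"t{i}": "01" for i in range(16)}
        m = assemble_mixed_matrix([("b", "binary", vals)],
                                  dummy_outgroup=False)
        with pytest.raises(ValueError, match="exact-search"):
            exact_search(m)


class TestResampling:
    def test_strong_signal_clades_highly_supported(self):
        tree = random_tree(8, seed=41)
        matrix, _, _ = simulate_mixed_dataset(
            tree, n_binary=50, n_continuous=0, seed=42, dummy_outgroup=False)
        support = resample_support(matrix, "bootstrap", reps=200, seed=43)
        true = {canon_side(s, matrix.taxa)
                for s in splits_from_tree(tree)
                if 1 < len(s) < len(matrix.taxa) - 1}
        sup = {canon_side(k, matrix.taxa): v for k, v in support.items()}
        for clade in true:
            assert sup.get(clade, 0.0) >= 95.0

    def test_single_character_jackknife_retention(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "1", "D": "1"})],
            dummy_outgroup=False)
        support = resample_support(m, "jackknife", p=0.36, reps=1000, seed=7)
        (clade, pct), = support.items()
        # retention probability 1 - p = 0.64; +-4 covers ~2.6 binomial SD
        assert pct == pytest.approx(64.0, abs=4.0)

    def test_seeded_determinism(self):
        m = assemble_mixed_matrix(
            [("b", "binary",
              {"A": "0011", "B": "0011", "C": "1100", "D": "1101",
               "E": "1110"})],
            dummy_outgroup=False)
        s1 = resample_support(m, "bootstrap", reps=50, seed=9)
        s2 = resample_support(m, "bootstrap", reps=50, seed=9)
        assert s1 == s2

    def test_invalid_reps_raises(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "1", "D": "1"})],
            dummy_outgroup=False)
        with pytest.raises(ValueError):
            resample_support(m, "bootstrap", reps=0)


class TestSynapomorphies:
    def test_unique_change_on_clade_stem(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "1", "D": "1"})],
            outgroup_coding="primitive")
        smap = map_synapomorphies("((A,B),(C,D),outgroup);", m)
        un = smap.unambiguous()
        assert len(un) == 1
        clade, char, frm, to, amb = un[0]
        assert clade == frozenset({"C", "D"})
        assert (frm, to) == ("0", "1")

    def test_homoplastic_pattern_is_ambiguous(self):
        # with an uninformative ('?') outgroup, 0101 admits two MP
        # reconstructions with disjoint change placements
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "1", "C": "0", "D": "1"})])
        smap = map_synapomorphies("((A,B),(C,D),outgroup);", m)
        assert smap.unambiguous() == []

    def test_planted_map_recovered_exactly(self):
        tree = random_tree(9, seed=61)
        matrix, planted, rooted = simulate_mixed_dataset(
            tree, n_binary=12, n_continuous=4, seed=62)
        smap = map_synapomorphies(rooted, matrix)
        got = {(char, clade) for clade, char, _, _, amb in smap.unambiguous()}
        want = {(char, clade) for char, clade, _, _ in planted}
        assert want <= got
        # directions match for the discrete characters
        by_key = {(char, clade): (frm, to)
                  for clade, char, frm, to, _ in smap.unambiguous()}
        for char, clade, frm, to in planted:
            if char.startswith("binary"):
                assert by_key[(char, clade)] == (frm, to)

    def test_missing_outgroup_raises(self):
        m = assemble_mixed_matrix(
            [("b", "binary", {"A": "0", "B": "0", "C": "1", "D": "1"})],
            dummy_outgroup=False)
        with pytest.raises(ValueError):
            map_synapomorphies("((A,B),(C,D));", m)
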