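"""Fitch parsimony, exhaustive search, tree statistics and bootstrap."""

import math
import random

import pytest

from karyophy.characters import CharacterDefinition, CharacterMatrix
from karyophy.parsimony import (
    MaxParsimony,
    bootstrap,
    enumerate_trees,
    exhaustive_search,
    fitch_steps,
    n_unrooted_topologies,
    round_half_up,
    tree_stats,
)
from karyophy.trees import read_newick

from conftest import brute_force_char_steps


def _matrix(taxa, columns):
    chars = [CharacterDefinition(f"c{j+1}", f"c{j+1}") for j in range(len(columns))]
    states = [[col[i] for col in columns] for i in range(len(taxa))]
    return CharacterMatrix(list(taxa), chars, states)


class TestFitch:
    def test_constant_column_needs_no_steps(self):
        taxa = list("ABCDE")
        m = _matrix(taxa, ["11111"])
        for t in enumerate_trees(taxa):
            assert fitch_steps(t, m).total_steps == 0

    def test_clean_bipartition_needs_one_step(self):
        m = _matrix(list("ABCDE"), ["11000"])
        t = read_newick("((A,B),(C,D),E);")
        assert fitch_steps(t, m).total_steps == 1

    def test_score_is_rooting_invariant(self):
        m = _matrix(list("ABCDE"), ["10110", "01?10", "11000"])
        t = read_newick("((A,B),(C,D),E);")
        rooted = read_newick("((A,B),((C,D),E));")
        assert fitch_steps(t, m).total_steps == fitch_steps(rooted, m).total_steps

    def test_missing_data_is_free(self):
        m = _matrix(list("ABCD"), ["1?00"])
        t = read_newick("((A,B),C,D);")
        assert fitch_steps(t, m).total_steps == 1

    def test_leaf_mismatch_is_an_error(self):
        m = _matrix(list("ABC"), ["110"])
        with pytest.raises(ValueError):
            fitch_steps(read_newick("(A,B,D);"), m)

    def test_matches_brute_force_on_random_instances(self):
        """Oracle equivalence on seeded random <=6-taxon instances."""
        rng = random.Random(2024)
        for _ in range(60):
            n = rng.choice([4, 5, 6])
            taxa = [f"T{i}" for i in range(n)]
            pool = list(enumerate_trees(taxa))
            tree = rng.choice(pool)
            cols = []
            for _ in range(4):
                col = [rng.choice("01?") for _ in range(n)]
                if all(s == "?" for s in col):
                    col[0] = "1"
                cols.append("".join(col))
            m = _matrix(taxa, cols)
            score = fitch_steps(tree, m)
            for j in range(4):
                expect = brute_force_char_steps(tree, m.column(j))
                assert score.per_character_steps[j] == expect

    def test_per_character_steps_respect_bounds(self):
        rng = random.Random(5)
        taxa = [f"T{i}" for i in range(6)]
        pool = list(enumerate_trees(taxa))
        for _ in range(20):
            tree = rng.choice(pool)
            col = "".join(rng.choice("01") for _ in range(6))
            m = _matrix(taxa, [col])
            s = fitch_steps(tree, m).total_steps
            n0, n1 = col.count("0"), col.count("1")
            lo = 1 if (n0 and n1) else 0
            assert lo <= s <= min(n0, n1) or (min(n0, n1) == 0 and s == 0)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105), (7, 945)])
    def test_counts_match_double_factorial(self, n, count):
        taxa = [f"T{i}" for i in range(n)]
        trees = list(enumerate_trees(taxa))
        assert len(trees) == count == n_unrooted_topologies(n)
        assert len(set(trees)) == count  # pairwise distinct topologies

    def test_cap_refusal_mentions_heuristics(self):
        taxa = [f"T{i}" for i in range(11)]
        with pytest.raises(ValueError, match="heuristic"):
            list(enumerate_trees(taxa))


class TestTreeStats:
    def test_homoplasy_free_limit(self):
        m = _matrix(list("ABCD"), ["1100", "1000"])
        st = tree_stats(m, s=2)  # s == m
        assert st.ci == 1.0 and st.hi == 0.0 and st.ri == 1.0

    def test_printed_profile_reproduces_published_indices(self):
        """33 single-step + 11 two-state characters give m=44, g=55; at
        s=45 the indices print as 0.978 / 0.909 / 0.022."""
        cols = ["10000"] * 33 + ["11000"] * 11
        m = _matrix(list("ABCDE"), cols)
        st = tree_stats(m, 45).rounded()
        assert (st.m, st.g) == (44, 55)
        assert (st.ci, st.ri, st.hi) == (0.978, 0.909, 0.022)

    def test_indices_invariant_under_column_permutation(self):
        rng = random.Random(11)
        cols = ["10110", "01100", "11?00", "10000", "11110"]
        m = _matrix(list("ABCDE"), cols)
        res = exhaustive_search(m)
        for _ in range(5):
            shuffled = cols[:]
            rng.shuffle(shuffled)
            res2 = exhaustive_search(_matrix(list("ABCDE"), shuffled))
            assert res2.length == res.length
            assert res2.stats == res.stats

    def test_hi_plus_ci_is_one_exactly(self):
        rng = random.Random(3)
        for _ in range(10):
            cols = []
            for _ in range(6):
                col = [rng.choice("01") for _ in range(5)]
                if len(set(col)) == 1:
                    col[0] = "1" if col[0] == "0" else "0"
                cols.append("".join(col))
            m = _matrix(list("ABCDE"), cols)
            res = exhaustive_search(m)
            assert res.stats.hi + res.stats.ci == 1.0
            assert res.stats.m <= res.length <= res.stats.g

    def test_s_below_minimum_is_an_error(self):
        m = _matrix(list("ABCD"), ["1100"])
        with pytest.raises(ValueError):
            tree_stats(m, 0)

    def test_undefined_retention_index_warns(self):
        # one autapomorphic column: g == m == 1; pretend s = 2
        m = _matrix(list("ABCD"), ["1000"])
        with pytest.warns(UserWarning, match="retention index"):
            st = tree_stats(m, 2)
        assert math.isnan(st.ri)

    def test_round_half_up(self):
        assert round_half_up(44 / 45) == 0.978
        assert round_half_up(0.0225) == 0.023
        assert round_half_up(10 / 11) == 0.909


class TestExhaustiveSearch:
    def test_fixture_mp_trees_all_contain_ccr_cut(self, fixture_matrix):
        res = exhaustive_search(fixture_matrix)
        assert res.n_trees_examined == 15
        assert all(t.has_bipartition({"CCR", "CUT"}) for t in res.mp_trees)
        assert not any(t.has_bipartition({"PIR", "CUT"}) for t in res.mp_trees)

    def test_constant_matrix_ties_all_topologies(self):
        m = _matrix(list("ABCDE"), ["11111", "11111"])
        res = exhaustive_search(m)
        assert res.length == 0 and len(res.mp_trees) == 15

    def test_search_length_equals_minimum_over_enumeration(self):
        rng = random.Random(99)
        cols = []
        for _ in range(8):
            col = [rng.choice("01?") for _ in range(6)]
            if all(s == "?" for s in col):
                col[0] = "1"
            cols.append("".join(col))
        taxa = [f"T{i}" for i in range(6)]
        m = _matrix(taxa, cols)
        res = exhaustive_search(m)
        lengths = {
            t: fitch_steps(t, m).total_steps for t in enumerate_trees(taxa)
        }
        assert res.length == min(lengths.values())
        assert set(res.mp_trees) == {
            t for t, L in lengths.items() if L == res.length
        }


class TestBootstrap:
    def test_same_seed_gives_identical_support(self, fixture_matrix):
        a = bootstrap(fixture_matrix, n_replicates=50, seed=13)
        b = bootstrap(fixture_matrix, n_replicates=50, seed=13)
        assert a.support == b.support

    def test_unanimous_signal_gets_full_support(self):
        m = _matrix(list("ABCDE"), ["11000"] * 20)
        bs = bootstrap(m, n_replicates=50, seed=1)
        assert bs.percentage({"A", "B"}) == 100.0

    def test_trivial_bipartitions_report_100(self, fixture_matrix):
        bs = bootstrap(fixture_matrix, n_replicates=10, seed=2)
        assert bs.percentage({"PIR"}) == 100.0
        assert bs.percentage(set(fixture_matrix.taxa) - {"PIR"}) == 100.0

    def test_sister_pair_beats_any_pir_cut_grouping(self, fixture_matrix):
        bs = bootstrap(fixture_matrix, n_replicates=200, seed=42)
        ccr_cut = bs.percentage({"CCR", "CUT"})
        assert ccr_cut > 0
        assert ccr_cut > bs.percentage({"PIR", "CUT"})
        assert ccr_cut > bs.support.get(frozenset({"PIR", "CUT", "BAR"}), 0.0)

    def test_replicate_count_must_be_positive(self, fixture_matrix):
        with pytest.raises(ValueError):
            bootstrap(fixture_matrix, n_replicates=0, seed=1)


class TestModelObjects:
    def test_fit_reports_single_mp_tree_and_summary(self, fixture_matrix):
        results = MaxParsimony(fixture_matrix).fit()
        assert len(results.mp_trees) == 1
        text = results.summary()
        assert "Most parsimonious trees  1" in text
        assert f"Tree length (s)          {results.length}" in text

    def test_rooted_tree_places_pithecia_basal(self, fixture_matrix):
        results = MaxParsimony(fixture_matrix).fit()
        rooted = results.rooted_tree({"BAR", "CAP"})
        assert rooted == read_newick("((BAR,CAP),(PIR,(CCR,CUT)));")

    def test_annotated_newick_carries_support_labels(self, fixture_matrix):
        results = MaxParsimony(fixture_matrix).fit()
        bs = results.bootstrap(n_replicates=30, seed=3)
        nwk = results.annotated_newick({"BAR", "CAP"}, bs)
        assert nwk.endswith(";") and any(ch.isdigit() for ch in nwk)

    def test_from_dataframe(self, fixture_matrix):
        df = fixture_matrix.to_dataframe()
        model = MaxParsimony.from_dataframe(df)
        assert model.fit().length == MaxParsimony(fixture_matrix).fit().length
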