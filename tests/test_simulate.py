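"""Synthetic data generators and the end-to-end recovery experiment."""

import itertools
import math

import numpy as np
import pytest

from karyophy.simulate import (
    CharacterSimConfig,
    KaryotypeSimConfig,
    ancestral_platyrrhini_karyotype,
    recovery_experiment,
    simulate_characters,
    simulate_karyotype_evolution,
)
from karyophy.synteny import count_signals, detect_associations
from karyophy.karyotype import validate_map
from karyophy.trees import read_newick


def analytic_p_variable(p: float) -> float:
    """Exact probability that a character is variable on the balanced
    5-taxon tree: enumeration over all 2^7 per-branch flip patterns,
    independent of the simulator's code path."""
    branches = ["cu", "uA", "uB", "cv", "vC", "vD", "cE"]
    paths = {
        "A": ("cu", "uA"), "B": ("cu", "uB"),
        "C": ("cv", "vC"), "D": ("cv", "vD"), "E": ("cE",),
    }
    pvar = 0.0
    for flips in itertools.product((0, 1), repeat=7):
        prob = 1.0
        for f in flips:
            prob *= p if f else (1 - p)
        fl = dict(zip(branches, flips))
        states = {t: sum(fl[b] for b in paths[t]) % 2 for t in paths}
        if len(set(states.values())) > 1:
            pvar += prob
    return pvar


class TestCharacterSimulation:
    def test_same_seed_is_bit_identical(self, balanced5):
        cfg = CharacterSimConfig(tree=balanced5, n_characters=40, seed=9)
        m1, f1 = simulate_characters(cfg)
        m2, f2 = simulate_characters(cfg)
        assert m1 == m2 and f1 == f2

    def test_zero_change_probability_gives_constant_columns(self, balanced5):
        cfg = CharacterSimConfig(
            tree=balanced5, n_characters=25, change_prob=0.0,
            root_state_prob=1.0, seed=4,
        )
        m, flips = simulate_characters(cfg)
        assert flips == []
        for row in m.states:
            assert row == ["1"] * 25

    def test_variable_fraction_matches_exact_enumeration(self, balanced5):
        p = 0.05
        n = 4000
        cfg = CharacterSimConfig(
            tree=balanced5, n_characters=n, change_prob=p, seed=17
        )
        m, _ = simulate_characters(cfg)
        frac = sum(
            1 for j in range(n) if len({r[j] for r in m.states}) > 1
        ) / n
        expect = analytic_p_variable(p)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se

    def test_flip_record_explains_leaf_states(self, balanced5):
        """Every leaf state is the root state XORed with the flips on its
        root path, so the record and the matrix must agree on parity."""
        cfg = CharacterSimConfig(
            tree=balanced5, n_characters=30, change_prob=0.2,
            root_state_prob=0.0, seed=6,
        )
        m, flips = simulate_characters(cfg)
        for j in range(30):
            for taxon in m.taxa:
                n_on_path = sum(
                    1 for b, jj in flips
                    if jj == j and taxon in b.split("|")
                )
                assert m.state(taxon, j) == str(n_on_path % 2)

    def test_invalid_configs_are_rejected(self, balanced5):
        with pytest.raises(ValueError):
            CharacterSimConfig(tree=balanced5, n_characters=0)
        with pytest.raises(ValueError):
            CharacterSimConfig(tree=balanced5, n_characters=1, change_prob=0.6)


class TestKaryotypeSimulation:
    def test_zero_events_leave_the_ancestral_karyotype(self, balanced5):
        cfg = KaryotypeSimConfig(tree=balanced5, mean_events=0.0, seed=1)
        maps, truth, events = simulate_karyotype_evolution(cfg)
        assert events == [] and truth.n_characters == 0
        for m in maps.values():
            forms = sorted(a.form.label for a in detect_associations(m))
            assert forms == sorted(
                ["3a/21", "5/7a", "2b/16b", "8a/18", "14/15a", "10a/16a"]
            )
            assert len(m.autosomes()) == 22

    def test_segment_conservation_across_the_tree(self, balanced5):
        cfg = KaryotypeSimConfig(tree=balanced5, mean_events=3.0, seed=23)
        maps, truth, events = simulate_karyotype_evolution(cfg)
        n_segments = len(ancestral_platyrrhini_karyotype().all_segments())
        for taxon, m in maps.items():
            assert validate_map(m) == []
            labels = sorted(
                s.label for c in m.chromosomes for s in c.segments
                if s.probe_chrom != "X"
            )
            assert len(labels) == n_segments
            assert count_signals(m).total_autosomal == n_segments

    def test_fusions_conserve_signals_and_reduce_chromosome_count(self, balanced5):
        cfg = KaryotypeSimConfig(
            tree=balanced5, mean_events=1.0, seed=8,
            event_weights={"centric_fusion": 1.0},
        )
        maps, truth, events = simulate_karyotype_evolution(cfg)
        base = ancestral_platyrrhini_karyotype()
        for taxon, m in maps.items():
            n_events_on_path = sum(
                1 for ev in events if taxon in ev.branch.split("|")
            )
            assert len(m.autosomes()) == len(base.autosomes) - n_events_on_path
            assert count_signals(m).total_autosomal == len(base.all_segments())

    def test_forced_translocation_creates_x1x2y(self, balanced5):
        cfg = KaryotypeSimConfig(
            tree=balanced5, mean_events=1.0, seed=3,
            event_weights={"sex_autosome_translocation": 1.0},
        )
        maps, _, events = simulate_karyotype_evolution(cfg)
        assert any(ev.type == "sex_autosome_translocation" for ev in events)
        for ev in events:
            for taxon in ev.branch.split("|"):
                m = maps[taxon]
                assert m.sex_system == "X1X2Y"
                assert m.diploid_number_male == m.diploid_number_female - 1
                assert m.chromosome("Y").is_y_composite

    def test_determinism(self, balanced5):
        cfg = KaryotypeSimConfig(tree=balanced5, mean_events=2.0, seed=77)
        a = simulate_karyotype_evolution(cfg)
        b = simulate_karyotype_evolution(cfg)
        assert a[1] == b[1]
        assert [e.label for e in a[2]] == [e.label for e in b[2]]

    def test_bad_weights_are_rejected(self, balanced5):
        with pytest.raises(ValueError):
            KaryotypeSimConfig(tree=balanced5, event_weights={"bogus": 1.0})
        with pytest.raises(ValueError):
            KaryotypeSimConfig(tree=balanced5, event_weights={"centric_fusion": 0.0})


class TestRecovery:
    def test_no_variation_reports_undefined(self, balanced5):
        cfg = CharacterSimConfig(
            tree=balanced5, n_characters=10, change_prob=0.0, seed=1
        )
        rep = recovery_experiment(cfg, n_runs=5, seed=1)
        assert not rep.defined and rep.n_undefined == 5
        assert math.isnan(rep.recovery_fraction)

    def test_unique_recovery_with_many_informative_characters(self, balanced5):
        """With >= 20 informative characters per run (p = 0.1, 200
        characters) the generating topology is the unique MP tree in at
        least 95% of runs."""
        cfg = CharacterSimConfig(
            tree=balanced5, n_characters=200, change_prob=0.1
        )
        rep = recovery_experiment(cfg, n_runs=100, seed=1)
        assert rep.unique_recovery_fraction >= 0.95
        assert rep.mean_rf < 0.5

    def test_recovery_degrades_with_event_saturation(self, balanced5):
        """Parsimony recovers the topology more often at 2 rearrangements
        per branch than at 8 (signal saturation produces homoplasy)."""
        lo = recovery_experiment(
            KaryotypeSimConfig(tree=balanced5, mean_events=2.0), n_runs=60,
            seed=5,
        )
        hi = recovery_experiment(
            KaryotypeSimConfig(tree=balanced5, mean_events=8.0), n_runs=60,
            seed=5,
        )
        assert lo.recovery_fraction > hi.recovery_fraction

    def test_karyotype_recovery_runs_end_to_end(self, balanced5):
        rep = recovery_experiment(
            KaryotypeSimConfig(tree=balanced5, mean_events=2.0), n_runs=20,
            seed=11,
        )
        assert rep.n_evaluated > 0
        assert 0.0 <= rep.recovery_fraction <= 1.0
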