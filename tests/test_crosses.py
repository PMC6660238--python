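"""Cross phenotyping, F1 selection, interaction classification."""

import math

import numpy as np
import pytest

import spoksim as sp
from spoksim.crosses import (DOMINANCE, MUTUAL_KILLING, MUTUAL_RESISTANCE,
                             SAME_TYPE, NoF1Available)

from conftest import single_locus_cross


class TestSimulateCross:
    def test_knockin_at_centromere_kills_every_ascus(self, model, registry,
                                                     spok_map):
        """PaPKS1 is tightly centromere-linked (d=0): killing is exactly 100%."""
        papks1 = spok_map.by_name["papks1"]
        dspok2 = sp.knockout(registry.genotype_of("s"), "Spok2")
        ki = sp.knockin(dspok2, model.allele("Spok3"), papks1)
        res = sp.simulate_cross(ki, dspok2, spok_map, model, 2000, seed=1)
        assert res.killing_pct == 100.0
        assert res.counts[2] == 2000

    def test_spok2_cross_killing_matches_calibration(self, model, registry,
                                                     spok_map):
        """s x ΔSpok2 reproduces the observed ~40.6% two-spored asci."""
        n = 30000
        s = registry.genotype_of("s")
        dspok2 = sp.knockout(s, "Spok2")
        res = sp.simulate_cross(s, dspok2, spok_map, model, n, seed=2)
        se = 100 * math.sqrt(0.406 * 0.594 / n)
        assert abs(res.killing_pct - 40.6) < 3 * se

    def test_null_cross_no_killing(self, model, registry, spok_map):
        res = sp.simulate_cross(registry.genotype_of("Wa46"),
                                registry.genotype_of("Wa47"),
                                spok_map, model, 500, seed=3)
        assert res.killing_pct == 0.0
        assert res.counts[4] == 500

    def test_n_asci_domain(self, model, registry, spok_map):
        with pytest.raises(ValueError):
            sp.simulate_cross(registry.genotype_of("S"),
                              registry.genotype_of("S"),
                              spok_map, model, 0, seed=1)

    def test_policies_differ_only_by_three_spored(self, model):
        import dataclasses
        model_q = dataclasses.replace(model, penetrance={"Spok3": 0.7})
        locus, gmap, killer, null = single_locus_cross(0.3, model_q)
        res = sp.simulate_cross(killer, null, gmap, model_q, 5000, seed=4)
        assert res.counts[3] > 0
        assert res.killing_pct_include3 < res.killing_pct


class TestExpectedDistribution:
    @pytest.mark.parametrize("f,q,expected", [
        (0.4, 1.0, (0.4, 0.0, 0.6)),
        (0.5, 0.0, (0.0, 0.0, 1.0)),
        (0.4, 0.8, (0.256, 0.128, 0.616)),
    ])
    def test_plug_in_values(self, f, q, expected):
        assert sp.expected_ascus_distribution(f, q) == pytest.approx(expected)

    def test_domain_errors(self):
        for f, q in ((-0.1, 0.5), (0.5, 1.2)):
            with pytest.raises(ValueError):
                sp.expected_ascus_distribution(f, q)

    def test_matches_simulation(self, model):
        import dataclasses
        f, q = 0.4, 0.8
        d = sp.distance_for_fds(f)
        model_q = dataclasses.replace(model, penetrance={"Spok3": q})
        locus, gmap, killer, null = single_locus_cross(d, model_q)
        n = 30000
        res = sp.simulate_cross(killer, null, gmap, model_q, n, seed=5)
        p2, p3, p4 = sp.expected_ascus_distribution(f, q)
        for klass, p in ((2, p2), (3, p3), (4, p4)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(res.fraction(klass) - p) < 3.5 * se


class TestF1Selection:
    def test_f1_from_psk1_x_psks_carries_spok2_and_block(self, model,
                                                         registry, spok_map):
        p1 = registry.genotype_of("Wa53")
        p2 = registry.genotype_of("S")
        rng = np.random.default_rng(6)
        for _ in range(5):
            f1 = sp.select_f1_from_two_spored(p1, p2, spok_map, model, rng)
            homologs = {a.homolog for a in f1.all_alleles()}
            assert homologs == {"Spok2", "Spok3", "Spok4"}
            assert spok_map.by_name["block_3L"] in f1.alleles

    def test_same_locus_mutual_killers_have_no_f1(self, model, registry,
                                                  spok_map):
        """Only empty (and four-spored) asci: no F1 obtainable."""
        papks1 = spok_map.by_name["papks1"]
        dspok2 = sp.knockout(registry.genotype_of("s"), "Spok2")
        ki3 = sp.knockin(dspok2, model.allele("Spok3"), papks1, name="ki3")
        ki4 = sp.knockin(dspok2, model.allele("Spok4"), papks1, name="ki4")
        rng = np.random.default_rng(7)
        with pytest.raises(NoF1Available) as err:
            sp.select_f1_from_two_spored(ki3, ki4, spok_map, model, rng,
                                         max_attempts=300)
        assert err.value.saw_killed_asci

    def test_no_killing_cross_has_no_f1(self, model, registry, spok_map):
        rng = np.random.default_rng(8)
        with pytest.raises(NoF1Available) as err:
            sp.select_f1_from_two_spored(registry.genotype_of("S"),
                                         registry.genotype_of("Wa63"),
                                         spok_map, model, rng,
                                         max_attempts=300)
        assert not err.value.saw_killed_asci


class TestClassification:
    def test_same_genotype_is_same_type(self, model, registry, spok_map):
        for name in ("S", "Wa53", "Wa46"):
            g = registry.genotype_of(name)
            call = sp.classify_interaction(g, g, spok_map, model,
                                           n_asci=400, seed=9)
            assert call.verdict == SAME_TYPE

    def test_psk1_psk7_mutual_resistance_despite_direct_killing(
            self, model, registry, spok_map):
        """Same three Spok genes at different block positions: the direct
        cross kills (the blocks can co-segregate away from two spores) yet
        the F1 design resolves the pair as mutually resistant."""
        p1 = registry.genotype_of("Wa53")
        p7 = registry.genotype_of("Wa58")
        direct = sp.simulate_cross(p1, p7, spok_map, model, 2000, seed=10)
        assert direct.killing_observed()
        call = sp.classify_interaction(p1, p7, spok_map, model,
                                       n_asci=800, seed=10)
        assert call.verdict == MUTUAL_RESISTANCE

    def test_psk7_dominates_psk8(self, model, registry, spok_map):
        call = sp.classify_interaction(registry.genotype_of("Wa58"),
                                       registry.genotype_of("Wa100"),
                                       spok_map, model, n_asci=800, seed=11)
        assert call.verdict == DOMINANCE
        assert call.dominant == "Wa58"

    def test_psk5_psks_mutual_killing(self, model, registry, spok_map):
        call = sp.classify_interaction(registry.genotype_of("Y"),
                                       registry.genotype_of("S"),
                                       spok_map, model, n_asci=800, seed=12)
        assert call.verdict == MUTUAL_KILLING

    def test_spok3_spok4_knockins_mutual_killing_empty_asci(
            self, model, registry, spok_map):
        papks1 = spok_map.by_name["papks1"]
        dspok2 = sp.knockout(registry.genotype_of("s"), "Spok2")
        ki3 = sp.knockin(dspok2, model.allele("Spok3"), papks1, name="ki3")
        ki4 = sp.knockin(dspok2, model.allele("Spok4"), papks1, name="ki4")
        call = sp.classify_interaction(ki3, ki4, spok_map, model,
                                       n_asci=400, seed=13)
        assert call.verdict == MUTUAL_KILLING

    def test_symmetry_up_to_relabeling(self, model, registry, spok_map):
        a = registry.genotype_of("Wa58")
        b = registry.genotype_of("Wa100")
        ab = sp.classify_interaction(a, b, spok_map, model, n_asci=600,
                                     seed=14)
        ba = sp.classify_interaction(b, a, spok_map, model, n_asci=600,
                                     seed=15)
        assert ab.verdict == ba.verdict == DOMINANCE
        assert ab.dominant == ba.dominant == "Wa58"

    def test_spok1_epistasis_dominates_psks(self, model, registry, spok_map):
        """Spok1 kills through Spok2 and resists it: T_D dominates Psk-S."""
        call = sp.classify_interaction(registry.genotype_of("T_D"),
                                       registry.genotype_of("S"),
                                       spok_map, model, n_asci=800, seed=16)
        assert call.verdict == DOMINANCE
        assert call.dominant == "T_D"

    def test_spok1_mutual_resistance_with_psk5(self, model, registry,
                                               spok_map):
        """Spok4 resists Spok1 and vice versa: T_D and a Psk-5 strain are
        mutually resistant (note the Psk-5 strain carries Spok3, which Spok1
        kills through, but Spok4 sits in the same block)."""
        call = sp.classify_interaction(registry.genotype_of("T_D"),
                                       registry.genotype_of("Y"),
                                       spok_map, model, n_asci=800, seed=17)
        assert call.verdict == MUTUAL_RESISTANCE


class TestHierarchy:
    def test_single_genotype_trivial_graph(self, model, registry, spok_map):
        h = sp.build_hierarchy([registry.genotype_of("S")], spok_map, model,
                               n_asci=300, seed=18)
        assert set(h.dominance.nodes) == {"Psk-S"}
        assert h.levels == {"Psk-S": 0}

    def test_two_naive_strains_one_level(self, model, registry, spok_map):
        h = sp.build_hierarchy([registry.genotype_of("Wa46"),
                                registry.genotype_of("Wa47")],
                               spok_map, model, n_asci=300, seed=19)
        assert set(h.dominance.nodes) == {"naive"}
        assert h.same_type == []  # same label collapses onto one node
        assert h.calls[0].verdict == SAME_TYPE

    def test_dot_export_mentions_all_nodes(self, model, registry, spok_map):
        h = sp.build_hierarchy([registry.genotype_of("S"),
                                registry.genotype_of("Wa46")],
                               spok_map, model, n_asci=400, seed=20)
        dot = h.to_dot()
        assert "Psk-S" in dot and "naive" in dot
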