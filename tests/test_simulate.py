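"""Planted landscapes, evolution simulation and the benchmark fixture."""

import io
from itertools import combinations

import numpy as np
import pytest

from anchorscape import (
    LandscapeConfig,
    RouteSchedule,
    Variant,
    fixture_with_wildtype,
    make_anchor_fixture,
    make_landscape,
    median_of_events,
    sample_anchor_set,
    sample_flow_events,
    simulate_segment_scan,
    simulate_pance,
    summarize_anchors,
    true_fitness,
    write_anchor_table,
)

SMALL = LandscapeConfig(n_segments=3, n_sites=10, n_candidates=12,
                        reference_length=60, interaction_density=0.2,
                        noise_sd=0.0)


class TestMakeLandscape:
    def test_deterministic_for_fixed_seed(self):
        a, b = make_landscape(SMALL, 7), make_landscape(SMALL, 7)
        assert a == b

    def test_structure_matches_config(self):
        l = make_landscape(SMALL, 7)
        assert l.n_candidates == 12
        assert len({m.site for m in l.mutations}) == 10
        assert sorted(i for seg in l.segments for i in seg) == list(range(12))
        for m in l.mutations:
            assert l.reference[m.site - 1] == m.wt_aa

    def test_zero_density_gives_purely_additive_landscape(self):
        cfg = LandscapeConfig(n_segments=2, n_sites=10, n_candidates=12,
                              reference_length=60, interaction_density=0.0)
        assert make_landscape(cfg, 3).interactions == {}

    def test_interaction_count_within_binomial_bounds(self):
        cfg = LandscapeConfig(n_segments=2, n_sites=40, n_candidates=50,
                              reference_length=200, interaction_density=0.2)
        l = make_landscape(cfg, 9)
        pairs = sum(1 for i, j in combinations(range(50), 2)
                    if l.mutations[i].site != l.mutations[j].site)
        mean, sd = 0.2 * pairs, (0.2 * 0.8 * pairs) ** 0.5
        assert abs(len(l.interactions) - mean) < 4 * sd

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_sites=10, n_candidates=5)
        with pytest.raises(ValueError):
            LandscapeConfig(interaction_density=1.5)


class TestTrueFitness:
    def test_wildtype_is_baseline(self):
        l = make_landscape(SMALL, 7)
        assert true_fitness(l, Variant(frozenset(), l.reference_id)) == l.b0

    def test_single_mutant_adds_one_effect(self):
        l = make_landscape(SMALL, 7)
        v = l.variant_from_indices([3])
        assert true_fitness(l, v) == pytest.approx(l.b0 + l.additive[3])

    def test_matches_exhaustive_term_sum_oracle(self, rng):
        l = make_landscape(SMALL, 7)
        for _ in range(50):
            sites = set()
            idxs = []
            for i in rng.permutation(l.n_candidates):
                if l.mutations[i].site not in sites and len(idxs) < 5:
                    idxs.append(int(i))
                    sites.add(l.mutations[i].site)
            expect = l.b0 + sum(l.additive[i] for i in idxs)
            for i, j in combinations(sorted(idxs), 2):
                expect += l.interactions.get((i, j), 0.0)
            assert true_fitness(l, l.variant_from_indices(idxs)) == \
                pytest.approx(expect)

    def test_non_candidate_mutation_rejected(self):
        l = make_landscape(SMALL, 7)
        from anchorscape import Mutation
        site = next(s for s in range(1, 61)
                    if s not in {m.site for m in l.mutations})
        stray = Mutation(site, l.reference[site - 1],
                         "A" if l.reference[site - 1] != "A" else "C")
        with pytest.raises(ValueError):
            true_fitness(l, Variant(frozenset({stray}), l.reference_id))


def _tsv_bytes(anchor_set):
    buf = io.StringIO()
    write_anchor_table(anchor_set, buf)
    return buf.getvalue()


class TestSimulators:
    def test_identical_seeds_give_byte_identical_output(self):
        l = make_landscape(SMALL, 7)
        routes = [RouteSchedule((0, 1, 2), route_id="r1", population_size=200)]
        a = simulate_segment_scan(l, routes, seed=4)
        b = simulate_segment_scan(l, routes, seed=4)
        assert _tsv_bytes(a.anchor_set) == _tsv_bytes(b.anchor_set)
        assert _tsv_bytes(a.anchor_set) != _tsv_bytes(
            simulate_segment_scan(l, routes, seed=5).anchor_set)

    def test_noiseless_observed_fitness_equals_planted(self):
        l = make_landscape(SMALL, 7)
        routes = [RouteSchedule((0, 1, 2), route_id="r1", population_size=200)]
        sim = simulate_segment_scan(l, routes, seed=4, proposal_rate=0.5)
        for rec in sim.anchor_set:
            assert rec.fitness == pytest.approx(
                2.0 ** sim.true_log2[rec.record_id])

    def test_zero_passages_yields_only_wildtype(self):
        l = make_landscape(SMALL, 7)
        sim = simulate_pance(l, passages=0, seed=1)
        assert len(sim.anchor_set) == 1
        assert sim.anchor_set.records[0].variant.is_wildtype

    def test_mutations_stay_within_active_segment(self):
        l = make_landscape(SMALL, 7)
        routes = [RouteSchedule((1,), route_id="r1", population_size=300)]
        sim = simulate_segment_scan(l, routes, seed=4, proposal_rate=1.0)
        allowed = {l.mutations[i] for i in l.segments[1]}
        for rec in sim.anchor_set:
            assert set(rec.variant.mutations) <= allowed

    def test_strong_selection_finds_segment_optimum(self):
        l = make_landscape(SMALL, 7)
        seg = 0
        route = RouteSchedule((seg,), passages_per_segment=15,
                              route_id="r1", population_size=500)
        sim = simulate_segment_scan(l, [route], seed=2, proposal_rate=1.0,
                               selection_strength=10.0,
                               selection_saturation=None)
        # exhaustive search over site-consistent subsets of the segment
        members = list(l.segments[seg])
        best, best_f = frozenset(), l.b0
        for k in range(len(members) + 1):
            for combo in combinations(members, k):
                sites = [l.mutations[i].site for i in combo]
                if len(set(sites)) != len(sites):
                    continue
                f = l.log2_fitness_indices(frozenset(combo))
                if f > best_f:
                    best, best_f = frozenset(combo), f
        finals = [r for r in sim.anchor_set
                  if r.route_id == "r1" and r.source == "supernatant"]
        dominant = finals[-1].variant.mutations
        assert dominant == {l.mutations[i] for i in best}

    def test_unknown_segment_rejected(self):
        l = make_landscape(SMALL, 7)
        with pytest.raises(ValueError):
            simulate_segment_scan(l, [RouteSchedule((9,), route_id="bad")], seed=1)


class TestSampleAnchorSet:
    def test_distinct_genotypes_and_noiseless_identity(self):
        l = make_landscape(SMALL, 7)
        sim = sample_anchor_set(l, 30, seed=3, max_mutations=4)
        genos = [r.variant.mutations for r in sim.anchor_set]
        assert len(set(genos)) == 30
        for rec in sim.anchor_set:
            assert rec.fitness == pytest.approx(
                2.0 ** true_fitness(l, rec.variant))


class TestFlowEvents:
    def test_single_draw_is_its_own_median(self):
        events = sample_flow_events(500.0, cv=0.3, n=1, seed=9)
        assert median_of_events(events) == events[0]

    def test_large_sample_median_concentrates_on_true_median(self):
        events = sample_flow_events(2000.0, cv=0.3, n=100_001, seed=9)
        assert median_of_events(events) == pytest.approx(2000.0, rel=0.02)

    def test_vanishing_cv_degenerates_to_the_median(self):
        events = sample_flow_events(500.0, cv=1e-6, n=100, seed=9)
        assert np.allclose(events, 500.0, rtol=1e-4)

    def test_invalid_parameters_rejected(self):
        for bad in [(0, 0.3, 10), (10, 0, 10), (10, 0.3, 0)]:
            with pytest.raises(ValueError):
                sample_flow_events(*bad, seed=1)


class TestAnchorFixture:
    def test_encodes_printed_summary_structure(self, anchor_fixture):
        out = summarize_anchors(anchor_fixture)
        assert out.n_variants == 82
        assert out.n_distinct_mutations == 52
        assert out.n_distinct_sites == 39
        assert out.fraction_gt2_mutations == pytest.approx(68 / 82)

    def test_regeneration_is_byte_identical(self, anchor_fixture):
        assert _tsv_bytes(make_anchor_fixture()) == _tsv_bytes(anchor_fixture)

    def test_all_genotypes_distinct(self, anchor_fixture):
        genos = [r.variant.mutations for r in anchor_fixture]
        assert len(set(genos)) == 82

    def test_variants_beat_wildtype(self, anchor_fixture):
        wt_fitness = 5.0
        frac = np.mean([r.fitness > wt_fitness for r in anchor_fixture])
        assert frac >= 0.95
        s57r = next(r for r in anchor_fixture if r.variant.label() == "S57R")
        assert s57r.fitness > wt_fitness

    def test_wildtype_augmented_view(self, anchor_fixture_wt):
        assert len(anchor_fixture_wt) == 83
        wt = anchor_fixture_wt.records[0]
        assert wt.variant.is_wildtype and wt.fitness == pytest.approx(5.0)
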