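"""The ε statistic, sign classification, anchor-set scans and enumeration."""

from itertools import combinations

import numpy as np
import pytest

from anchorscape import (
    AnchorRecord,
    AnchorSet,
    EpistasisQuery,
    LandscapeConfig,
    Variant,
    classify_epistasis,
    enumerate_quadruples,
    epistasis_value,
    make_landscape,
    scan_epistasis,
)
from anchorscape.variants import parse_mutation

from conftest import make_set, make_variant


def fs(*tokens):
    return frozenset(parse_mutation(t) for t in tokens)


def oracle_classify(f_bg, f_a, f_b, f_ab, tol):
    """Independent brute-force sign table for the classifier."""
    eps = (f_bg + f_ab) - (f_a + f_b)
    if abs(eps) <= tol:
        return "none"

    def flips(alone, with_other):
        return bool(alone * with_other < 0 and abs(alone) > tol
                    and abs(with_other) > tol)

    n = int(flips(f_a - f_bg, f_ab - f_b)) + int(flips(f_b - f_bg, f_ab - f_a))
    return {0: "magnitude", 1: "sign", 2: "reciprocal_sign"}[n]


class TestEpsilonValue:
    def test_additive_quadruple_is_zero(self):
        assert epistasis_value(1, 2, 3, 4) == 0

    def test_positive_epistasis(self):
        assert epistasis_value(1, 2, 3, 6) == 2

    def test_symmetric_under_group_exchange(self, rng):
        for _ in range(200):
            f_bg, f_a, f_b, f_ab = rng.uniform(0.1, 50, 4)
            assert epistasis_value(f_bg, f_a, f_b, f_ab) == pytest.approx(
                epistasis_value(f_bg, f_b, f_a, f_ab))

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            epistasis_value(1, float("nan"), 3, 4)


class TestClassifier:
    @pytest.mark.parametrize("quad,expect", [
        ((1, 2, 3, 6), "magnitude"),        # both effects stay positive
        ((2, 1, 1, 3), "reciprocal_sign"),  # both effects flip negative->positive
        ((1, 0.5, 2, 3), "sign"),           # A flips, B does not
    ])
    def test_reference_cases(self, quad, expect):
        assert classify_epistasis(*quad).klass == expect

    def test_huge_tolerance_always_none(self, rng):
        for _ in range(50):
            quad = rng.uniform(0.1, 50, 4)
            assert classify_epistasis(*quad, tolerance=1e9).klass == "none"

    def test_zero_tolerance_none_only_at_exact_additivity(self, rng):
        for _ in range(200):
            quad = rng.uniform(0.1, 50, 4)
            r = classify_epistasis(*quad)
            assert (r.klass == "none") == (r.epsilon == 0)

    def test_agrees_with_sign_table_oracle_on_random_quadruples(self, rng):
        for _ in range(10_000):
            quad = rng.uniform(0.1, 50, 4)
            tol = float(rng.choice([0.0, 0.1, 1.0]))
            assert classify_epistasis(*quad, tolerance=tol).klass == \
                oracle_classify(*quad, tol)


class TestScan:
    def _planted_set_and_queries(self, seed):
        """Anchors for every (WT, i, j, ij) quadruple of a planted landscape."""
        cfg = LandscapeConfig(n_segments=2, n_sites=8, n_candidates=8,
                              reference_length=60, interaction_density=0.4,
                              sign_flip_prob=0.3, noise_sd=0.0)
        l = make_landscape(cfg, seed)
        genotypes = {frozenset()}
        queries = []
        for (i, j), _ in l.interactions.items():
            genotypes |= {frozenset({i}), frozenset({j}), frozenset({i, j})}
            queries.append(EpistasisQuery(
                Variant(frozenset(), l.reference_id),
                frozenset({l.mutations[i]}), frozenset({l.mutations[j]})))
        records = [
            AnchorRecord(l.variant_from_indices(g),
                         2.0 ** l.log2_fitness_indices(g), record_id=f"g{k}")
            for k, g in enumerate(sorted(genotypes, key=sorted))
        ]
        return l, AnchorSet(l.reference, records, l.reference_id), queries

    def test_recovers_planted_interactions_exactly_on_log2_scale(self):
        l, anchors, queries = self._planted_set_and_queries(seed=5)
        assert len(queries) >= 3
        report = scan_epistasis(anchors, queries, scale="log2")
        assert not report.unsatisfiable
        for res in report.results:
            i = l.index_of(next(iter(res.query.group_a)))
            j = l.index_of(next(iter(res.query.group_b)))
            planted = l.interactions[(min(i, j), max(i, j))]
            assert res.epsilon == pytest.approx(planted, abs=1e-9)

    def test_additive_landscape_scans_to_zero_everywhere(self):
        cfg = LandscapeConfig(n_segments=2, n_sites=8, n_candidates=8,
                              reference_length=60, interaction_density=0.0,
                              noise_sd=0.0)
        l = make_landscape(cfg, 11)
        genotypes = [frozenset(c) for k in range(3)
                     for c in combinations(range(4), k)]
        records = [AnchorRecord(l.variant_from_indices(g),
                                2.0 ** l.log2_fitness_indices(g),
                                record_id=f"g{k}")
                   for k, g in enumerate(genotypes)]
        anchors = AnchorSet(l.reference, records, l.reference_id)
        queries = enumerate_quadruples(anchors, max_group_size=2)
        report = scan_epistasis(anchors, queries, scale="log2")
        assert report.results
        for res in report.results:
            assert abs(res.epsilon) <= 1e-9

    def test_missing_double_mutant_reported_not_fatal(self):
        s = make_set([("WT", 5.0), ("D33E", 10.0), ("S57R", 15.0)])
        q = EpistasisQuery(Variant(frozenset()), fs("D33E"), fs("S57R"))
        report = scan_epistasis(s, [q])
        assert not report.results
        [(bad, missing)] = report.unsatisfiable
        assert bad is q
        assert missing == ["D33E;S57R"]

    def test_empty_query_list(self, triangle_set):
        report = scan_epistasis(triangle_set, [])
        assert not report.results and not report.unsatisfiable

    def test_replicates_combined_by_geometric_mean(self):
        s = make_set([("WT", 4.0), ("WT", 9.0), ("D33E", 6.0),
                      ("S57R", 6.0), ("D33E;S57R", 6.0)])
        q = EpistasisQuery(Variant(frozenset()), fs("D33E"), fs("S57R"))
        [res] = scan_epistasis(s, [q]).results
        assert res.epsilon == pytest.approx(6.0 + 6.0 - 6.0 - 6.0)  # gm(4,9)=6


class TestEnumerateQuadruples:
    def test_minimal_lattice_yields_single_query(self):
        s = make_set([("WT", 5.0), ("D33E", 8.0), ("S57R", 12.0),
                      ("D33E;S57R", 20.0)])
        [q] = enumerate_quadruples(s, max_group_size=1)
        assert q.background.is_wildtype
        assert {q.group_a, q.group_b} == {fs("D33E"), fs("S57R")}

    def test_no_quadruple_no_query(self):
        s = make_set([("WT", 5.0), ("D33E", 8.0)])
        assert enumerate_quadruples(s, max_group_size=1) == []

    def test_matches_exhaustive_oracle_on_random_lattice_subset(self, rng):
        tokens = ["D33E", "R43S", "S57R", "P94L"]
        all_genos = [frozenset(c) for k in range(5)
                     for c in combinations(tokens, k)]
        picked = [all_genos[i] for i in rng.choice(len(all_genos), 12,
                                                   replace=False)]
        s = make_set([(";".join(sorted(g, key=lambda t: int(t[1:-1]))) or "WT",
                       float(rng.uniform(1, 50))) for g in picked])
        present = {frozenset(parse_mutation(t) for t in g) for g in picked}

        # oracle: try every (bg, A, B) split of every present genotype
        expected = set()
        for top in present:
            for k_bg in range(len(top) + 1):
                for bg in map(frozenset, combinations(sorted(top, key=str), k_bg)):
                    rest = top - bg
                    if len(rest) < 2:
                        continue
                    for k_a in range(1, len(rest)):
                        if k_a > 2 or len(rest) - k_a > 2:
                            continue
                        for a in map(frozenset,
                                     combinations(sorted(rest, key=str), k_a)):
                            b = rest - a
                            if bg in present and (bg | a) in present \
                                    and (bg | b) in present:
                                key = (bg, frozenset({a, b}))
                                expected.add(key)
        got = {(q.background.mutations, frozenset({q.group_a, q.group_b}))
               for q in enumerate_quadruples(s, max_group_size=2)}
        assert got == expected
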