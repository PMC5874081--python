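"""Hypergeometric/Fisher oracles, directional partitioning and BY correction."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from degmeta import (
    AnnotationTrack,
    ContingencyTable2x2,
    GeneUniverse,
    SignedGeneSet,
    benjamini_yekutieli,
    enrichment_table,
    fisher_exact_upper,
    hypergeom_upper_tail,
    overlap_test,
    stratified_overlap,
)

from .conftest import signed


def exact_upper_tail(k: int, n_a: int, n_b: int, N: int) -> float:
    """Independent oracle: exact integer-arithmetic tail summation."""
    num = sum(
        math.comb(n_a, j) * math.comb(N - n_a, n_b - j)
        for j in range(k, min(n_a, n_b) + 1)
    )
    return num / math.comb(N, n_b)


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        for n_a, n_b, N in [(0, 0, 1), (3, 4, 10), (5, 5, 100)]:
            assert hypergeom_upper_tail(0, n_a, n_b, N) == 1.0

    def test_support_lower_bound_is_certain(self):
        # N=10, both lists of 6: overlap can never be below 2
        assert hypergeom_upper_tail(2, 6, 6, 10) == 1.0

    def test_subset_enumeration_oracle_N6(self):
        # enumerate every pair of 3-subsets of a 6-universe, count overlaps >= 2
        universe = range(6)
        a = set(range(3))
        tail = sum(1 for b in combinations(universe, 3) if len(a & set(b)) >= 2)
        expected = tail / math.comb(6, 3)
        assert hypergeom_upper_tail(2, 3, 3, 6) == pytest.approx(expected, rel=1e-14)

    def test_term_summation_oracle(self):
        expected = sum(
            math.comb(5, j) * math.comb(15, 5 - j) for j in range(3, 6)
        ) / math.comb(20, 5)
        assert hypergeom_upper_tail(3, 5, 5, 20) == pytest.approx(expected, rel=1e-14)

    def test_extreme_tail_does_not_underflow(self):
        # a huge forced overlap: log-space summation keeps p positive
        p = hypergeom_upper_tail(2000, 2000, 2000, 30000)
        assert 0 < p < 1e-300

    def test_agrees_with_scipy_sf(self):
        # independent library route: scipy parameterizes as sf(k-1, N, n_a, n_b)
        for k, n_a, n_b, N in [(3, 5, 5, 20), (10, 50, 60, 500), (117, 800, 4000, 27416)]:
            assert hypergeom_upper_tail(k, n_a, n_b, N) == pytest.approx(
                scipy_hypergeom.sf(k - 1, N, n_a, n_b), rel=1e-10
            )

    def test_bounds_violations_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 6, 6, 10)  # below feasible minimum 2
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 11, 5, 10)

    def test_monotone_in_k_and_n_a(self):
        N, n_a, n_b = 60, 20, 25
        ps = [hypergeom_upper_tail(k, n_a, n_b, N) for k in range(0, min(n_a, n_b) + 1)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        ps_a = [hypergeom_upper_tail(5, na, n_b, N) for na in range(5, 36)]
        assert all(p1 <= p2 for p1, p2 in zip(ps_a, ps_a[1:]))

    def test_lower_tail_complements_upper(self):
        # P[X <= k] + P[X >= k+1] == 1
        k, n_a, n_b, N = 4, 10, 12, 40
        lo = hypergeom_upper_tail(k, n_a, n_b, N, lower=True)
        hi = hypergeom_upper_tail(k + 1, n_a, n_b, N)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)


class TestOverlapTest:
    def test_total_overlap_forced(self, tiny_universe):
        all_up = SignedGeneSet("all", {g: 1 for g in tiny_universe.ids})
        r = overlap_test(all_up, all_up, tiny_universe)
        assert r.k == tiny_universe.size
        assert r.p_upper == 1.0

    def test_hand_enumerated_partition(self, tiny_universe):
        g = tiny_universe.ids
        a = SignedGeneSet("a", {g[1]: 1, g[2]: 1, g[3]: -1})
        b = SignedGeneSet("b", {g[2]: 1, g[3]: 1, g[4]: -1})
        r = overlap_test(a, b, tiny_universe)
        assert r.k == 2
        assert r.partition == {
            "concordant_up": 1,
            "concordant_down": 0,
            "discordant_a_up": 0,
            "discordant_a_down": 1,
        }
        assert set(r.class_pvalues) == set(r.partition)

    def test_printed_percent_style(self):
        # 1068 of a 4081-gene track overlapping: 26% at nearest-integer precision
        u = GeneUniverse.from_iterable(f"G{i}" for i in range(27416))
        ids = u.ids
        track = AnnotationTrack("track", frozenset(ids[:4081]), u)
        query = SignedGeneSet("q", {ids[i]: 1 for i in range(1068)})
        r = overlap_test(query, track, u)
        assert r.k == 1068
        assert r.percent_of_b_rounded() == 26
        assert r.percent_of_b_rounded(1) == pytest.approx(26.2)

    def test_direction_blind_inputs_skip_partition(self, tiny_universe):
        a = SignedGeneSet("a", {tiny_universe.ids[0]: 1})
        t = AnnotationTrack("t", frozenset(tiny_universe.ids[:5]), tiny_universe)
        r = overlap_test(a, t, tiny_universe)
        assert r.partition is None and r.class_pvalues is None

    def test_direction_info_does_not_change_k_or_p(self, universe_1k, rng):
        ids = np.asarray(universe_1k.ids)
        a_ids = rng.choice(ids, 80, replace=False)
        b_ids = rng.choice(ids, 120, replace=False)
        a_signed = SignedGeneSet("a", {g: int(s) for g, s in zip(a_ids, rng.choice([-1, 1], 80))})
        b_signed = SignedGeneSet("b", {g: int(s) for g, s in zip(b_ids, rng.choice([-1, 1], 120))})
        a_blind = SignedGeneSet("a", {g: 1 for g in a_ids})
        b_track = AnnotationTrack("b", frozenset(b_ids), universe_1k)
        r1 = overlap_test(a_signed, b_signed, universe_1k)
        r2 = overlap_test(a_blind, b_track, universe_1k)
        assert (r1.k, r1.p_upper) == (r2.k, r2.p_upper)
        assert sum(r1.partition.values()) == r1.k

    def test_restricts_inputs_to_universe_first(self, tiny_universe):
        a = SignedGeneSet("a", {tiny_universe.ids[0]: 1, "ZZ9": 1})
        b = SignedGeneSet("b", {tiny_universe.ids[0]: 1})
        r = overlap_test(a, b, tiny_universe)
        assert r.n_a == 1 and r.k == 1


class TestStratifiedOverlap:
    def test_degenerate_stratum_reduces_to_overlap_test(self, tiny_universe):
        a = SignedGeneSet("a", {g: 1 for g in tiny_universe.ids[:4]})
        full = AnnotationTrack("all", frozenset(tiny_universe.ids), tiny_universe)
        (res,) = stratified_overlap(a, [full], tiny_universe)
        ref = overlap_test(a, full, tiny_universe)
        assert (res.k, res.p_upper) == (ref.k, ref.p_upper)

    def test_disjoint_strata_overlaps_are_additive(self, universe_1k, rng):
        ids = np.asarray(universe_1k.ids)
        b_ids = rng.choice(ids, 200, replace=False)
        s1 = AnnotationTrack("s1", frozenset(b_ids[:90]), universe_1k)
        s2 = AnnotationTrack("s2", frozenset(b_ids[90:]), universe_1k)
        whole = AnnotationTrack("b", frozenset(b_ids), universe_1k)
        a = SignedGeneSet("a", {g: 1 for g in rng.choice(ids, 150, replace=False)})
        r1, r2 = stratified_overlap(a, [s1, s2], universe_1k)
        assert r1.k + r2.k == overlap_test(a, whole, universe_1k).k
        assert r1.N == r2.N == universe_1k.size

    def test_empty_strata_list_rejected(self, tiny_universe):
        with pytest.raises(ValueError):
            stratified_overlap(signed("a", AT1G00001=1), [], tiny_universe)


class TestFisherExact:
    def test_equals_hypergeom_under_margin_mapping(self):
        for a, b, c, d in [(2, 1, 1, 2), (0, 3, 4, 5), (5, 0, 0, 5), (7, 2, 3, 11)]:
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_exact_upper(t) == hypergeom_upper_tail(a, a + b, a + c, a + b + c + d)

    def test_margin_preserving_enumeration_oracle(self):
        # all 2x2 tables with row margins (3,3) and column margins (3,3), N=6
        t = ContingencyTable2x2(2, 1, 1, 2)
        # P[A >= 2] where A ~ Hypergeom(N=6, 3, 3)
        expected = sum(
            math.comb(3, j) * math.comb(3, 3 - j) for j in range(2, 4)
        ) / math.comb(6, 3)
        assert fisher_exact_upper(t) == pytest.approx(expected, rel=1e-14)

    def test_perfect_association_closed_form(self):
        t = ContingencyTable2x2(5, 0, 0, 5)
        assert fisher_exact_upper(t) == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_agrees_with_scipy_fisher(self):
        from scipy.stats import fisher_exact

        for a, b, c, d in [(8, 2, 3, 12), (1, 9, 9, 1), (4, 4, 4, 4)]:
            _odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert fisher_exact_upper(ContingencyTable2x2(a, b, c, d)) == pytest.approx(p, rel=1e-9)


def by_oracle(pvals):
    """Hand-computed BY step-up: p_(i) * m * c(m) / i, cummin from largest rank."""
    m = len(pvals)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvals[i])
    raw = [pvals[order[i]] * m * c_m / (i + 1) for i in range(m)]
    running = float("inf")
    adj_sorted = [0.0] * m
    for i in range(m - 1, -1, -1):
        running = min(running, raw[i])
        adj_sorted[i] = min(1.0, running)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert benjamini_yekutieli([0.03]) == [0.03]

    def test_all_equal_stay_equal(self):
        adj = benjamini_yekutieli([0.2] * 5)
        assert len(set(np.round(adj, 15))) == 1

    def test_matches_hand_oracle(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        assert benjamini_yekutieli(pvals) == pytest.approx(by_oracle(pvals), rel=1e-12)

    def test_empty_list(self):
        assert benjamini_yekutieli([]) == []

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        _rej, adj, _a, _b = multipletests(pvals, method="fdr_by")
        assert benjamini_yekutieli(pvals) == pytest.approx(list(adj), rel=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_by_dominates_bh_dominates_raw(self, pvals):
        from statsmodels.stats.multitest import multipletests

        by = np.asarray(benjamini_yekutieli(pvals))
        _r, bh, _a, _b = multipletests(pvals, method="fdr_bh")
        assert np.all(by >= bh - 1e-12)
        assert np.all(by >= np.asarray(pvals) - 1e-12)


class TestEnrichmentTable:
    def test_rows_and_by_column(self, universe_1k, rng):
        ids = np.asarray(universe_1k.ids)
        tracks = [
            AnnotationTrack(f"t{i}", frozenset(rng.choice(ids, 100, replace=False)), universe_1k)
            for i in range(3)
        ]
        query = SignedGeneSet("q", {g: 1 for g in rng.choice(ids, 50, replace=False)})
        df = enrichment_table(query, tracks, universe_1k)
        assert list(df["track"]) == ["t0", "t1", "t2"]
        assert (df["a"] + df["b"] + df["c"] + df["d"] == universe_1k.size).all()
        assert (df["p_by"] >= df["p_fisher"] - 1e-12).all()
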