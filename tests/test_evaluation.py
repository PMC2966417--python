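"""Coordination analysis with randomization nulls, hallmark recovery, and
hypergeometric enrichment with BH correction."""

import math

import numpy as np
import pytest

from minegs import (
    GeneNetwork,
    GeneRanking,
    GeneSetCollection,
    bh_adjust,
    coordination_rate,
    enrichment_scan,
    hallmark_recovery,
    hypergeometric_p,
    null_coordination,
    one_sample_ttest,
)
from minegs.partners import NFPTable


def _nfp(partners, k=3, rule="diffusion"):
    return NFPTable(rule, k, {g: [(p, 1.0) for p in ps] for g, ps in partners.items()})


def _sets(spec):
    coll = GeneSetCollection()
    for name, members in spec.items():
        coll.add(name, members)
    return coll


class TestCoordinationRate:
    def test_full_containment_is_coordinated(self):
        table = _nfp({"g": ["p1", "p2", "p3"]})
        sets = _sets({"s": ["g", "p1", "p2", "p3"]})
        res = coordination_rate(table, sets)
        assert res.evaluable == 1 and res.coordinated == 1

    def test_two_shared_members_not_coordinated(self):
        table = _nfp({"g": ["p1", "p2", "p3"]})
        # every group member is annotated, but no single set holds >= 3 of them
        sets = _sets({"s": ["g", "p1", "x", "y"], "anno": ["p2", "p3", "q"]})
        res = coordination_rate(table, sets)
        assert res.evaluable == 1 and res.coordinated == 0

    def test_unannotated_member_makes_gene_unevaluable(self):
        table = _nfp({"g": ["p1", "p2", "p3"]})
        sets = _sets({"s": ["g", "p1", "p2"]})  # p3 carries no annotation
        assert coordination_rate(table, sets).evaluable == 0

    def test_underfilled_gene_excluded(self):
        table = _nfp({"g": ["p1", "p2"]})  # k=3, list of 2
        sets = _sets({"s": ["g", "p1", "p2"]})
        assert coordination_rate(table, sets).evaluable == 0

    def test_oversized_set_ignored(self):
        table = _nfp({"g": ["p1", "p2", "p3"]})
        big = [f"x{i}" for i in range(200)] + ["g", "p1", "p2", "p3"]  # 204 members
        sets = _sets({"big": big, "anno": ["g", "p1", "q"]})
        res = coordination_rate(table, sets, max_set_size=200)
        # "big" annotates everyone (evaluable) but is too large to witness
        # coordination; "anno" shares only 2 of the group
        assert res.evaluable == 1 and res.coordinated == 0
        res2 = coordination_rate(table, sets, max_set_size=204)
        assert res2.coordinated == 1

    def test_toy_collection_matches_exhaustive_enumeration(self):
        table = _nfp(
            {
                "g1": ["g2", "g3", "g4"],
                "g2": ["g1", "g3", "g5"],
                "g5": ["g1", "g2", "g4"],
            }
        )
        sets = _sets(
            {
                "sA": ["g1", "g2", "g3", "g9"],
                "sB": ["g4", "g5", "g9", "g8"],
                "sC": ["g1", "g2", "g3", "g4", "g5"],
            }
        )
        # brute force over all (gene, set) pairs
        groups = {g: [g] + table.partner_ids(g) for g in table.genes()}
        annotated = sets.annotated_genes()
        expected_eval = expected_coord = 0
        for g, group in groups.items():
            if any(m not in annotated for m in group):
                continue
            expected_eval += 1
            if any(
                sum(m in sets.members(s) for m in group) >= 3
                for s in sets.names()
                if len(sets.members(s)) <= 200
            ):
                expected_coord += 1
        res = coordination_rate(table, sets)
        assert (res.evaluable, res.coordinated) == (expected_eval, expected_coord)

    def test_enlarging_size_cap_never_decreases_rate(self):
        table = _nfp({"g": ["p1", "p2", "p3"]})
        members = ["g", "p1", "p2", "p3", "x1", "x2"]
        sets = _sets({"s": members})
        r_small = coordination_rate(table, sets, max_set_size=5).rate
        r_big = coordination_rate(table, sets, max_set_size=6).rate
        assert r_big >= r_small


class TestNullCoordination:
    def test_seeded_runs_bit_reproducible(self):
        universe = tuple(f"g{i}" for i in range(8))
        sets = _sets({"s": list(universe[:5])})
        a = null_coordination("uniform", universe, None, sets, reps=5, seed=42)
        b = null_coordination("uniform", universe, None, sets, reps=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_saturated_annotation_gives_rate_one(self):
        universe = tuple(f"g{i}" for i in range(6))
        sets = _sets({"all": list(universe)})
        rates = null_coordination("uniform", universe, None, sets, reps=3, seed=0)
        np.testing.assert_array_equal(rates, 1.0)

    def test_network_null_respects_degree(self):
        genes = ("hub", "a", "b", "c", "leaf")
        edges = frozenset({("hub", "a"), ("hub", "b"), ("hub", "c"), ("a", "leaf")})
        net = GeneNetwork(genes, edges)
        sets = _sets({"s": list(genes)})
        rates = null_coordination("network", genes, net, sets, reps=4, seed=1)
        # only "hub" has >=3 neighbors, and the all-gene set makes it coordinated
        np.testing.assert_array_equal(rates, 1.0)

    def test_uniform_null_mean_below_true_rate_on_structured_fixture(self):
        # annotated modules of 4; true NFPs exactly match the modules
        modules = {f"mod{m}": [f"m{m}_{i}" for i in range(4)] for m in range(3)}
        universe = tuple(g for mod in modules.values() for g in mod)
        sets = _sets(modules)
        partners = {
            g: [x for x in mod if x != g] for mod in modules.values() for g in mod
        }
        table = _nfp(partners)
        true_rate = coordination_rate(table, sets).rate
        nulls = null_coordination("uniform", universe, None, sets, reps=50, seed=3)
        assert true_rate == 1.0
        assert nulls.mean() < true_rate

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            null_coordination("uniform", ("a", "b"), None, _sets({"s": ["a"]}), reps=0)
        with pytest.raises(ValueError):
            null_coordination("bogus", ("a", "b"), None, _sets({"s": ["a"]}))


class TestOneSampleTTest:
    def test_observed_at_null_mean_gives_p_one(self):
        assert one_sample_ttest(np.array([0.1, 0.2, 0.3]), 0.2) == pytest.approx(1.0)

    def test_hand_computed_closed_form(self):
        # t = (0.2 - 0.6) / (0.1 / sqrt(3)) = -4*sqrt(3); for df=2 the two-sided
        # p-value has the closed form 1 - |t| / sqrt(t^2 + 2)
        t = -4 * math.sqrt(3)
        expected_p = 1 - abs(t) / math.sqrt(t * t + 2)
        assert one_sample_ttest(np.array([0.1, 0.2, 0.3]), 0.6) == pytest.approx(
            expected_p, rel=1e-10
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            one_sample_ttest(np.array([0.2, 0.2, 0.2]), 0.5)


def _ranking(order):
    mi = {g: 1.0 / (i + 1) for i, g in enumerate(order)}
    return GeneRanking("classic", mi, mi, tuple(order))


class TestHallmarkRecovery:
    def test_hallmarks_ranked_first(self):
        r = _ranking([f"g{i}" for i in range(10)])
        assert hallmark_recovery(r, ["g0", "g1", "g2"], top_n=5) == 3

    def test_top_n_equals_universe(self):
        r = _ranking([f"g{i}" for i in range(10)])
        assert hallmark_recovery(r, ["g3", "g9", "outside"], top_n=10) == 2

    def test_hand_enumerated_toy(self):
        order = ["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"]
        assert hallmark_recovery(_ranking(order), ["b", "e", "j"], top_n=5) == 2

    def test_top_n_too_large_errors(self):
        with pytest.raises(ValueError):
            hallmark_recovery(_ranking(["a", "b"]), ["a"], top_n=3)


class TestHypergeometric:
    def test_zero_overlap_full_tail(self):
        assert hypergeometric_p(10, 4, 3, 0) == pytest.approx(1.0)

    def test_exhaustive_enumeration_n10(self):
        # P(X >= 5) for N=10, K=5, n=5 is 1/C(10,5) = 1/252
        assert hypergeometric_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)
        # cross-check the whole tail against combinatorial enumeration
        for x in range(6):
            expected = sum(
                math.comb(5, i) * math.comb(5, 5 - i) for i in range(x, 6)
            ) / math.comb(10, 5)
            assert hypergeometric_p(10, 5, 5, x) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_overlap(self):
        ps = [hypergeometric_p(20, 8, 6, x) for x in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_p(10, 5, 5, 6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_step_up_arithmetic_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_order_invariance_and_monotonicity(self):
        p = np.array([0.3, 0.001, 0.2, 0.04, 0.9])
        adj = bh_adjust(p)
        perm = [4, 2, 0, 1, 3]
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1)

    def test_exhaustive_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(7)
        # direct step-up: adj_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p)
        m = p.size
        sorted_adj = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_adj, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestEnrichmentScan:
    def test_raw_p_matches_hypergeometric_oracle_on_12_gene_toy(self):
        universe = [f"g{i}" for i in range(12)]
        sets = _sets(
            {
                "s1": universe[0:5],
                "s2": universe[3:9],
                "s3": universe[8:12],
                "outside": ["x1", "x2", "x3"],  # fully outside the universe
            }
        )
        selected = set(universe[:4])
        rows = enrichment_scan(selected, sets, universe, min_size=3, max_size=10, alpha=0.1)
        assert {r.name for r in rows} == {"s1", "s2", "s3"}  # "outside" excluded
        for r in rows:
            K = len(sets.members(r.name) & set(universe))
            x = len(sets.members(r.name) & selected)
            assert r.K == K and r.x == x
            assert r.p == pytest.approx(hypergeometric_p(12, K, 4, x), rel=1e-12)
        np.testing.assert_allclose(
            [r.p_adj for r in rows], bh_adjust([r.p for r in rows])
        )

    def test_size_window_is_the_tested_set_count(self):
        universe = [f"g{i}" for i in range(12)]
        sets = _sets({"tiny": universe[:2], "ok": universe[:6], "ok2": universe[2:10]})
        rows = enrichment_scan(set(universe[:3]), sets, universe, min_size=3, max_size=8)
        assert {r.name for r in rows} == {"ok", "ok2"}

    def test_selection_equal_universe(self):
        universe = [f"g{i}" for i in range(12)]
        sets = _sets({"s": universe[:6]})
        rows = enrichment_scan(set(universe), sets, universe, min_size=3, max_size=10)
        # n = N forces x = K: the upper tail P(X >= K) is exactly 1
        assert rows[0].x == rows[0].K == 6
        assert rows[0].p == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            enrichment_scan(set(), _sets({"s": ["a"]}), [])
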