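"""Graph construction, pair counting, expectations and the Yates test."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cgckit.cgc_scoring import GeneRecord, ScoredGene
from cgckit.errors import DataError, ValidationError
from cgckit.qtl_connectivity import (
    ConnectionGraph,
    build_graph,
    connecting_gene_pairs,
    count_pairs,
    expected_pairs,
    filter_high_score_pairs,
    holm_adjust,
    significant_qtl_pairs,
    yates_chisq_2x2,
)
from tests.conftest import make_locus, make_qtl


def toy_graph(qtl_genes, edges, qtl_crosses=None):
    """Build a ConnectionGraph directly from membership dicts (test shortcut)."""
    if qtl_crosses is None:
        qtl_crosses = {
            q: frozenset({"cross1" if q.startswith("A") else "cross2"})
            for q in qtl_genes
        }
    return ConnectionGraph(
        cross1="cross1",
        cross2="cross2",
        qtl_genes={q: frozenset(g) for q, g in qtl_genes.items()},
        qtl_crosses={q: frozenset(c) for q, c in qtl_crosses.items()},
        edges=frozenset(frozenset(e) for e in edges),
    )


def brute_force_count(qtl_genes, edges, q1, q2):
    edge_set = {frozenset(e) for e in edges}
    return sum(
        1
        for g1, g2 in product(qtl_genes[q1], qtl_genes[q2])
        if frozenset((g1, g2)) in edge_set
    )


def oracle_yates(a, b, c, d):
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    return chi2, float(stats.chi2.sf(chi2, 1))


class TestBuildGraph:
    def _world(self):
        catalog = [
            make_locus("A", "chr1", 100, 200),
            make_locus("B", "chr2", 100, 200),
            make_locus("C", "chr3", 100, 200),  # outside all QTLs
            make_locus("D", "chr1", 300, 400),
        ]
        qtls = [
            make_qtl("Q1", "chr1", 1, 1000, cross="cross1"),
            make_qtl("Q2", "chr2", 1, 1000, cross="cross2"),
        ]
        return catalog, qtls

    def test_cross_cross_edge(self):
        catalog, qtls = self._world()
        records = [GeneRecord("A", links=("B",))]
        g = build_graph(records, qtls, catalog)
        assert g.stats().total_cross_cross == 1
        assert count_pairs(g, "Q1", "Q2") == 1

    def test_reciprocal_links_dedup(self):
        catalog, qtls = self._world()
        records = [GeneRecord("A", links=("B",)), GeneRecord("B", links=("A",))]
        g = build_graph(records, qtls, catalog)
        assert len(g.edges) == 1

    def test_link_outside_qtls_dropped(self):
        catalog, qtls = self._world()
        records = [GeneRecord("A", links=("C",))]
        g = build_graph(records, qtls, catalog)
        assert len(g.edges) == 0

    def test_unresolvable_target_dropped(self, caplog):
        catalog, qtls = self._world()
        records = [GeneRecord("A", links=("Nope", "B"))]
        with caplog.at_level("WARNING"):
            g = build_graph(records, qtls, catalog)
        assert g.dropped_links == (("A", "Nope"),)
        assert len(g.edges) == 1

    def test_same_cross_edge_not_cross_cross(self):
        catalog = [make_locus("A", "chr1", 100, 200), make_locus("D", "chr1", 300, 400)]
        qtls = [
            make_qtl("Q1", "chr1", 1, 1000, cross="cross1"),
            make_qtl("Q2", "chr2", 1, 1000, cross="cross2"),
        ]
        g = build_graph([GeneRecord("A", links=("D",))], qtls, catalog)
        assert len(g.edges) == 1
        assert g.stats().total_cross_cross == 0

    def test_needs_two_crosses(self):
        catalog, _ = self._world()
        qtls = [make_qtl("Q1", "chr1", 1, 1000, cross="cross1")]
        with pytest.raises(DataError):
            build_graph([], qtls, catalog)


class TestCountPairs:
    def test_empty_graph(self):
        g = toy_graph({"A1": {"a"}, "B1": {"b"}}, [])
        assert count_pairs(g, "A1", "B1") == 0

    def test_complete_bipartite(self):
        # 3 x 2 genes fully linked -> 6 pairs, matches brute-force enumeration
        qtl_genes = {"A1": {"a1", "a2", "a3"}, "B1": {"b1", "b2"}}
        edges = [(a, b) for a in qtl_genes["A1"] for b in qtl_genes["B1"]]
        g = toy_graph(qtl_genes, edges)
        assert count_pairs(g, "A1", "B1") == 6
        assert count_pairs(g, "A1", "B1") == brute_force_count(qtl_genes, edges, "A1", "B1")

    def test_symmetric_in_argument_order(self):
        qtl_genes = {"A1": {"a1", "a2"}, "B1": {"b1"}}
        g = toy_graph(qtl_genes, [("a1", "b1")])
        assert count_pairs(g, "A1", "B1") == count_pairs(g, "B1", "A1") == 1

    def test_same_cross_rejected(self):
        g = toy_graph({"A1": {"a"}, "A2": {"b"}, "B1": {"c"}}, [])
        with pytest.raises(ValidationError):
            count_pairs(g, "A1", "A2")

    def test_brute_force_on_random_instances(self, rng):
        genes1 = [f"a{i}" for i in range(6)]
        genes2 = [f"b{i}" for i in range(6)]
        for _ in range(200):
            qtl_genes = {
                "A1": set(rng.choice(genes1, rng.integers(1, 5), replace=False)),
                "A2": set(rng.choice(genes1, rng.integers(1, 5), replace=False)),
                "B1": set(rng.choice(genes2, rng.integers(1, 5), replace=False)),
                "B2": set(rng.choice(genes2, rng.integers(1, 5), replace=False)),
            }
            all_pairs = [(a, b) for a in genes1 for b in genes2]
            k = int(rng.integers(0, 12))
            idx = rng.choice(len(all_pairs), k, replace=False)
            edges = [all_pairs[i] for i in idx]
            g = toy_graph(qtl_genes, edges)
            for q1, q2 in product(["A1", "A2"], ["B1", "B2"]):
                assert count_pairs(g, q1, q2) == brute_force_count(qtl_genes, edges, q1, q2)


class TestExpectedPairs:
    def test_symmetry_equal_sizes(self):
        # 2 x 2 equal QTLs, T = 8 -> every pair expects T / 4
        qtl_genes = {
            "A1": {"a1", "a2"}, "A2": {"a3", "a4"},
            "B1": {"b1", "b2"}, "B2": {"b3", "b4"},
        }
        edges = [("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4"),
                 ("a1", "b3"), ("a2", "b4"), ("a3", "b1"), ("a4", "b2")]
        g = toy_graph(qtl_genes, edges)
        for q1, q2 in product(["A1", "A2"], ["B1", "B2"]):
            assert expected_pairs(g, q1, q2) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        # sizes (2,3) x (4,1): products 8,2,12,3 sum 25; T=10 -> 10*8/25 = 3.2
        qtl_genes = {
            "A1": {f"a{i}" for i in range(2)},
            "A2": {f"c{i}" for i in range(3)},
            "B1": {f"b{i}" for i in range(4)},
            "B2": {"d0"},
        }
        a1 = sorted(qtl_genes["A1"])
        b1 = sorted(qtl_genes["B1"])
        edges = [(a, b) for a in a1 for b in b1]  # 8 edges A1-B1
        edges += [("c0", "d0"), ("c1", "d0")]  # 2 more cross-cross edges
        g = toy_graph(qtl_genes, edges)
        assert g.stats().total_cross_cross == 10
        assert expected_pairs(g, "A1", "B1") == pytest.approx(3.2)

    def test_single_pair_carries_all(self):
        qtl_genes = {"A1": {"a1", "a2"}, "B1": {"b1"}}
        g = toy_graph(qtl_genes, [("a1", "b1"), ("a2", "b1")])
        assert expected_pairs(g, "A1", "B1") == pytest.approx(2.0)

    def test_no_edges_untestable(self):
        g = toy_graph({"A1": {"a"}, "B1": {"b"}}, [])
        assert math.isnan(expected_pairs(g, "A1", "B1"))

    def test_expectation_conserved(self, rng):
        """Sum of expectations over all cross1 x cross2 pairs equals T."""
        for _ in range(50):
            qtl_genes = {
                f"A{i}": {f"a{i}_{j}" for j in range(rng.integers(1, 5))} for i in range(3)
            }
            qtl_genes.update(
                {f"B{i}": {f"b{i}_{j}" for j in range(rng.integers(1, 5))} for i in range(2)}
            )
            g1 = [g for q in ("A0", "A1", "A2") for g in qtl_genes[q]]
            g2 = [g for q in ("B0", "B1") for g in qtl_genes[q]]
            pairs = [(a, b) for a in g1 for b in g2]
            k = int(rng.integers(1, len(pairs)))
            edges = [pairs[i] for i in rng.choice(len(pairs), k, replace=False)]
            g = toy_graph(qtl_genes, edges)
            total = sum(
                expected_pairs(g, q1, q2)
                for q1, q2 in product(("A0", "A1", "A2"), ("B0", "B1"))
            )
            assert total == pytest.approx(g.stats().total_cross_cross)


class TestYatesChisq:
    def test_hand_evaluated(self):
        chi2, p = yates_chisq_2x2(20, 10, 15, 30)
        assert chi2 == pytest.approx(6.752232, abs=1e-4)

    def test_proportional_table_is_null(self):
        chi2, p = yates_chisq_2x2(10, 20, 20, 40)
        assert chi2 == 0.0 and p == 1.0

    def test_clamped_to_zero(self):
        # |ad - bc| <= N/2 must clamp rather than go negative
        chi2, p = yates_chisq_2x2(5, 5, 5, 6)
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_degenerates_to_null(self):
        # zero margin forces |ad - bc| = 0, which the clamp maps to (0, 1)
        chi2, p = yates_chisq_2x2(0, 0, 5, 6)
        assert chi2 == 0.0 and p == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            yates_chisq_2x2(-1, 1, 1, 1)

    @given(
        a=st.integers(0, 60), b=st.integers(0, 60),
        c=st.integers(0, 60), d=st.integers(0, 60),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_and_invariances(self, a, b, c, d):
        if (a + b) * (c + d) * (a + c) * (b + d) == 0:
            return
        chi2, p = yates_chisq_2x2(a, b, c, d)
        exp_chi2, exp_p = oracle_yates(a, b, c, d)
        assert chi2 == pytest.approx(exp_chi2)
        assert p == pytest.approx(exp_p)
        # invariant under transposition and row/column swaps
        for perm in [(a, c, b, d), (c, d, a, b), (b, a, d, c)]:
            assert yates_chisq_2x2(*perm)[0] == pytest.approx(chi2)


class TestHolm:
    def test_adjusts_monotonically(self):
        # sorted: 0.01*3=0.03, 0.03*2=0.06, 0.04*1=0.04 -> bumped to 0.06
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == [0.03, 0.06, 0.06]

    def test_nan_passthrough(self):
        adj = holm_adjust([0.01, math.nan])
        assert adj[0] == 0.01 and math.isnan(adj[1])


class TestSignificantQtlPairs:
    def test_single_pair_carries_everything(self):
        # only one pair exists: expected == observed, p == 1
        qtl_genes = {"A1": {"a1", "a2"}, "B1": {"b1", "b2"}}
        g = toy_graph(qtl_genes, [("a1", "b1"), ("a2", "b2")])
        (res,) = significant_qtl_pairs(g)
        assert res.observed == 2
        assert res.expected == pytest.approx(2.0)
        assert res.p == pytest.approx(1.0)
        assert res.flag == ""

    def test_no_edges_untestable(self):
        g = toy_graph({"A1": {"a"}, "B1": {"b"}}, [])
        (res,) = significant_qtl_pairs(g)
        assert res.flag == "untestable"

    def test_planted_excess_flagged(self):
        # all 25 A1-B1 slots filled, a handful of edges elsewhere
        qtl_genes = {
            "A1": {f"a{i}" for i in range(5)},
            "A2": {f"c{i}" for i in range(5)},
            "B1": {f"b{i}" for i in range(5)},
            "B2": {f"d{i}" for i in range(5)},
        }
        edges = [(a, b) for a in qtl_genes["A1"] for b in qtl_genes["B1"]]
        edges += [(f"c{i}", f"d{i}") for i in range(5)]
        g = toy_graph(qtl_genes, edges)
        results = significant_qtl_pairs(g)
        top = results[0]
        assert (top.qtl1, top.qtl2) == ("A1", "B1")
        assert top.observed > top.expected
        assert top.flag == "significant"

    def test_near_miss_band(self):
        g = toy_graph({"A1": {"a"}, "B1": {"b"}}, [("a", "b")])
        (res,) = significant_qtl_pairs(g, alpha=0.05, near_miss=1.1)
        # p == 1 but observed == expected -> no near-miss flag either
        assert res.flag == ""

    def test_dual_cross_qtl_excluded_from_self_pairing(self):
        # one QTL mapped in both crosses must not pair with itself
        qtl_genes = {"Shared": {"s1"}, "A1": {"a1"}, "B1": {"b1"}}
        qtl_crosses = {
            "Shared": {"cross1", "cross2"},
            "A1": {"cross1"},
            "B1": {"cross2"},
        }
        g = toy_graph(qtl_genes, [("a1", "b1")], qtl_crosses)
        pairs = {(r.qtl1, r.qtl2) for r in significant_qtl_pairs(g)}
        assert ("Shared", "Shared") not in pairs
        assert ("Shared", "B1") in pairs and ("A1", "Shared") in pairs


class TestConnectingGenePairs:
    def test_listing_matches_count(self):
        qtl_genes = {"A1": {"a1", "a2"}, "B1": {"b1", "b2"}}
        edges = [("a1", "b1"), ("a2", "b1")]
        g = toy_graph(qtl_genes, edges)
        pairs = connecting_gene_pairs(g, "A1", "B1")
        assert len(pairs) == count_pairs(g, "A1", "B1") == 2
        assert all(a in qtl_genes["A1"] and b in qtl_genes["B1"] for a, b in pairs)


class TestFilterHighScorePairs:
    SCORES = {"a": 49.9, "b": 12.0, "c": 50.0, "d": 0.0, "e": 120.0, "f": 80.0}

    def test_both_below_dropped(self):
        assert filter_high_score_pairs([("a", "b")], self.SCORES) == []

    def test_inclusive_boundary_kept(self):
        assert filter_high_score_pairs([("c", "d")], self.SCORES) == [("c", "d")]

    def test_both_above_kept(self):
        assert filter_high_score_pairs([("e", "f")], self.SCORES) == [("e", "f")]

    def test_unscored_gene_named(self):
        with pytest.raises(DataError, match="ghost"):
            filter_high_score_pairs([("ghost", "a")], self.SCORES)

    def test_accepts_scored_gene_objects(self):
        scores = {"x": ScoredGene("x", 60.0), "y": ScoredGene("y", 10.0)}
        assert filter_high_score_pairs([("x", "y")], scores) == [("x", "y")]
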