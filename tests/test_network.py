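import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet.network import (CeRNATriple, CorrelationEdge, SpongeResult,
                            assemble_triples, build_network,
                            derive_circ_mrna_candidates,
                            filter_negative_pairs, filter_positive_pairs,
                            hub_rank, hypergeom_sf, pearson, spearman,
                            sponge_test, top_edges, write_graphml, write_sif)
from cernet.targets import InteractionCandidate

from oracles import (hypergeom_tail_enumeration, pearson_textbook,
                     spearman_via_ranks)


class TestCorrelations:
    def test_perfect_antimonotone(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_midranks_with_ties(self):
        assert spearman([1, 2, 2, 4], [10, 20, 20, 40]) == pytest.approx(1.0)

    def test_spearman_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = rng.integers(0, 8, size=12).astype(float)  # heavy ties
            y = rng.integers(0, 8, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(spearman_via_ranks(x, y),
                                                   abs=1e-12)

    def test_pearson_linear_maps(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x, y = rng.standard_normal((2, 15))
            assert pearson(x, y) == pytest.approx(pearson_textbook(x, y),
                                                  abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))
        assert math.isnan(pearson([1, 2, 3], [5, 5, 5]))

    def test_short_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestHypergeom:
    def test_worked_example(self):
        assert hypergeom_sf(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_sf(0, 4, 5, 10) == 1.0

    def test_full_enumeration_small_universes(self):
        for N in (5, 8, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_sf(k, K, n, N) == pytest.approx(
                            hypergeom_tail_enumeration(k, K, n, N), abs=1e-12)

    def test_agrees_with_scipy_cross_check(self):
        from scipy.stats import hypergeom
        rng = np.random.default_rng(4)
        for _ in range(100):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_sf(k, K, n, N) == pytest.approx(expected,
                                                             rel=1e-9)

    @given(st.integers(1, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_nonincreasing_in_k(self, N, K, n):
        K, n = min(K, N), min(n, N)
        ps = [hypergeom_sf(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_violated_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 11, 5, 10)


class TestSpongeTest:
    def test_disjoint_sets_fail(self):
        res = sponge_test({"a"}, {"b"}, {"a", "b", "c"})
        assert (res.shared, res.p, res.passed) == (0, 1.0, False)

    def test_forced_full_overlap_is_not_significant(self):
        uni = set("abcde")
        res = sponge_test(uni, uni, uni)
        assert res.p == 1.0 and not res.passed

    def test_nested_small_case_matches_kernel(self):
        uni = set(range(10))
        res = sponge_test(set(range(4)), set(range(3, 8)), uni)
        assert res.shared == 1
        assert res.p == pytest.approx(hypergeom_sf(1, 4, 5, 10))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sponge_test(set(), set(), set())


def expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows).T


def cand(mirna, target, layer="mRNA"):
    return InteractionCandidate(mirna, target, layer, {"8mer": 1}, 3.0)


class TestCorrelationFilters:
    def test_strictness_at_boundary(self):
        # rho exactly -0.7 must NOT pass the strict < -0.7 filter
        mirna = expr({"m": [1, 2, 3, 4, 5, 6]})
        # construct y with spearman exactly -0.7: d^2 sum = 59.5 impossible;
        # use threshold -1 instead: only exact antimonotone passes
        down = expr({"t": [6, 5, 4, 3, 2, 1]})
        near = expr({"u": [6, 5, 4, 3, 1, 2]})
        edges = filter_negative_pairs([cand("m", "t"), cand("m", "u")],
                                      mirna, pd.concat([down, near]),
                                      threshold=-1.0)
        assert edges == []
        edges = filter_negative_pairs([cand("m", "t")], mirna, down,
                                      threshold=-0.999)
        assert [e.node_b for e in edges] == ["t"]

    def test_undefined_correlation_dropped_with_warning(self, caplog):
        mirna = expr({"m": [1, 2, 3, 4]})
        const = expr({"t": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            edges = filter_negative_pairs([cand("m", "t")], mirna, const)
        assert edges == [] and "undefined" in caplog.text

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            filter_negative_pairs([cand("m", "t")],
                                  expr({"x": [1, 2, 3]}),
                                  expr({"t": [1, 2, 3]}))

    def test_positive_filter_passes_identical_profiles(self):
        circ = expr({"c": [1, 5, 2, 8, 3, 9]})
        mrna = expr({"g": [1, 5, 2, 8, 3, 9], "h": [9, 3, 8, 2, 5, 1]})
        edges = filter_positive_pairs([("c", "g"), ("c", "h")], circ, mrna)
        assert [(e.node_a, e.node_b) for e in edges] == [("c", "g")]

    def test_shared_mirna_candidate_derivation(self):
        cm = [CorrelationEdge("m1", "c1", "circRNA-miRNA", -0.9, "spearman",
                              6, True)]
        mm = [CorrelationEdge("m1", "g1", "miRNA-mRNA", -0.8, "spearman",
                              6, True),
              CorrelationEdge("m2", "g2", "miRNA-mRNA", -0.8, "spearman",
                              6, True)]
        assert derive_circ_mrna_candidates(cm, mm) == [("c1", "g1")]


def edge(a, b, kind, coef):
    return CorrelationEdge(a, b, kind, coef, "spearman", 6, True)


def make_triples(n=3, mirna="m0"):
    sponge = {(f"c{i}", f"g{i}"): SpongeResult(2, 2, 2, 20, 0.005, True)
              for i in range(n)}
    mm = [edge(mirna if i == 0 else f"m{i}", f"g{i}", "miRNA-mRNA", -0.9)
          for i in range(n)]
    cm = [edge(mirna if i == 0 else f"m{i}", f"c{i}", "circRNA-miRNA", -0.8)
          for i in range(n)]
    cg = [CorrelationEdge(f"c{i}", f"g{i}", "circRNA-mRNA", 0.95, "pearson",
                          6, True) for i in range(n)]
    return assemble_triples(mm, cm, cg, sponge)


class TestAssembleAndNetwork:
    def test_all_filters_required(self):
        triples = make_triples(2)
        assert [(t.circ, t.mirna, t.mrna) for t in triples] == \
            [("c0", "m0", "g0"), ("c1", "m1", "g1")]
        # removing circ-miR edges empties the output
        assert assemble_triples(
            [edge("m0", "g0", "miRNA-mRNA", -0.9)], [],
            [CorrelationEdge("c0", "g0", "circRNA-mRNA", 0.95, "pearson",
                             6, True)],
            {("c0", "g0"): SpongeResult(1, 1, 1, 30, 0.03, True)}) == []

    def test_failed_sponge_blocks_triple(self):
        sponge = {("c0", "g0"): SpongeResult(1, 1, 1, 10, 0.1, False)}
        out = assemble_triples([edge("m0", "g0", "miRNA-mRNA", -0.9)],
                               [edge("m0", "c0", "circRNA-miRNA", -0.8)],
                               [CorrelationEdge("c0", "g0", "circRNA-mRNA",
                                                0.95, "pearson", 6, True)],
                               sponge)
        assert out == []

    def test_duplicate_inputs_do_not_duplicate_triples(self):
        mm = [edge("m0", "g0", "miRNA-mRNA", -0.9)] * 2
        cm = [edge("m0", "c0", "circRNA-miRNA", -0.8)] * 2
        cg = [CorrelationEdge("c0", "g0", "circRNA-mRNA", 0.95, "pearson",
                              6, True)]
        out = assemble_triples(mm, cm, cg, {("c0", "g0"):
                                            SpongeResult(1, 1, 1, 30, 0.03,
                                                         True)})
        assert len(out) == 1

    def test_single_triple_network_shape(self):
        net = build_network(make_triples(1))
        assert net.node_counts == {"circRNA": 1, "miRNA": 1, "mRNA": 1}
        assert net.n_edges == 2
        assert net.summary_line() == ("1 circRNA nodes, 1 miRNA nodes, "
                                      "1 mRNA nodes, and 2 edges")

    def test_node_counts_sum_and_recount(self, pipeline_result):
        net = pipeline_result.network
        assert sum(net.node_counts.values()) == net.graph.number_of_nodes()
        ids = {n for t in pipeline_result.triples
               for n in (t.circ, t.mirna, t.mrna)}
        assert set(net.graph.nodes) == ids

    def test_hub_rank_star_and_ties(self):
        triples = make_triples(3, mirna="m_hub")
        # make m_hub anchor all three clusters
        sponge = {(f"c{i}", f"g{i}"): SpongeResult(2, 2, 2, 20, 0.005, True)
                  for i in range(3)}
        mm = [edge("m_hub", f"g{i}", "miRNA-mRNA", -0.9) for i in range(3)]
        cm = [edge("m_hub", f"c{i}", "circRNA-miRNA", -0.8) for i in range(3)]
        cg = [CorrelationEdge(f"c{i}", f"g{i}", "circRNA-mRNA", 0.95,
                              "pearson", 6, True) for i in range(3)]
        net = build_network(assemble_triples(mm, cm, cg, sponge))
        ranked = hub_rank(net)
        assert ranked[0] == "m_hub"
        assert ranked[1:] == sorted(ranked[1:])  # equal degrees in id order

    def test_top_edges_ranking_and_bounds(self):
        net = build_network(make_triples(3))
        assert top_edges(net, 100).n_edges == net.n_edges
        best = top_edges(net, 1)
        assert best.n_edges == 1
        # best edge: smallest sponge p, then largest |coefficient|
        ((u, v, d),) = best.graph.edges(data=True)
        all_keys = [(dd["sponge_p"], -abs(dd["coefficient"]))
                    for _, _, dd in net.graph.edges(data=True)]
        assert (d["sponge_p"], -abs(d["coefficient"])) == min(all_keys)

    def test_exports_roundtrip(self, tmp_path, pipeline_result):
        import networkx as nx
        write_graphml(pipeline_result.network, tmp_path / "n.graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert back.number_of_edges() == pipeline_result.network.n_edges
        write_sif(pipeline_result.network, tmp_path / "n.sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert len(lines) == pipeline_result.network.n_edges
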