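import itertools
import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import cofracnet as cn
from cofracnet.diffnet import (
    GeneSetCollection,
    abundance_by_overlap_class,
    annotate_edges_with_abundance,
    build_gene_sets_from_annotations,
    correlation_shift_test,
    delta_nppi_test,
    enrichment_map_edges,
    enrichment_map_json,
    log_odds_enrichment,
    pair_annotation_sharing_enrichment,
    protein_autocorrelation,
    read_gmt,
    rewire_degree_preserving,
    stouffer,
    write_gmt,
)
from cofracnet.inference import InteractionNetwork, compare_networks
from cofracnet.matrix import from_array


def er_network(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
    return InteractionNetwork(g)


class TestGeneSets:
    def test_gmt_roundtrip(self, tmp_path):
        sets = GeneSetCollection(
            {"GO:1": frozenset("ABC"), "GO:2": frozenset("BD")},
            names={"GO:1": "one", "GO:2": "two"},
        )
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert back.sets == sets.sets
        assert back.name("GO:2") == "two"

    def test_size_filter_drops_broad_and_tiny_terms(self):
        sets = GeneSetCollection(
            {
                "small": frozenset("A"),
                "ok": frozenset("AB"),
                "broad": frozenset(f"P{i}" for i in range(150)),
            }
        )
        kept = sets.filter_sizes(min_size=2, max_size=100)
        assert set(kept.sets) == {"ok"}
        assert kept.size_filtered

    def test_annotation_ingestion_with_exclusions_and_propagation(self):
        annotations = pd.DataFrame(
            {
                "protein": ["A", "B", "C", "D"],
                "term": ["child", "child", "child", "root"],
                "evidence": ["EXP", "IEA", "IDA", "EXP"],
                "qualifier": [None, None, "NOT", None],
            }
        )
        ontology = {"child": ["root"]}
        sets = build_gene_sets_from_annotations(annotations, ontology)
        # B (IEA evidence) and C (NOT qualifier) are excluded; A propagates up
        assert sets.sets["root"] == frozenset("AD")
        assert "child" not in sets.sets  # one member only after exclusions


class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self):
        net = er_network(40, 0.2, seed=1)
        rewired = rewire_degree_preserving(net, seed=2)
        assert rewired.n_edges == net.n_edges
        assert sorted(dict(rewired.graph.degree).values()) == sorted(
            dict(net.graph.degree).values()
        )
        assert rewired.edge_set != net.edge_set  # actually randomized

    def test_triangle_is_fixed_point(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert rewire_degree_preserving(net, seed=0).edge_set == net.edge_set

    def test_star_is_fixed_point(self):
        net = InteractionNetwork.from_edges([("H", s) for s in "ABCD"])
        assert rewire_degree_preserving(net, seed=0).edge_set == net.edge_set

    def test_isolated_nodes_survive(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("C", "D")])
        g.add_node("LONER")
        rewired = rewire_degree_preserving(InteractionNetwork(g), seed=3)
        assert "LONER" in rewired.nodes


class TestDeltaNPPI:
    def test_planted_rewired_term_dominates(self):
        rng = np.random.default_rng(0)
        term_proteins = [f"T{i}" for i in range(10)]
        background = [f"B{i}" for i in range(200)]
        g_stim = nx.Graph()
        g_stim.add_edges_from(itertools.combinations(term_proteins, 2))
        g_unstim = nx.Graph()
        for g in (g_stim, g_unstim):
            nodes = background
            for _ in range(400):
                a, b = rng.choice(nodes, 2, replace=False)
                g.add_edge(a, b)
        sets = {"planted": frozenset(term_proteins)}
        for t in range(20):
            sets[f"rand{t}"] = frozenset(rng.choice(background, 8, replace=False))
        test = delta_nppi_test(
            InteractionNetwork(g_stim), InteractionNetwork(g_unstim),
            GeneSetCollection(sets), n_perm=100, seed=1,
        )
        by_term = {r.term: r for r in test.results}
        planted = by_term["planted"]
        assert planted.delta == 45
        assert planted.q < 0.2
        assert abs(planted.z) == max(abs(r.z) for r in test.results)

    def test_self_comparison_finds_nothing(self):
        net = er_network(60, 0.1, seed=5)
        rng = np.random.default_rng(6)
        sets = GeneSetCollection(
            {
                f"t{i}": frozenset(rng.choice(sorted(net.nodes), 8, replace=False))
                for i in range(10)
            }
        )
        test = delta_nppi_test(net, net, sets, n_perm=100, seed=7)
        assert all(r.delta == 0 for r in test.results)
        assert not test.significant(0.2)

    def test_singleton_terms_are_skipped(self):
        net = er_network(20, 0.2, seed=8)
        sets = GeneSetCollection({p: frozenset({p}) for p in sorted(net.nodes)})
        test = delta_nppi_test(net, net, sets, n_perm=10, seed=9)
        assert not test.results
        assert len(test.skipped) == len(sets)

    def test_invariants_of_reported_statistics(self):
        net_a = er_network(40, 0.15, seed=10)
        net_b = er_network(40, 0.15, seed=11)
        rng = np.random.default_rng(12)
        sets = GeneSetCollection(
            {
                f"t{i}": frozenset(rng.choice(sorted(net_a.nodes | net_b.nodes), 6,
                                              replace=False))
                for i in range(8)
            }
        )
        test = delta_nppi_test(net_a, net_b, sets, n_perm=50, seed=13)
        for r in test.results:
            assert r.delta == r.n_ppi_stim - r.n_ppi_unstim
            assert r.q >= r.p
            if r.null_sd > 0:
                assert r.z == pytest.approx((r.delta - r.null_mean) / r.null_sd)


class TestSharingEnrichment:
    def test_universal_term_gives_p_one(self):
        net = er_network(20, 0.2, seed=14)
        sets = GeneSetCollection({"all": frozenset(net.nodes)})
        res = pair_annotation_sharing_enrichment(net, sets, n_perm=50, seed=15)
        assert res.observed == 1.0
        assert res.p == 1.0

    def test_unannotated_proteins_give_p_one(self):
        net = er_network(20, 0.2, seed=16)
        sets = GeneSetCollection({"other": frozenset({"Q1", "Q2"})})
        res = pair_annotation_sharing_enrichment(net, sets, n_perm=50, seed=17)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_module_structure_is_detected(self):
        modules = [[f"M{m}_{i}" for i in range(8)] for m in range(5)]
        g = nx.Graph()
        for proteins in modules:
            g.add_edges_from(itertools.combinations(proteins, 2))
        net = InteractionNetwork(g)
        sets = GeneSetCollection(
            {f"mod{m}": frozenset(proteins) for m, proteins in enumerate(modules)}
        )
        res = pair_annotation_sharing_enrichment(net, sets, n_perm=200, seed=18)
        assert res.observed == 1.0
        assert res.p <= 0.01

    def test_empirical_p_respects_add_one_bounds(self):
        net = er_network(15, 0.3, seed=19)
        sets = GeneSetCollection({"x": frozenset(sorted(net.nodes)[:5])})
        res = pair_annotation_sharing_enrichment(net, sets, n_perm=99, seed=20)
        assert 1 / 100 <= res.p <= 1.0


class TestProteinAutocorrelation:
    def test_stouffer_closed_form(self):
        assert stouffer([1, 1, 1]) == pytest.approx(np.sqrt(3))
        assert stouffer([2.0]) == pytest.approx(2.0)

    def test_unchanged_protein_has_maximal_combined_z(self):
        rng = np.random.default_rng(21)
        base = rng.random((6, 20)) + 0.1
        stim = []
        unstim = []
        for rep in (1, 2, 3):
            u = base + rng.normal(0, 0.01, base.shape)
            s = u.copy()
            # shuffle every profile except protein X across fractions
            for i in range(1, 6):
                s[i] = rng.permutation(s[i])
            proteins = ["X"] + [f"P{i}" for i in range(1, 6)]
            stim.append(from_array(np.abs(s), proteins, replicate=rep, channel="heavy"))
            unstim.append(from_array(np.abs(u), proteins, replicate=rep,
                                     channel="medium"))
        scores = protein_autocorrelation(stim, unstim)
        best = max(scores, key=lambda s: s.combined_z)
        assert best.protein == "X"
        assert all(r == pytest.approx(1.0, abs=1e-9) for r in best.r.values())

    def test_rewired_complex_members_score_low(self):
        lows, highs = [], []
        for s in range(5):
            truth = cn.generate_complex_truth(40, 6, (3, 4), 0.5, seed=30 + s)
            config = cn.SimulationConfig(n_proteins=40, spike_rate=0.0, seed=300 + s)
            matrices, _ = cn.simulate_chromatograms(truth, config)
            stim = [m for m in matrices if m.condition == "stimulated"]
            unstim = [m for m in matrices if m.condition == "unstimulated"]
            scores = {a.protein: a.combined_z for a in protein_autocorrelation(stim, unstim)}
            rewired = {
                p for cid in truth.rewired_complexes for p in truth.complexes[cid]
            }
            stable = {
                p
                for cid, mm in truth.complexes.items()
                if cid not in truth.rewired_complexes
                for p in mm
            }
            lows.append(np.mean([scores[p] for p in rewired if p in scores]))
            highs.append(np.mean([scores[p] for p in stable if p in scores]))
        assert np.mean(lows) < np.mean(highs)


class TestCorrelationShift:
    def test_identical_conditions_are_not_significant(self):
        rng = np.random.default_rng(40)
        values = rng.random((8, 30)) + 0.1
        m = from_array(values, [f"P{i}" for i in range(8)])
        res = correlation_shift_test(m, m, {f"P{i}" for i in range(8)})
        assert res.defined
        assert res.p >= 0.99
        assert res.median_shift == pytest.approx(0.0)

    def test_planted_coelution_shift_is_detected(self):
        truth = cn.generate_complex_truth(30, 4, (4, 5), 1.0, seed=41)
        config = cn.SimulationConfig(n_proteins=30, spike_rate=0.0, seed=42)
        matrices, _ = cn.simulate_chromatograms(truth, config)
        stim = [m for m in matrices if m.condition == "stimulated"]
        unstim = [m for m in matrices if m.condition == "unstimulated"]
        members = set(truth.complexes["C001"])
        # this complex co-elutes only when unstimulated (rewired_fraction 1)
        res = correlation_shift_test(unstim, stim, members)
        assert res.defined
        assert res.median_shift > 0
        assert res.p < 0.01

    def test_too_few_pairs_is_undefined(self):
        m = from_array(np.random.default_rng(43).random((2, 10)), ["A", "B"])
        res = correlation_shift_test(m, m, {"A", "B"})
        assert not res.defined
        assert np.isnan(res.p)


class TestLogOdds:
    def test_balanced_table_is_null(self):
        res = log_odds_enrichment(10, 10, 10, 10)
        assert res.log_odds == pytest.approx(0.0)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        res = log_odds_enrichment(20, 5, 5, 20)
        assert res.log_odds == pytest.approx(np.log(16))
        assert res.z == pytest.approx(np.log(16) / np.sqrt(0.5))
        assert res.p == pytest.approx(2 * norm.sf(abs(res.z)))

    def test_zero_cells_get_continuity_correction(self):
        res = log_odds_enrichment(10, 0, 5, 8)
        assert np.isfinite(res.z) and np.isfinite(res.p)

    @pytest.mark.parametrize("table", [(3, 7, 11, 2), (40, 3, 9, 27)])
    def test_p_is_normal_tail_of_z(self, table):
        res = log_odds_enrichment(*table)
        assert res.p == pytest.approx(2 * norm.sf(abs(res.z)))


class TestEnrichmentMap:
    def test_jaccard_edges(self):
        sets = GeneSetCollection(
            {
                "a": frozenset("XY"),
                "b": frozenset("XZ"),     # jaccard 1/3 with a: boundary edge
                "c": frozenset("QW"),     # disjoint from everything
                "d": frozenset("XY"),     # identical to a
            }
        )
        edges = {(t1, t2): j for t1, t2, j in enrichment_map_edges(sets)}
        assert edges[("a", "d")] == pytest.approx(1.0)
        assert edges[("a", "b")] == pytest.approx(1 / 3)
        assert not any("c" in e for e in edges)

    def test_json_graph_structure(self):
        net_a = er_network(30, 0.2, seed=50)
        net_b = er_network(30, 0.2, seed=51)
        rng = np.random.default_rng(52)
        sets = GeneSetCollection(
            {
                f"t{i}": frozenset(rng.choice(sorted(net_a.nodes), 6, replace=False))
                for i in range(5)
            }
        )
        test = delta_nppi_test(net_a, net_b, sets, n_perm=20, seed=53)
        graph = enrichment_map_json(test, sets)
        assert {n["term"] for n in graph["nodes"]} == set(sets.sets)
        json.dumps(graph)  # serializable


class TestAbundanceAnnotation:
    def test_max_absolute_fold_change(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("C", "D"), ("E", "F")])
        fc = {"A": 0.5, "B": -2.0, "C": 1.0}
        ann = annotate_edges_with_abundance(net, fc)
        by_pair = {(r.protein_a, r.protein_b): r.max_abs_log2fc for r in ann.itertuples()}
        assert by_pair[("A", "B")] == pytest.approx(2.0)
        assert by_pair[("C", "D")] == pytest.approx(1.0)  # missing endpoint ignored
        assert np.isnan(by_pair[("E", "F")])              # both missing

    def test_classwise_medians_match_brute_force(self):
        a = InteractionNetwork.from_edges([("A", "B"), ("B", "C")])
        b = InteractionNetwork.from_edges([("A", "B"), ("C", "D")])
        comp = compare_networks(a, b)
        fc = {"A": 1.0, "B": 2.0, "C": 0.5, "D": -3.0}
        summary = abundance_by_overlap_class(
            comp, annotate_edges_with_abundance(a, fc),
            annotate_edges_with_abundance(b, fc),
        )
        rows = {r["class"]: r for _, r in summary.iterrows()}
        assert rows["shared"]["median_max_abs_log2fc"] == pytest.approx(2.0)
        assert rows["a_only"]["median_max_abs_log2fc"] == pytest.approx(2.0)
        assert rows["b_only"]["median_max_abs_log2fc"] == pytest.approx(3.0)
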