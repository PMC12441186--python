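"""Network construction, thresholded components and cluster classification."""

import networkx as nx
import pytest

from ssnscreen.config import TaxonConfig, TaxonConfigError
from ssnscreen.pairalign import AlignParams, bit_score, raw_score
from ssnscreen.seqio_orf import ProteinRecord
from ssnscreen.ssn_graph import (
    SSNError,
    SSNGraph,
    build_ssn,
    candidate_pool,
    classify_cluster,
    components_at,
    export_network,
    read_edge_list,
    sweep,
)

from oracles import oracle_components

CFG = TaxonConfig(
    focal="K", producers=frozenset({"K", "U"}), nonproducers=frozenset({"C1", "C2"})
)


def rec(pid, taxon, seq):
    return ProteinRecord(id=pid, taxon=taxon, seq=seq)


def random_graph(rng, n_nodes, p_edge=0.15):
    """An SSNGraph with arbitrary scored edges (no alignment involved)."""
    g = nx.Graph()
    nodes = [f"n{k:02d}" for k in range(n_nodes)]
    taxa = ["K", "U", "C1", "C2"]
    for k, n in enumerate(nodes):
        g.add_node(n, taxon=taxa[k % 4], record=None, multiplicity=1)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], score=float(rng.uniform(50, 200)))
    return SSNGraph(graph=g, floor=50.0, params=AlignParams(), duplicates={n: (n,) for n in nodes})


class TestBuildSSN:
    def test_three_identical_sequences_form_triangle(self):
        seq = "MKVAWHEQRNDLFYCIGPST" * 3
        recs = [rec(f"p{k}", t, seq) for k, t in enumerate(["K", "U", "C1"])]
        g = build_ssn(recs, floor=50.0)
        assert g.graph.number_of_edges() == 3

    def test_floor_above_every_score_gives_empty_edge_set(self):
        seq = "MKVAWHEQRNDLFYCIGPST" * 3
        recs = [rec(f"p{k}", "K", seq + "A" * k) for k in range(3)]
        g = build_ssn(recs, floor=1e6)
        assert g.graph.number_of_edges() == 0

    def test_edge_set_matches_all_pairs_filter(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        recs = []
        base = "".join(rng.choice(aa, size=80))
        for k in range(40):
            if k % 2:
                seq = "".join(rng.choice(aa, size=80))
            else:  # related to base -> some edges exist
                seq = "".join(c if rng.random() > 0.2 else str(rng.choice(aa)) for c in base)
            recs.append(rec(f"p{k:02d}", ["K", "U", "C1", "C2"][k % 4], seq))
        floor = 40.0
        g = build_ssn(recs, floor=floor)
        p = AlignParams()
        expect = set()
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                if bit_score(raw_score(a.seq, b.seq, p)) >= floor:
                    expect.add(frozenset({a.id, b.id}))
        got = {frozenset(e) for e in g.graph.edges}
        assert got == expect

    def test_duplicate_sequences_collapse_to_smallest_id(self):
        seq = "MKVAWHEQRNDLFYCIGPST" * 3
        recs = [rec("zz", "K", seq), rec("aa", "K", seq), rec("bb", "U", seq + "AAA")]
        g = build_ssn(recs, floor=50.0)
        assert "aa" in g.graph and "zz" not in g.graph
        assert g.duplicates["aa"] == ("aa", "zz")
        assert g.graph.nodes["aa"]["multiplicity"] == 2

    def test_fewer_than_two_proteins_is_error(self):
        with pytest.raises(SSNError):
            build_ssn([rec("p", "K", "MKV")])


class TestComponentsAt:
    def test_above_max_edge_all_singletons(self, rng):
        g = random_graph(rng, 20)
        part = components_at(g, 1e9)
        assert all(len(c) == 1 for c in part.clusters)
        assert len(part.clusters) == 20

    def test_at_floor_connected_graph_is_one_cluster(self):
        g = nx.Graph()
        for k in range(5):
            g.add_node(f"n{k}", taxon="K", record=None, multiplicity=1)
            if k:
                g.add_edge(f"n{k-1}", f"n{k}", score=60.0)
        ssn = SSNGraph(graph=g, floor=50.0, params=AlignParams(), duplicates={})
        part = components_at(ssn, 50.0)
        assert len(part.clusters) == 1

    def test_matches_union_find_oracle(self, rng):
        for trial in range(20):
            g = random_graph(rng, 60)
            edges = [(u, v, s) for u, v, s in g.graph.edges(data="score")]
            for t in rng.uniform(50, 210, size=10):
                got = set(components_at(g, float(t)).clusters)
                assert got == oracle_components(list(g.graph.nodes), edges, float(t))

    def test_below_floor_is_error(self, rng):
        with pytest.raises(SSNError, match="floor"):
            components_at(random_graph(rng, 5), 10.0)


class TestClassify:
    def _graph(self, taxa):
        g = nx.Graph()
        for k, t in enumerate(taxa):
            g.add_node(f"n{k}", taxon=t, record=None, multiplicity=1)
        return SSNGraph(graph=g, floor=50.0, params=AlignParams(), duplicates={})

    def test_producers_only_is_nsc(self):
        g = self._graph(["K", "U"])
        assert classify_cluster({"n0", "n1"}, g, CFG).label == "NSC"

    def test_any_nonproducer_is_shared(self):
        g = self._graph(["K", "C2"])
        assert classify_cluster({"n0", "n1"}, g, CFG).label == "shared"

    def test_all_focal_is_focal_specific(self):
        g = self._graph(["K", "K"])
        lab = classify_cluster({"n0", "n1"}, g, CFG)
        assert lab.label == "focal_specific"
        assert lab.taxon_counts == {"K": 2}

    def test_unknown_taxon_is_config_error(self):
        g = self._graph(["K", "Mystery"])
        with pytest.raises(TaxonConfigError):
            classify_cluster({"n0", "n1"}, g, CFG)


class TestSweep:
    def test_refinement_monotonicity(self, rng):
        for trial in range(100):
            g = random_graph(rng, 25)
            sw = sweep(g, 50, 25, 200, CFG)
            for p1, p2 in zip(sw.partitions, sw.partitions[1:]):
                assert len(p2.clusters) >= len(p1.clusters)
                for c2 in p2.clusters:
                    parents = [c1 for c1 in p1.clusters if c2 <= c1]
                    assert len(parents) == 1

    def test_partition_covers_nodes_exactly_once(self, rng):
        g = random_graph(rng, 30)
        part = components_at(g, 100.0)
        all_nodes = [n for c in part.clusters for n in c]
        assert sorted(all_nodes) == sorted(g.graph.nodes)

    def test_control_in_nsc_at_start_emerges_at_start(self):
        g = nx.Graph()
        g.add_node("k1", taxon="K", record=None, multiplicity=1)
        g.add_node("u1", taxon="U", record=None, multiplicity=1)
        g.add_edge("k1", "u1", score=300.0)
        ssn = SSNGraph(graph=g, floor=50.0, params=AlignParams(), duplicates={})
        sw = sweep(ssn, 50, 50, 200, CFG, controls=["k1"])
        assert sw.emergence["k1"] == 50.0

    def test_control_welded_to_nonproducer_never_emerges(self):
        g = nx.Graph()
        for n, t in [("k1", "K"), ("c1", "C1")]:
            g.add_node(n, taxon=t, record=None, multiplicity=1)
        g.add_edge("k1", "c1", score=1e9)
        ssn = SSNGraph(graph=g, floor=50.0, params=AlignParams(), duplicates={})
        sw = sweep(ssn, 50, 50, 200, CFG, controls=["k1"])
        assert sw.emergence["k1"] is None

    def test_missing_control_listed_in_error(self, rng):
        g = random_graph(rng, 5)
        with pytest.raises(SSNError, match="ghost"):
            sweep(g, 50, 50, 200, CFG, controls=["ghost"])

    def test_once_nonproducer_free_never_absorbs_one(self, rng):
        # label monotonicity: an NSC/focal cluster can only split as t rises
        for trial in range(20):
            g = random_graph(rng, 20)
            sw = sweep(g, 50, 30, 200, CFG)
            for (p1, l1), (p2, l2) in zip(
                zip(sw.partitions, sw.labels), zip(sw.partitions[1:], sw.labels[1:])
            ):
                for c2 in p2.clusters:
                    parent = next(c1 for c1 in p1.clusters if c2 <= c1)
                    if l1[parent].label != "shared":
                        assert l2[c2].label != "shared"


class TestExportAndPool:
    def test_round_trip_edge_list(self, rng, tmp_path):
        g = random_graph(rng, 60)
        part = components_at(g, 50.0)
        labels = {c: classify_cluster(c, g, CFG) for c in part.clusters}
        export_network(g, part, labels, tmp_path, graphml=True)
        back = read_edge_list(tmp_path / "edges.tsv")
        got = {(u, v): round(s, 6) for u, v, s in back}
        expect = {
            (min(u, v), max(u, v)): round(s, 6)
            for u, v, s in g.graph.edges(data="score")
        }
        assert got == expect
        assert (tmp_path / "network.graphml").exists()

    def test_empty_edge_graph_exports_nodes_only(self, rng, tmp_path):
        g = random_graph(rng, 5, p_edge=0.0)
        part = components_at(g, 50.0)
        export_network(g, part, {c: classify_cluster(c, g, CFG) for c in part.clusters}, tmp_path)
        assert read_edge_list(tmp_path / "edges.tsv") == []
        assert (tmp_path / "nodes.tsv").read_text().count("\n") == 6  # header + 5

    def test_candidate_pool_focal_only(self, rng):
        g = random_graph(rng, 24)
        part = components_at(g, 50.0)
        labels = {c: classify_cluster(c, g, CFG) for c in part.clusters}
        pool = candidate_pool(g, part, labels, CFG)
        for node, lab in pool.items():
            assert g.taxon_of(node) == "K"
            assert lab in {"NSC", "focal_specific", "unclustered"}
        # focal genes in shared clusters are excluded
        for c in part.clusters:
            if len(c) > 1 and labels[c].label == "shared":
                assert not (set(c) & set(pool))
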