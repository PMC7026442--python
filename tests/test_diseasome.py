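import itertools

import networkx as nx
import numpy as np
import pytest

from expolink import build_diseasome, export_network, jaccard_score, \
    multi_disease_genes, shared_genes
from expolink.diffexpr import DiseaseGeneSet
from expolink.diseasome import UndefinedScoreError


def gset(did, up=(), down=()):
    return DiseaseGeneSet(did, frozenset(up), frozenset(down))


class TestSetScores:
    def test_shared_genes_enumeration(self):
        assert shared_genes({"A", "B"}, {"C"}) == (0, frozenset())
        assert shared_genes({"A", "B"}, {"A", "B"}) == (2, frozenset({"A", "B"}))
        n, inter = shared_genes({"A", "B", "C", "D"}, {"B", "D", "E"})
        assert n == 2 and inter == {"B", "D"}

    def test_jaccard_examples(self):
        assert jaccard_score({"A", "B"}, {"A", "B"}) == 1.0
        assert jaccard_score({"A"}, {"B"}) == 0.0
        assert jaccard_score({"A", "B", "C", "D"}, {"B", "D", "E"}) == pytest.approx(0.4)

    def test_jaccard_undefined_for_empty_sets(self):
        with pytest.raises(UndefinedScoreError):
            jaccard_score(set(), set())

    def test_jaccard_properties_random_pairs(self, rng):
        universe = [f"G{i}" for i in range(30)]
        for _ in range(200):
            a = {g for g in universe if rng.random() < 0.3}
            b = {g for g in universe if rng.random() < 0.3}
            if not (a | b):
                continue
            s = jaccard_score(a, b)
            assert 0.0 <= s <= 1.0
            assert s == jaccard_score(b, a)
            assert (s == 1.0) == (a == b)
            assert (s == 0.0) == (not a & b)
            n, _ = shared_genes(a, b)
            assert s == pytest.approx(n / (len(a) + len(b) - n))


class TestBuildDiseasome:
    def test_disjoint_sets_give_no_gene_nodes(self):
        net = build_diseasome(gset("WF", up={"A", "B"}),
                              [gset("CC", up={"X"}), gset("PC", up={"Y"})], "up")
        assert net.gene_nodes() == []
        assert net.shared_count("CC") == 0

    def test_gene_shared_to_two_diseases_has_degree_three(self):
        net = build_diseasome(
            gset("WF", up={"A", "B", "C"}),
            [gset("CC", up={"A", "X"}), gset("GC", up={"A", "C", "Y"})], "up")
        assert net.graph.degree("A") == 3
        cc_gc = [r for r in net.associations if {r.source, r.target} == {"CC", "GC"}]
        assert len(cc_gc) == 1 and "A" in cc_gc[0].genes

    def test_duplicate_disease_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_diseasome(gset("WF", up={"A"}),
                            [gset("CC", up={"A"}), gset("CC", up={"A"})], "up")

    def test_matches_bruteforce_reconstruction(self, rng):
        universe = [f"G{i:02d}" for i in range(50)]
        for trial in range(20):
            n_dis = int(rng.integers(1, 6))
            exp_up = frozenset(g for g in universe if rng.random() < 0.4)
            dsets = {f"D{k}": frozenset(g for g in universe if rng.random() < 0.3)
                     for k in range(n_dis)}
            net = build_diseasome(
                gset("EXP", up=exp_up),
                [gset(k, up=v) for k, v in dsets.items()], "up")
            # brute force: retained genes, bipartite edges, association records
            genes_bf = set()
            for v in dsets.values():
                genes_bf |= set(exp_up) & set(v)
            assert set(net.gene_nodes()) == genes_bf
            for g in genes_bf:
                expect = {"EXP"} | {k for k, v in dsets.items() if g in v}
                assert set(net.graph.neighbors(g)) == expect
            all_sets = {"EXP": exp_up, **dsets}
            for a, b in itertools.combinations(sorted(all_sets, key=lambda x: (x != "EXP", x)), 2):
                inter = all_sets[a] & all_sets[b]
                rec = [r for r in net.associations if {r.source, r.target} == {a, b}]
                if "EXP" in (a, b) or inter:
                    assert len(rec) == 1
                    assert rec[0].n_shared == len(inter)
                    union = all_sets[a] | all_sets[b]
                    if union:
                        assert rec[0].jaccard == pytest.approx(len(inter) / len(union))
                else:
                    assert rec == []


class TestMultiDiseaseGenes:
    def test_every_gene_touches_exposure_plus_one(self):
        net = build_diseasome(gset("WF", up={"A", "B"}),
                              [gset("CC", up={"A", "B"})], "up")
        assert multi_disease_genes(net, 2) == {"A", "B"}

    def test_k_exceeding_node_count_is_empty(self):
        net = build_diseasome(gset("WF", up={"A"}), [gset("CC", up={"A"})], "up")
        assert multi_disease_genes(net, 10) == frozenset()

    def test_gene_shared_to_all_diseases(self):
        diseases = [gset(d, up={"A", f"X{d}"}) for d in ("CC", "PC", "LC", "GC")]
        net = build_diseasome(gset("WF", up={"A"}), diseases, "up")
        assert multi_disease_genes(net, 5) == {"A"}


class TestExports:
    def test_sif_line_count_equals_bipartite_edges(self, tmp_path):
        net = build_diseasome(gset("WF", up={"A", "B", "C"}),
                              [gset("CC", up={"A", "B"}), gset("GC", up={"B"})], "up")
        export_network(net, tmp_path / "n.sif", "sif")
        lines = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert len(lines) == net.graph.number_of_edges()

    def test_empty_network_exports(self, tmp_path):
        net = build_diseasome(gset("WF", up={"A"}), [gset("CC", up={"X"})], "up")
        for fmt, name in (("graphml", "e.graphml"), ("sif", "e.sif"), ("tsv", "e.tsv")):
            export_network(net, tmp_path / name, fmt)
            assert (tmp_path / name).exists()

    def test_graphml_round_trip_isomorphic(self, tmp_path):
        net = build_diseasome(gset("WF", up={"A", "B", "C"}),
                              [gset("CC", up={"A", "C"}), gset("GC", up={"C"})], "up")
        export_network(net, tmp_path / "n.graphml", "graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        bipartite = nx.Graph((u, v) for u, v, d in back.edges(data=True)
                             if d.get("kind") == "disease-gene")
        assert nx.is_isomorphic(net.graph, bipartite)
        assert {n for n, d in back.nodes(data=True) if d["kind"] == "gene"} == \
            set(net.gene_nodes())

    def test_deterministic_bytes(self, tmp_path, rng):
        universe = [f"G{i}" for i in range(30)]
        exp = frozenset(rng.choice(universe, 15, replace=False))
        dis = frozenset(rng.choice(universe, 12, replace=False))
        net = build_diseasome(gset("WF", up=exp), [gset("CC", up=dis)], "up")
        export_network(net, tmp_path / "a.tsv", "tsv")
        export_network(net, tmp_path / "b.tsv", "tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_unknown_format_rejected(self, tmp_path):
        net = build_diseasome(gset("WF", up={"A"}), [gset("CC", up={"A"})], "up")
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(net, tmp_path / "x", "dot")
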