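"""Exposure-centered gene-disease (diseasome) association networks.

Two diseases are associated when they share at least one significant
dysregulated gene; the shared count is n_ij = N(G_i ∩ G_j) and the edge
prediction score is the Jaccard coefficient
E(i,j) = N(G_i ∩ G_j) / N(G_i ∪ G_j).  Up- and down-regulated networks are
built independently and centered on the exposure: gene nodes are exactly the
genes the exposure shares with at least one disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .diffexpr import DiseaseGeneSet

EXPORT_FORMATS = ("graphml", "sif", "tsv")


class UndefinedScoreError(ValueError):
    """Jaccard score requested for two empty sets."""


def shared_genes(set_i, set_j) -> tuple[int, frozenset]:
    """Number of shared dysregulated genes and the intersection itself."""
    inter = frozenset(set_i) & frozenset(set_j)
    return len(inter), inter


def jaccard_score(set_i, set_j) -> float:
    """Intersection-over-union edge prediction score, in [0, 1]."""
    a, b = frozenset(set_i), frozenset(set_j)
    union = a | b
    if not union:
        raise UndefinedScoreError("Jaccard score undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass(frozen=True)
class Association:
    """Disease-disease association record: shared count and Jaccard score."""

    source: str
    target: str
    n_shared: int
    jaccard: float
    genes: frozenset


@dataclass(eq=False)
class DiseasomeNetwork:
    """Direction-stratified bipartite disease-gene graph with association records."""

    direction: str
    exposure_id: str
    disease_ids: tuple
    graph: nx.Graph
    associations: list

    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    def disease_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "disease")

    def shared_count(self, disease_id: str) -> int:
        """n_ij between the exposure and one disease."""
        for assoc in self.associations:
            if {assoc.source, assoc.target} == {self.exposure_id, disease_id}:
                return assoc.n_shared
        raise KeyError(disease_id)


def build_diseasome(exposure: DiseaseGeneSet, diseases: list,
                    direction: str) -> DiseasomeNetwork:
    """Build the exposure-centered network for one direction ('up'/'down').

    Gene nodes are ∪_d (G_exposure ∩ G_d); every retained gene links to the
    exposure and to each disease whose significant set contains it.
    Association records cover all exposure-disease pairs plus disease-disease
    pairs sharing at least one gene.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    ids = [exposure.disease_id] + [d.disease_id for d in diseases]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate disease ids: {ids}")

    exp_set = exposure.for_direction(direction)
    dsets = {d.disease_id: d.for_direction(direction) for d in diseases}
    gene_nodes = frozenset().union(*(exp_set & s for s in dsets.values())) if dsets else frozenset()

    g = nx.Graph()
    g.add_node(exposure.disease_id, kind="disease", role="exposure", direction=direction)
    for did in sorted(dsets):
        g.add_node(did, kind="disease", role="disease", direction=direction)
    for gene in sorted(gene_nodes):
        g.add_node(gene, kind="gene", direction=direction)
        g.add_edge(exposure.disease_id, gene, kind="disease-gene")
        for did in sorted(dsets):
            if gene in dsets[did]:
                g.add_edge(did, gene, kind="disease-gene")

    associations: list[Association] = []
    all_sets = {exposure.disease_id: exp_set, **dsets}
    ordered = [exposure.disease_id] + sorted(dsets)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            n, inter = shared_genes(all_sets[a], all_sets[b])
            if a != exposure.disease_id and n == 0:
                continue  # disease-disease pairs require >=1 shared gene
            union = all_sets[a] | all_sets[b]
            score = len(inter) / len(union) if union else float("nan")
            associations.append(Association(a, b, n, score, inter))

    return DiseasomeNetwork(direction, exposure.disease_id, tuple(sorted(dsets)),
                            g, associations)


def multi_disease_genes(network: DiseasomeNetwork, k: int) -> frozenset:
    """Genes whose bipartite degree is >= k (the exposure counts as one endpoint)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return frozenset(
        n for n, d in network.graph.nodes(data=True)
        if d["kind"] == "gene" and network.graph.degree(n) >= k
    )


def export_network(network: DiseasomeNetwork, path, fmt: str = "tsv") -> None:
    """Write the network; node/edge ordering is lexicographic for determinism.

    graphml: full graph with node/edge attributes (Cytoscape-compatible).
    sif:     one line per bipartite disease-gene edge.
    tsv:     bipartite edges plus association records with n_shared/jaccard.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}")
    if fmt == "graphml":
        g = nx.Graph()
        for n in sorted(network.graph.nodes):
            g.add_node(n, **network.graph.nodes[n])
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            g.add_edge(u, v, **network.graph.edges[u, v])
        for assoc in network.associations:
            g.add_edge(assoc.source, assoc.target, kind="association",
                       n_shared=assoc.n_shared, jaccard=float(assoc.jaccard))
        nx.write_graphml(g, path)
        return
    lines = []
    if fmt == "sif":
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            lines.append(f"{u}\tassociates\t{v}")
    else:
        lines.append("source\ttarget\ttype\tn_shared\tjaccard")
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            lines.append(f"{u}\t{v}\tdisease-gene\t\t")
        for assoc in network.associations:
            lines.append(
                f"{assoc.source}\t{assoc.target}\tassociation\t{assoc.n_shared}"
                f"\t{assoc.jaccard:.10g}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
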