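"""Sequence similarity network construction, threshold sweep and
taxon-composition cluster classification.

The discovery computation: proteins are nodes; an undirected edge joins two
proteins whenever their pairwise bit score reaches the floor (default 50).
Raising the edge-score threshold fragments the network; a connected
component whose members all come from the producer lineage — with at least
one member from a producer taxon other than the focal species — is a
lineage-specific cluster (NSC). The minimal threshold at which a gene first
sits in such a cluster is its emergence threshold; a known pathway gene
serves as positive control for the sweep.

Exact duplicate sequences are collapsed to one representative node (the
smallest id), with multiplicity recorded, so trivially identical transcripts
cannot inflate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import TaxonConfig
from .pairalign import AlignParams, bit_score, raw_score
from .seqio_orf import ProteinRecord

LABEL_NSC = "NSC"
LABEL_FOCAL = "focal_specific"
LABEL_SHARED = "shared"


class SSNError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterLabel:
    label: str
    taxon_counts: Mapping[str, int]


@dataclass(frozen=True)
class ClusterPartition:
    """Connected components at one edge-score threshold.

    Singleton clusters (including nodes with no edge at the graph floor)
    are the 'unclustered' set.
    """

    threshold: float
    clusters: tuple[frozenset[str], ...]

    @property
    def singletons(self) -> tuple[frozenset[str], ...]:
        return tuple(c for c in self.clusters if len(c) == 1)

    def cluster_of(self, node_id: str) -> frozenset[str]:
        for c in self.clusters:
            if node_id in c:
                return c
        raise KeyError(node_id)


@dataclass
class SSNGraph:
    """All-vs-all similarity network over deduplicated protein nodes."""

    graph: nx.Graph
    floor: float
    params: AlignParams
    duplicates: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def taxon_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["taxon"]

    def protein(self, node_id: str) -> ProteinRecord:
        return self.graph.nodes[node_id]["record"]


@dataclass(frozen=True)
class SweepResult:
    thresholds: tuple[float, ...]
    partitions: tuple[ClusterPartition, ...]
    labels: tuple[Mapping[frozenset, ClusterLabel], ...]
    emergence: Mapping[str, float | None]

    def partition_at(self, threshold: float) -> ClusterPartition:
        try:
            return self.partitions[self.thresholds.index(threshold)]
        except ValueError:
            raise SSNError(f"threshold {threshold} not in sweep schedule") from None

    def labels_at(self, threshold: float) -> Mapping[frozenset, ClusterLabel]:
        return self.labels[self.thresholds.index(threshold)]


def collapse_duplicates(
    proteins: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, tuple[str, ...]]]:
    """One representative per unique (taxon, sequence); multiplicity recorded."""
    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for p in sorted(proteins, key=lambda r: r.id):
        groups.setdefault((p.taxon, p.seq), []).append(p)
    reps: list[ProteinRecord] = []
    dup_map: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        rep = members[0]  # smallest id
        reps.append(rep)
        dup_map[rep.id] = tuple(m.id for m in members)
    reps.sort(key=lambda r: r.id)
    return reps, dup_map


def build_ssn(
    proteins: Sequence[ProteinRecord],
    p: AlignParams | None = None,
    floor: float = 50.0,
) -> SSNGraph:
    """All-vs-all local alignment; keep edges with bit score >= floor."""
    p = p or AlignParams()
    if len(proteins) < 2:
        raise SSNError("need at least 2 proteins to build a network")
    if any(not pr.taxon for pr in proteins):
        raise SSNError("every protein needs a taxon label")
    reps, dup_map = collapse_duplicates(proteins)
    g = nx.Graph()
    for rec in reps:
        g.add_node(rec.id, taxon=rec.taxon, record=rec, multiplicity=len(dup_map[rec.id]))
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            bits = bit_score(raw_score(a.seq, b.seq, p))
            if bits >= floor:
                g.add_edge(a.id, b.id, score=bits)
    return SSNGraph(graph=g, floor=floor, params=p, duplicates=dup_map)


def components_at(g: SSNGraph, t: float) -> ClusterPartition:
    """Connected components of the subgraph of edges with score >= t."""
    if t < g.floor:
        raise SSNError(
            f"threshold {t} below graph floor {g.floor}: edges below the floor were never computed"
        )
    sub = nx.Graph()
    sub.add_nodes_from(g.graph.nodes)
    sub.add_edges_from(
        (u, v) for u, v, s in g.graph.edges(data="score") if s >= t
    )
    comps = [frozenset(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: min(c))
    return ClusterPartition(threshold=t, clusters=tuple(comps))


def classify_cluster(
    cluster: Iterable[str], g: SSNGraph, cfg: TaxonConfig
) -> ClusterLabel:
    """Label a component by its taxon composition.

    shared          — any member from a non-producer taxon
    focal_specific  — every member from the focal taxon
    NSC             — no non-producer member and >=1 non-focal producer member
    """
    counts: dict[str, int] = {}
    for node in sorted(cluster):
        tax = g.taxon_of(node)
        cfg.require_known(tax)
        counts[tax] = counts.get(tax, 0) + 1
    if not counts:
        raise SSNError("empty cluster")
    if any(t in cfg.nonproducers for t in counts):
        label = LABEL_SHARED
    elif set(counts) == {cfg.focal}:
        label = LABEL_FOCAL
    else:
        label = LABEL_NSC
    return ClusterLabel(label=label, taxon_counts=counts)


def sweep(
    g: SSNGraph,
    start: float,
    step: float,
    stop: float,
    cfg: TaxonConfig,
    controls: Sequence[str] = (),
) -> SweepResult:
    """Raise the edge-score threshold from start to stop in fixed increments.

    For each control gene the emergence threshold is the minimal threshold
    at which its cluster is labelled NSC; a control that never lands in an
    NSC is reported with emergence None.
    """
    if start < g.floor:
        raise SSNError(f"sweep start {start} below graph floor {g.floor}")
    if step <= 0:
        raise SSNError("sweep step must be positive")
    missing = [c for c in controls if c not in g.graph]
    if missing:
        raise SSNError(f"control gene(s) not in graph: {missing}")
    thresholds: list[float] = []
    t = float(start)
    while t <= stop + 1e-9:
        thresholds.append(round(t, 6))
        t += step
    partitions: list[ClusterPartition] = []
    labelings: list[dict[frozenset, ClusterLabel]] = []
    emergence: dict[str, float | None] = {c: None for c in controls}
    for t in thresholds:
        part = components_at(g, t)
        labels = {c: classify_cluster(c, g, cfg) for c in part.clusters}
        partitions.append(part)
        labelings.append(labels)
        for c in controls:
            if emergence[c] is None:
                cl = part.cluster_of(c)
                if labels[cl].label == LABEL_NSC:
                    emergence[c] = t
    return SweepResult(
        thresholds=tuple(thresholds),
        partitions=tuple(partitions),
        labels=tuple(labelings),
        emergence=emergence,
    )


def candidate_pool(
    g: SSNGraph,
    partition: ClusterPartition,
    labels: Mapping[frozenset, ClusterLabel],
    cfg: TaxonConfig,
) -> dict[str, str]:
    """Focal-taxon genes that are candidates at one threshold.

    Returns node id -> pool label: members of NSC clusters, members of
    focal-specific clusters, and unclustered (singleton) focal genes.
    Collapsed duplicate ids inherit their representative's pool label.
    """
    pool: dict[str, str] = {}
    for cluster in partition.clusters:
        lab = labels[cluster].label
        for node in sorted(cluster):
            if g.taxon_of(node) != cfg.focal:
                continue
            if len(cluster) == 1:
                pool[node] = "unclustered"
            elif lab in (LABEL_NSC, LABEL_FOCAL):
                pool[node] = lab
        # shared multi-member clusters contribute no candidates
    expanded = dict(pool)
    for rep, dups in g.duplicates.items():
        if rep in pool:
            for d in dups:
                expanded[d] = pool[rep]
    return expanded


def export_network(
    g: SSNGraph,
    partition: ClusterPartition,
    labels: Mapping[frozenset, ClusterLabel],
    out_dir: str | Path,
    graphml: bool = False,
) -> None:
    """Write the edge list, node attributes and (optionally) GraphML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        sorted((min(u, v), max(u, v), s) for u, v, s in g.graph.edges(data="score")),
        columns=["u", "v", "score"],
    )
    edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.6f")
    cluster_id = {}
    node_label = {}
    for k, cluster in enumerate(partition.clusters, start=1):
        for node in cluster:
            cluster_id[node] = k
            node_label[node] = (
                "unclustered" if len(cluster) == 1 else labels[cluster].label
            )
    nodes = pd.DataFrame(
        [
            (
                n,
                g.taxon_of(n),
                cluster_id[n],
                node_label[n],
                g.graph.nodes[n]["multiplicity"],
            )
            for n in g.nodes
        ],
        columns=["id", "taxon", "cluster", "label", "multiplicity"],
    )
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    if graphml:
        gg = nx.Graph()
        for n in g.nodes:
            gg.add_node(n, taxon=g.taxon_of(n), label=node_label[n])
        for u, v, s in g.graph.edges(data="score"):
            gg.add_edge(u, v, score=float(s))
        nx.write_graphml(gg, out / "network.graphml")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read back an exported edge list (round-trip check / reuse)."""
    df = pd.read_csv(path, sep="\t")
    return [(str(u), str(v), float(s)) for u, v, s in df.itertuples(index=False)]
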