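"""End-to-end screen: baits -> homologs -> network -> sweep -> report.

Glue that composes the stage modules the way the discovery screen ran:
keyword-scoped focal baits, closest homolog per bait per foreign
transcriptome, all-vs-all network over baits + homologs, upward threshold
sweep with NSC classification, and candidate ranking fused with bait
coexpression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import AnnotationTable, KeywordScope, select_baits
from .coexpression import (
    CandidateReport,
    ExpressionMatrix,
    pearson_vs_bait,
    rank_candidates,
)
from .config import TaxonConfig
from .pairalign import AlignParams, best_homolog
from .seqio_orf import OrfRule, ProteinRecord, Transcript, extract_orfs
from .ssn_graph import SSNGraph, SweepResult, build_ssn, sweep


@dataclass
class ScreenResult:
    baits: list[ProteinRecord]
    homologs: list[ProteinRecord]
    homolog_table: list[tuple[str, str, str, float, float]]  # bait, taxon, hit, raw, bits
    graph: SSNGraph
    sweep: SweepResult
    r_by_node: dict[str, float | None]
    report: CandidateReport


def proteomes_from_transcripts(
    transcripts: Mapping[str, Sequence[Transcript]], rule: OrfRule
) -> dict[str, list[ProteinRecord]]:
    """Translate every taxon's transcripts under the ORF rule."""
    return {
        taxon: [orf for t in ts for orf in extract_orfs(t, rule)]
        for taxon, ts in transcripts.items()
    }


def retrieve_homologs(
    baits: Sequence[ProteinRecord],
    foreign: Mapping[str, Sequence[ProteinRecord]],
    params: AlignParams,
) -> tuple[list[ProteinRecord], list[tuple[str, str, str, float, float]]]:
    """Closest homolog of each bait in each foreign taxon (deduplicated)."""
    table: list[tuple[str, str, str, float, float]] = []
    hits: dict[str, ProteinRecord] = {}
    for bait in baits:
        for taxon in sorted(foreign):
            rec, res = best_homolog(bait, list(foreign[taxon]), params)
            table.append((bait.id, taxon, rec.id, res.score, res.norm_score))
            hits.setdefault(rec.id, rec)
    return [hits[k] for k in sorted(hits)], table


def evaluate_against_truth(sim, result: "ScreenResult") -> dict:
    """Score a screen of synthetic data against the generator's bookkeeping.

    A planted family counts as recovered when, at some sweep threshold, its
    members present in the network form exactly one complete NSC-labelled
    cluster. Also reports the control's emergence threshold against the
    generation-time forced interval, and whether the planted pathway genes
    occupy the top of the candidate report.
    """
    truth = sim.truth
    g = result.graph
    node_ids = set(g.graph.nodes)

    def nodes_of(transcript_ids) -> frozenset[str]:
        present = set()
        for tid in transcript_ids:
            for node in node_ids:
                if node == tid or node.startswith(tid + "_orf"):
                    present.add(node)
        return frozenset(present)

    recovered: dict[str, bool] = {}
    for fam in truth.nsc_families:
        members = nodes_of(truth.nsc_members[fam])
        ok = False
        if members:
            for part, labels in zip(result.sweep.partitions, result.sweep.labels):
                if members in part.clusters and labels[members].label == "NSC":
                    ok = True
                    break
        recovered[fam] = ok

    control_nodes = nodes_of([truth.control_transcript])
    emergence = None
    for node in control_nodes:
        emergence = result.sweep.emergence.get(node, emergence)
    lo, hi = truth.forced_interval[truth.family_of[truth.control_transcript]]
    in_interval = emergence is not None and lo < emergence <= hi

    pathway_nodes = nodes_of(truth.pathway_transcripts)
    top = list(result.report.gene_ids[: len(pathway_nodes)])
    top_hits = sum(1 for n in top if n in pathway_nodes)

    return {
        "recovered": recovered,
        "n_recovered": sum(recovered.values()),
        "n_planted": len(truth.nsc_families),
        "control_emergence": emergence,
        "forced_interval": (lo, hi),
        "control_in_interval": in_interval,
        "pathway_top_hits": top_hits,
        "n_pathway_present": len(pathway_nodes),
    }


def run_screen(
    transcripts: Mapping[str, Sequence[Transcript]],
    annotation: AnnotationTable,
    expression: ExpressionMatrix,
    cfg: TaxonConfig,
    scope: KeywordScope,
    bait_gene: str,
    controls: Sequence[str] = (),
    rule: OrfRule | None = None,
    params: AlignParams | None = None,
    floor: float = 50.0,
    start: float = 50.0,
    step: float = 5.0,
    stop: float = 200.0,
    report_threshold: float | None = None,
    top_k: int | None = None,
) -> ScreenResult:
    """Run the full screen; ids in ``controls``/``bait_gene`` are transcript ids.

    ``report_threshold`` defaults to the sweep threshold at which the most
    focal genes sit in NSC-labelled clusters (smallest such threshold on
    ties) — the analogue of raising the cutoff until the lineage-specific
    candidates have emerged.
    """
    rule = rule or OrfRule()
    params = params or AlignParams()
    proteomes = proteomes_from_transcripts(transcripts, rule)
    baits = select_baits(annotation, scope, proteomes[cfg.focal])
    if not baits:
        raise ValueError(f"no baits matched scope {scope.name!r}")
    foreign = {t: ps for t, ps in proteomes.items() if t != cfg.focal}
    homologs, table = retrieve_homologs(baits, foreign, params)
    graph = build_ssn(list(baits) + homologs, params, floor=floor)

    control_nodes = []
    for c in controls:
        matches = [b.id for b in baits if b.source_transcript == c or b.id == c]
        if not matches:
            raise ValueError(f"control {c!r} is not among the baits")
        control_nodes.extend(matches)
    sw = sweep(graph, start, step, stop, cfg, controls=control_nodes)

    if report_threshold is None:
        best_count = -1
        report_threshold = sw.thresholds[-1]
        for t, part_t, labels_t in zip(sw.thresholds, sw.partitions, sw.labels):
            count = sum(
                1
                for c in part_t.clusters
                if labels_t[c].label == "NSC" and len(c) > 1
                for node in c
                if graph.taxon_of(node) == cfg.focal
            )
            if count > best_count:
                best_count = count
                report_threshold = t

    r_by_transcript = pearson_vs_bait(expression, bait_gene)
    r_by_node: dict[str, float | None] = {}
    for prot in list(baits) + homologs:
        src = prot.source_transcript or prot.id
        r_by_node[prot.id] = r_by_transcript.get(src)

    report = rank_candidates(sw, graph, report_threshold, r_by_node, cfg, top_k=top_k)
    return ScreenResult(
        baits=baits,
        homologs=homologs,
        homolog_table=table,
        graph=graph,
        sweep=sw,
        r_by_node=r_by_node,
        report=report,
    )
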