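"""Sweep the edge-score threshold upward and classify clusters by taxon mix.

From the floor of 50 bits up to 200 in increments of 5, connected
components are recomputed and labelled: shared (reaches a non-producer),
focal_specific (focal taxon only), or NSC (producer lineage only, with at
least one non-focal producer). The positive-control gene — the focal member
of the first planted family — must land in an NSC at some threshold; its
emergence threshold validates the sweep. Writes per-threshold cluster
membership and the emergence table under results/ssn/.
"""

import json
from pathlib import Path

import pandas as pd

from ssnscreen.config import TaxonConfig
from ssnscreen.pairalign import AlignParams
from ssnscreen.seqio_orf import read_protein_fasta
from ssnscreen.ssn_graph import build_ssn, sweep

ROOT = Path(__file__).resolve().parents[1] / "results"
START, STEP, STOP = 50.0, 5.0, 200.0


def main() -> None:
    truth = json.loads((ROOT / "sim" / "truth.json").read_text())
    control_node = truth["control_transcript"] + "_orf1"
    baits = read_protein_fasta(ROOT / "baits.faa", taxon="M_speciosa", role="bait")
    foreign_ids = set()
    homolog_table = pd.read_csv(ROOT / "ssn" / "homologs.tsv", sep="\t")
    homologs = []
    for taxon, group in homolog_table.groupby("taxon"):
        prots = {p.id: p for p in read_protein_fasta(ROOT / "proteomes" / f"{taxon}.faa", taxon=taxon)}
        for hit in sorted(set(group["hit_id"])):
            if hit not in foreign_ids:
                foreign_ids.add(hit)
                homologs.append(prots[hit].with_role("homolog"))
    g = build_ssn(list(baits) + homologs, AlignParams(), floor=START)
    cfg = TaxonConfig()
    sw = sweep(g, START, STEP, STOP, cfg, controls=[control_node])
    rows = []
    for t, part, labels in zip(sw.thresholds, sw.partitions, sw.labels):
        for k, c in enumerate(part.clusters, start=1):
            lab = "unclustered" if len(c) == 1 else labels[c].label
            for node in sorted(c):
                rows.append((t, k, node, g.taxon_of(node), lab))
    pd.DataFrame(
        rows, columns=["threshold", "cluster_id", "member", "taxon", "label"]
    ).to_csv(ROOT / "ssn" / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(sw.emergence.items()), columns=["control", "emergence_threshold"]
    ).to_csv(ROOT / "ssn" / "emergence.tsv", sep="\t", index=False)

    em = sw.emergence[control_node]
    lo, hi = truth["forced_interval"][truth["family_of"][truth["control_transcript"]]]
    print(f"control {control_node} emerges in an NSC at threshold {em}")
    print(f"  generation-time forced interval: ({lo:.1f}, {hi:.1f}] bits "
          f"-> {'consistent' if lo < em <= hi else 'INCONSISTENT'}")
    for t in (50.0, 100.0, 150.0, 200.0):
        labels = sw.labels_at(t)
        part = sw.partition_at(t)
        n_nsc = sum(1 for c in part.clusters if len(c) > 1 and labels[c].label == "NSC")
        print(f"  threshold {t:5.0f}: {len(part.clusters)} clusters, {n_nsc} NSC")


if __name__ == "__main__":
    main()
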