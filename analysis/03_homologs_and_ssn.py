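"""Retrieve each bait's closest homolog per foreign taxon and build the SSN.

For every bait, the highest-scoring protein in each of the five other
proteomes joins the network. All-vs-all local alignment (BLOSUM62, gap
11/1) gives bit-score edges; pairs below the floor of 50 bits are dropped.
Writes the homolog table and the network (edge list, node attributes,
GraphML) under results/ssn/.
"""

from pathlib import Path

import pandas as pd

from ssnscreen.pairalign import AlignParams
from ssnscreen.pipeline import retrieve_homologs
from ssnscreen.seqio_orf import read_protein_fasta
from ssnscreen.ssn_graph import build_ssn, components_at, classify_cluster, export_network
from ssnscreen.config import TaxonConfig

ROOT = Path(__file__).resolve().parents[1] / "results"
TAXA = ("M_speciosa", "U_guianensis", "U_rhynchophylla",
        "C_pubescens", "C_arabica", "C_roseus")
FLOOR = 50.0


def main() -> None:
    params = AlignParams()
    baits = read_protein_fasta(ROOT / "baits.faa", taxon="M_speciosa", role="bait")
    foreign = {
        t: read_protein_fasta(ROOT / "proteomes" / f"{t}.faa", taxon=t)
        for t in TAXA if t != "M_speciosa"
    }
    homologs, table = retrieve_homologs(baits, foreign, params)
    out = ROOT / "ssn"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        table, columns=["bait_id", "taxon", "hit_id", "raw_score", "norm_score"]
    ).to_csv(out / "homologs.tsv", sep="\t", index=False, float_format="%.6f")
    print(f"{len(table)} bait x taxon assignments -> {len(homologs)} distinct homologs")

    g = build_ssn(list(baits) + homologs, params, floor=FLOOR)
    cfg = TaxonConfig()
    part = components_at(g, FLOOR)
    labels = {c: classify_cluster(c, g, cfg) for c in part.clusters}
    export_network(g, part, labels, out, graphml=True)
    n_multi = sum(1 for c in part.clusters if len(c) > 1)
    print(f"SSN: {len(g.nodes)} nodes, {g.graph.number_of_edges()} edges >= {FLOOR} bits; "
          f"{n_multi} clusters at the floor")


if __name__ == "__main__":
    main()
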