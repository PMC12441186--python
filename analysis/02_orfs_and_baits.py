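"""Translate every taxon's transcripts and select the focal bait family.

Applies the ORF rule (ATG start, >=100 residues) to all six transcriptomes,
then scopes the focal proteome to reductase/dehydrogenase annotations.
Writes per-taxon proteomes and the bait FASTA under results/.
"""

from pathlib import Path

from ssnscreen import REDUCTASE_SCOPE, select_baits, write_fasta
from ssnscreen.annotation import AnnotationTable
from ssnscreen.seqio_orf import OrfRule, extract_orfs, read_fasta

ROOT = Path(__file__).resolve().parents[1] / "results"
FOCAL = "M_speciosa"
TAXA = ("M_speciosa", "U_guianensis", "U_rhynchophylla",
        "C_pubescens", "C_arabica", "C_roseus")


def main() -> None:
    rule = OrfRule(min_len=100)
    prot_dir = ROOT / "proteomes"
    prot_dir.mkdir(parents=True, exist_ok=True)
    proteomes = {}
    for taxon in TAXA:
        transcripts = read_fasta(ROOT / "sim" / f"{taxon}.transcripts.fasta", taxon)
        orfs = [o for t in transcripts for o in extract_orfs(t, rule)]
        write_fasta(orfs, prot_dir / f"{taxon}.faa")
        proteomes[taxon] = orfs
        print(f"{taxon}: {len(transcripts)} transcripts -> {len(orfs)} ORFs >=100 aa")
    table = AnnotationTable.from_tsv(ROOT / "sim" / "annotation.tsv")
    baits = select_baits(table, REDUCTASE_SCOPE, proteomes[FOCAL])
    write_fasta(baits, ROOT / "baits.faa")
    print(f"{len(baits)} baits matched scope {REDUCTASE_SCOPE.name} "
          f"({', '.join(REDUCTASE_SCOPE.keywords)})")


if __name__ == "__main__":
    main()
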