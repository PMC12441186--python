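"""Transcript I/O and ORF extraction.

Turns assembled transcriptome sequences into candidate protein sequences
using the screening rule applied throughout this pipeline: every open
reading frame starting at an ATG and translating to at least ``min_len``
residues (default 100) is reported as a protein.

Transcripts from de novo assemblies are treated as oriented (sense-strand)
by default; reverse-strand scanning can be enabled per :class:`OrfRule`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input or duplicate record ids."""


@dataclass(frozen=True)
class Transcript:
    """A stranded nucleotide sequence from one taxon's transcriptome."""

    id: str
    taxon: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid nucleotide(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A translated ORF (or externally provided protein).

    ``frame`` is the 0-based reading-frame offset on the scanned strand and
    ``strand`` is '+' or '-'. ``start``/``end`` are 0-based half-open
    coordinates of the coding region (excluding the stop codon) on the
    *forward* strand of the source transcript, so that re-slicing and
    re-translating reproduces ``seq`` exactly.
    """

    id: str
    taxon: str
    seq: str
    source_transcript: str | None = None
    frame: int = 0
    strand: str = "+"
    start: int | None = None
    end: int | None = None
    annotation: str | None = None
    role: str = "other"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")
        if "*" in self.seq:
            raise ValueError(f"protein {self.id}: internal stop symbol")
        bad = set(self.seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"protein {self.id}: invalid residue(s) {sorted(bad)}")
        if self.role not in {"bait", "homolog", "control", "other"}:
            raise ValueError(f"protein {self.id}: unknown role {self.role!r}")

    def with_role(self, role: str) -> "ProteinRecord":
        return replace(self, role=role)


@dataclass(frozen=True)
class OrfRule:
    """Parameters of the ORF screening rule.

    min_len counts residues of the translated product including the initial
    methionine and excluding the stop. With ``require_stop`` False (the
    default), ORFs running off the 3' end are kept — assembled transcripts
    are frequently 3'-incomplete.
    """

    min_len: int = 100
    start_codon: str = "ATG"
    require_stop: bool = False
    scan_reverse_strand: bool = False
    codon_table: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if len(self.start_codon) != 3:
            raise ValueError("start_codon must be a codon")
        if self.codon_table != 1:
            raise ValueError("only the standard genetic code is supported")


def translate_codons(nt: str) -> str:
    """Translate an in-frame nucleotide stretch; codons containing N -> X.

    Trailing bases not forming a full codon are ignored. Stop codons are not
    expected inside ``nt`` (callers slice up to the stop).
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in _STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at offset {i}")
        else:
            aa.append(_CODON_TO_AA[codon])
    return "".join(aa)


def _scan_strand(seq: str, rule: OrfRule) -> list[tuple[int, int, int, str]]:
    """Yield (frame, start, end, protein) for maximal ORFs on one strand.

    For each frame, codons are walked 5'->3'; within each inter-stop
    segment only the 5'-most ATG is reported (longest-per-stop convention).
    ``end`` excludes the stop codon. Codons containing N are translated to X
    and never terminate an ORF.
    """
    found = []
    n = len(seq)
    for frame in range(3):
        pending_start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            is_stop = "N" not in codon and codon in _STOP_CODONS
            if is_stop:
                if pending_start is not None:
                    prot = translate_codons(seq[pending_start:i])
                    if len(prot) >= rule.min_len:
                        found.append((frame, pending_start, i, prot))
                    pending_start = None
            elif pending_start is None and codon == rule.start_codon:
                pending_start = i
            i += 3
        if pending_start is not None and not rule.require_stop:
            # 3'-incomplete ORF: translate up to the last full codon
            end = pending_start + (n - pending_start) // 3 * 3
            prot = translate_codons(seq[pending_start:end])
            if len(prot) >= rule.min_len:
                found.append((frame, pending_start, end, prot))
    return found


def extract_orfs(t: Transcript, rule: OrfRule | None = None) -> list[ProteinRecord]:
    """Report every qualifying ORF of a transcript as a ProteinRecord.

    Output is ordered by forward-strand start position (forward-strand ORFs
    first, then reverse-strand ones if enabled), deterministically. Record
    ids are ``<transcript_id>_orf<k>`` in output order.
    """
    rule = rule or OrfRule()
    hits: list[tuple[str, int, int, int, str]] = []
    by_pos = lambda h: (h[1], h[0])  # start position, then frame
    for frame, start, end, prot in sorted(_scan_strand(t.seq, rule), key=by_pos):
        hits.append(("+", frame, start, end, prot))
    if rule.scan_reverse_strand:
        rc = str(Seq(t.seq).reverse_complement())
        n = len(t.seq)
        rev = []
        for frame, start, end, prot in _scan_strand(rc, rule):
            # map back to forward-strand coordinates (half-open)
            rev.append((frame, n - end, n - start, prot))
        for frame, start, end, prot in sorted(rev, key=by_pos):
            hits.append(("-", frame, start, end, prot))
    records = []
    for k, (strand, frame, start, end, prot) in enumerate(hits, start=1):
        records.append(
            ProteinRecord(
                id=f"{t.id}_orf{k}",
                taxon=t.taxon,
                seq=prot,
                source_transcript=t.id,
                frame=frame,
                strand=strand,
                start=start,
                end=end,
            )
        )
    return records


def retranslate(record: ProteinRecord, transcript: Transcript) -> str:
    """Re-translate the cited coordinates of ``transcript`` (coordinate check)."""
    if record.start is None or record.end is None:
        raise ValueError(f"{record.id}: no coordinates recorded")
    region = transcript.seq[record.start : record.end]
    if record.strand == "-":
        region = str(Seq(region).reverse_complement())
    return translate_codons(region)


def read_fasta(path: str | Path, taxon: str) -> list[Transcript]:
    """Read nucleotide FASTA into Transcripts; ids are the first header token."""
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(Transcript(id=rec.id, taxon=taxon, seq=str(rec.seq)))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def read_protein_fasta(path: str | Path, taxon: str, role: str = "other") -> list[ProteinRecord]:
    """Read a protein FASTA (as written by :func:`write_fasta`)."""
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        parts = rec.description.split()
        tax = parts[1] if len(parts) > 1 else taxon
        out.append(ProteinRecord(id=rec.id, taxon=tax, seq=str(rec.seq).upper(), role=role))
    return out


def write_fasta(records: Sequence[Transcript | ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped, header '<id> <taxon>'."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.taxon) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)
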