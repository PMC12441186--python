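"""ORF extraction and FASTA round-trips against an exhaustive-scan oracle."""

import numpy as np
import pytest

from ssnscreen.seqio_orf import (
    FastaParseError,
    OrfRule,
    ProteinRecord,
    Transcript,
    extract_orfs,
    read_fasta,
    read_protein_fasta,
    retranslate,
    write_fasta,
)

from oracles import oracle_orfs

SENSE_CODON = "GCT"  # Ala


def random_transcript(rng, length, tid="t1") -> Transcript:
    seq = "".join(rng.choice(("A", "C", "G", "T"), size=length))
    return Transcript(id=tid, taxon="tax", seq=seq)


class TestTranscriptValidation:
    def test_rejects_invalid_alphabet(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            Transcript(id="t", taxon="x", seq="ACGU")

    def test_normalizes_case(self):
        assert Transcript(id="t", taxon="x", seq="acgtn").seq == "ACGTN"

    def test_rejects_empty_id_and_seq(self):
        with pytest.raises(ValueError):
            Transcript(id="", taxon="x", seq="ACGT")
        with pytest.raises(ValueError):
            Transcript(id="t", taxon="x", seq="")


class TestOrfRule:
    def test_min_length_boundary(self):
        # ATG + 99 sense codons + stop -> exactly 100 residues: kept
        seq = "ATG" + SENSE_CODON * 99 + "TAA"
        t = Transcript(id="t", taxon="x", seq=seq)
        orfs = extract_orfs(t, OrfRule(min_len=100))
        assert len(orfs) == 1
        assert orfs[0].seq == "M" + "A" * 99
        # one sense codon fewer -> 99 residues: rejected
        short = Transcript(id="t", taxon="x", seq="ATG" + SENSE_CODON * 98 + "TAA")
        assert extract_orfs(short, OrfRule(min_len=100)) == []

    def test_no_start_codon(self):
        t = Transcript(id="t", taxon="x", seq="CCCCCCCCC")
        assert extract_orfs(t, OrfRule(min_len=1)) == []

    def test_no_stop_kept_unless_required(self):
        seq = "ATG" + SENSE_CODON * 30  # runs off the 3' end
        t = Transcript(id="t", taxon="x", seq=seq)
        assert len(extract_orfs(t, OrfRule(min_len=10))) == 1
        assert extract_orfs(t, OrfRule(min_len=10, require_stop=True)) == []

    def test_n_codons_translate_to_x_and_never_stop(self):
        # TNA could resolve to a stop but must translate as X
        seq = "ATG" + "TNA" + SENSE_CODON * 20 + "TAA"
        t = Transcript(id="t", taxon="x", seq=seq)
        orfs = extract_orfs(t, OrfRule(min_len=5))
        assert len(orfs) == 1
        assert orfs[0].seq == "MX" + "A" * 20

    def test_longest_per_stop_convention(self):
        # two in-frame ATGs sharing one stop: only the 5'-most is reported
        seq = "ATG" + SENSE_CODON * 5 + "ATG" + SENSE_CODON * 10 + "TAA"
        t = Transcript(id="t", taxon="x", seq=seq)
        orfs = extract_orfs(t, OrfRule(min_len=5))
        assert len(orfs) == 1
        assert len(orfs[0].seq) == 17

    def test_invalid_rule(self):
        with pytest.raises(ValueError):
            OrfRule(min_len=0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("require_stop", [False, True])
    def test_matches_exhaustive_atg_scan(self, rng, require_stop):
        for k in range(10):
            t = random_transcript(rng, 2000, tid=f"t{k}")
            got = {
                (o.start, o.end, o.seq)
                for o in extract_orfs(t, OrfRule(min_len=20, require_stop=require_stop))
            }
            assert got == oracle_orfs(t.seq, 20, require_stop=require_stop)

    def test_reverse_strand_matches_oracle_on_rc(self, rng):
        from Bio.Seq import Seq

        t = random_transcript(rng, 1500)
        rule = OrfRule(min_len=20, scan_reverse_strand=True)
        got_rev = {o.seq for o in extract_orfs(t, rule) if o.strand == "-"}
        rc = str(Seq(t.seq).reverse_complement())
        assert got_rev == {p for (_, _, p) in oracle_orfs(rc, 20)}

    def test_coordinate_honesty(self, rng):
        t = random_transcript(rng, 2000)
        for o in extract_orfs(t, OrfRule(min_len=20, scan_reverse_strand=True)):
            assert retranslate(o, t) == o.seq

    def test_count_monotone_in_min_len(self, rng):
        t = random_transcript(rng, 3000)
        counts = [len(extract_orfs(t, OrfRule(min_len=m))) for m in (5, 10, 20, 40, 80)]
        assert counts == sorted(counts, reverse=True)


class TestFastaRoundTrip:
    def test_transcript_round_trip(self, rng, tmp_path):
        ts = [random_transcript(rng, 200, tid=f"tr{k}") for k in range(5)]
        path = tmp_path / "t.fasta"
        write_fasta(ts, path)
        back = read_fasta(path, taxon="tax")
        assert back == ts

    def test_protein_round_trip(self, rng, tmp_path):
        prots = [
            ProteinRecord(id=f"p{k}", taxon="tax", seq="M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)))
            for k in range(100)
        ]
        path = tmp_path / "p.faa"
        write_fasta(prots, path)
        back = read_protein_fasta(path, taxon="tax")
        assert [(p.id, p.taxon, p.seq) for p in back] == [
            (p.id, p.taxon, p.seq) for p in prots
        ]

    def test_empty_file_and_empty_list(self, tmp_path):
        path = tmp_path / "e.fasta"
        write_fasta([], path)
        assert read_fasta(path, taxon="tax") == []

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "d.fasta"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="duplicate"):
            read_fasta(path, taxon="tax")

    def test_bad_record_named_in_error(self, tmp_path):
        path = tmp_path / "b.fasta"
        path.write_text(">ok\nACGT\n>bad\nACQT\n")
        with pytest.raises(FastaParseError, match="bad"):
            read_fasta(path, taxon="tax")
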