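"""Pairwise protein alignment scoring, identity and best-homolog retrieval.

Alignment is optimal affine-gap dynamic programming via Bio.Align's
PairwiseAligner, with BLOSUM62 and gap open 11 / extend 1 (NCBI convention:
a gap of length k costs 11 + k). Local mode drives homolog retrieval and
network edge weights; global mode drives identity reporting.

Edge scores for the similarity network are expressed as bit scores via the
Karlin–Altschul transform, bits = (lambda*S - ln K) / ln 2 with the standard
gapped-BLOSUM62 constants lambda = 0.267, K = 0.041. This puts thresholds on
the familiar alignment-score (~ -log10 E-value) scale used by SSN tools;
raw scores remain available.

The unknown residue X scores 0 against every residue (neutral), so runs of
X neither reward nor penalize an alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio_orf import ProteinRecord

KARLIN_ALTSCHUL_LAMBDA = 0.267
KARLIN_ALTSCHUL_K = 0.041


class AlignmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.mode not in {"local", "global"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        available = substitution_matrices.load()
        if self.matrix not in available:
            raise ValueError(f"unknown substitution matrix {self.matrix!r}")


@dataclass(frozen=True)
class AlignResult:
    score: float
    norm_score: float
    identity_pct: float
    aln_len: int


def bit_score(raw: float) -> float:
    """Karlin–Altschul bit score of a raw BLOSUM62 alignment score."""
    return (KARLIN_ALTSCHUL_LAMBDA * raw - math.log(KARLIN_ALTSCHUL_K)) / math.log(2)


@lru_cache(maxsize=8)
def _neutral_x_matrix(name: str):
    """Load a substitution matrix with the X row/column zeroed."""
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        xi = m.alphabet.index("X")
        for j in range(len(m.alphabet)):
            m[xi, j] = 0.0
            m[j, xi] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _neutral_x_matrix(matrix)
    # NCBI convention: first gapped column costs open+extend, each further one extend
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    al.mode = mode
    return al


def raw_score(a_seq: str, b_seq: str, p: AlignParams) -> float:
    """Optimal alignment score only (no traceback) — the hot path."""
    if not a_seq or not b_seq:
        raise AlignmentInputError("empty sequence")
    al = _aligner(p.matrix, p.gap_open, p.gap_extend, p.mode)
    return float(al.score(a_seq, b_seq))


def align(a: ProteinRecord, b: ProteinRecord, p: AlignParams | None = None) -> AlignResult:
    """Align two proteins; identity is per aligned column including gaps.

    Score and identity are symmetric in (a, b): the pair is canonicalized by
    sequence before traceback so the reported optimal alignment does not
    depend on argument order.
    """
    p = p or AlignParams()
    if not a.seq or not b.seq:
        raise AlignmentInputError("empty sequence")
    x, y = (a.seq, b.seq) if a.seq <= b.seq else (b.seq, a.seq)
    al = _aligner(p.matrix, p.gap_open, p.gap_extend, p.mode)
    best = al.align(x, y)[0]
    counts = best.counts()
    aln_len = best.length
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    score = float(best.score)
    return AlignResult(
        score=score,
        norm_score=bit_score(score),
        identity_pct=identity,
        aln_len=aln_len,
    )


def percent_identity(a: ProteinRecord, b: ProteinRecord, p: AlignParams | None = None) -> int:
    """Global-alignment percent identity, rounded to the nearest integer."""
    p = p or AlignParams()
    if p.mode != "global":
        p = AlignParams(p.matrix, p.gap_open, p.gap_extend, "global")
    res = align(a, b, p)
    return int(round(res.identity_pct))


def best_homolog(
    bait: ProteinRecord,
    foreign: list[ProteinRecord],
    p: AlignParams | None = None,
) -> tuple[ProteinRecord, AlignResult]:
    """The foreign protein with the highest-scoring alignment to the bait.

    Ties on raw score break to the lexicographically smallest id. The
    returned record carries role='homolog'.
    """
    p = p or AlignParams()
    if not foreign:
        raise AlignmentInputError(
            f"no foreign proteins offered for bait {bait.id}: taxon contributes no node"
        )
    best_rec: ProteinRecord | None = None
    best_score = -math.inf
    for rec in foreign:
        s = raw_score(bait.seq, rec.seq, p)
        if s > best_score or (s == best_score and best_rec is not None and rec.id < best_rec.id):
            best_rec, best_score = rec, s
    assert best_rec is not None
    return best_rec.with_role("homolog"), align(bait, best_rec, p)
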