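"""Independent reference implementations used only to check the package.

Each oracle is written from the definition of the operation it checks,
sharing no code with the implementation under test: an exhaustive all-ATG
ORF scan, a textbook Gotoh affine-gap dynamic program over the raw BLOSUM62
table, a union-find connected-components pass, and the closed-form Pearson
formula.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_FWD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)

_B62 = substitution_matrices.load("BLOSUM62")


def oracle_translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        c = nt[i : i + 3]
        out.append("X" if "N" in c else _FWD[c])
    return "".join(out)


def oracle_orfs(
    seq: str, min_len: int, require_stop: bool = False, longest_per_stop: bool = True
) -> set[tuple[int, int, str]]:
    """Every qualifying ORF as (start, end, protein), by exhaustive ATG scan.

    For each ATG position, extend in frame to the first stop codon (codons
    containing N never stop); keep if the translation reaches min_len.
    With longest_per_stop, only the 5'-most ATG per (frame, stop) survives.
    """
    hits: dict[tuple[int, int], tuple[int, int, str]] = {}
    all_hits: set[tuple[int, int, str]] = set()
    for s in range(len(seq) - 2):
        if seq[s : s + 3] != "ATG":
            continue
        i = s
        end = None
        while i + 3 <= len(seq):
            c = seq[i : i + 3]
            if "N" not in c and c in _STOPS:
                end = i
                break
            i += 3
        if end is None:
            if require_stop:
                continue
            end = s + (len(seq) - s) // 3 * 3
            stop_key = (s % 3, -1)
        else:
            stop_key = (s % 3, end)
        prot = oracle_translate(seq[s:end])
        if len(prot) < min_len:
            continue
        hit = (s, end, prot)
        all_hits.add(hit)
        if stop_key not in hits or s < hits[stop_key][0]:
            hits[stop_key] = hit
    return set(hits.values()) if longest_per_stop else all_hits


def _score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def oracle_global_align(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Needleman–Wunsch/Gotoh optimal global score; gap of length k costs open + k*extend."""
    first = gap_open + gap_extend
    ninf = -math.inf
    n, m = len(a), len(b)
    M = [[ninf] * (m + 1) for _ in range(n + 1)]
    X = [[ninf] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[ninf] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -first - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -first - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def oracle_local_align(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Smith–Waterman/Gotoh optimal local score (zero floor)."""
    first = gap_open + gap_extend
    ninf = -math.inf
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[ninf] * (m + 1) for _ in range(n + 1)]
    Y = [[ninf] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def oracle_components(
    nodes: list[str], edges: list[tuple[str, str, float]], threshold: float
) -> set[frozenset[str]]:
    """Connected components over edges with score >= threshold, via union-find."""
    dsu = _DSU(nodes)
    for u, v, s in edges:
        if s >= threshold:
            dsu.union(u, v)
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(dsu.find(n), set()).add(n)
    return {frozenset(c) for c in comps.values()}


def oracle_pearson(x, y) -> float | None:
    """Textbook formula: covariance over product of standard deviations."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    if vx == 0 or vy == 0:
        return None
    return cov / math.sqrt(vx * vy)
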