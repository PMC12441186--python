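"""Bait-centric Pearson coexpression and candidate ranking.

Every gene's tissue expression profile (FPKM over tissue x replicate
samples) is correlated against a bait gene's profile with the plain sample
Pearson coefficient — replicates enter as samples, no log transform by
default, exactly a spreadsheet-style correlation. Coexpression is then
fused with the similarity-network cluster labels into a ranked candidate
report: lineage-specific (NSC) membership outranks focal-specific
membership outranks unclustered status, and within a label candidates sort
by r descending (undefined r last), then id. The fusion rule is a
convention of this pipeline; the original screen treated cluster membership
and coexpression as separate candidate streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TaxonConfig
from .ssn_graph import SSNGraph, SweepResult, candidate_pool

_LABEL_PRIORITY = {"NSC": 0, "focal_specific": 1, "unclustered": 2}


class ExpressionError(ValueError):
    pass


class ExpressionMatrix:
    """Genes x samples FPKM matrix (non-negative, unique gene ids)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ExpressionError("duplicate gene ids in expression matrix")
        if frame.shape[1] < 2:
            raise ExpressionError("need at least 2 samples for correlation")
        if (frame.values < 0).any():
            raise ExpressionError("FPKM values must be non-negative")
        self.frame = frame.astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.6f")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def profile(self, gene: str) -> np.ndarray:
        return self.frame.loc[gene].to_numpy()


def pearson_vs_bait(
    m: ExpressionMatrix, bait: str, log_transform: bool = False
) -> dict[str, float | None]:
    """Sample Pearson r of every gene's profile against the bait's.

    Genes with zero variance (including the degenerate case where the bait
    itself is flat) get r = None rather than NaN. With ``log_transform``,
    profiles are log2(FPKM + 1) first.
    """
    if bait not in m.frame.index:
        raise ExpressionError(f"bait gene {bait!r} not in expression matrix")
    x = m.frame.to_numpy()
    if log_transform:
        x = np.log2(x + 1.0)
    b = x[m.frame.index.get_loc(bait)]
    bc = b - b.mean()
    bnorm = float(np.sqrt((bc**2).sum()))
    out: dict[str, float | None] = {}
    for gene, row in zip(m.frame.index, x):
        rc = row - row.mean()
        rnorm = float(np.sqrt((rc**2).sum()))
        if bnorm == 0.0 or rnorm == 0.0:
            out[gene] = None
        else:
            out[gene] = float(np.dot(bc, rc) / (bnorm * rnorm))
    return out


@dataclass(frozen=True)
class CandidateReport:
    """Ranked focal-taxon candidates at a chosen network threshold."""

    frame: pd.DataFrame  # gene_id, label, emergence, r_bait, rank

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])


def rank_candidates(
    ssn: SweepResult,
    g: SSNGraph,
    threshold: float,
    r: Mapping[str, float | None],
    cfg: TaxonConfig,
    top_k: int | None = None,
) -> CandidateReport:
    """Fuse cluster labels and coexpression into a ranked candidate list.

    Pool at ``threshold``: focal genes in NSC or focal-specific clusters
    plus unclustered focal genes. Order: label priority (NSC first), then r
    descending with undefined r last, then gene id. Each gene's emergence
    threshold (minimal threshold at which its cluster is NSC-labelled) is
    reported where it exists within the sweep schedule.
    """
    part = ssn.partition_at(threshold)
    labels = ssn.labels_at(threshold)
    pool = candidate_pool(g, part, labels, cfg)

    emergence: dict[str, float | None] = {}
    for gene in pool:
        rep = gene if gene in g.graph else None
        if rep is None:  # collapsed duplicate: find its representative
            rep = next(k for k, dups in g.duplicates.items() if gene in dups)
        em = None
        for t, p_t, l_t in zip(ssn.thresholds, ssn.partitions, ssn.labels):
            cl = p_t.cluster_of(rep)
            if l_t[cl].label == "NSC":
                em = t
                break
        emergence[gene] = em

    rows = []
    for gene, label in pool.items():
        rows.append(
            {
                "gene_id": gene,
                "label": label,
                "emergence": emergence[gene],
                "r_bait": r.get(gene),
            }
        )
    rows.sort(
        key=lambda row: (
            _LABEL_PRIORITY[row["label"]],
            row["r_bait"] is None,
            -(row["r_bait"] or 0.0),
            row["gene_id"],
        )
    )
    if top_k is not None:
        rows = rows[:top_k]
    frame = pd.DataFrame(
        rows, columns=["gene_id", "label", "emergence", "r_bait"]
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    return CandidateReport(frame=frame)
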