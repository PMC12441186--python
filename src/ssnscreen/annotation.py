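"""Keyword-scoped bait selection from functional annotation tables.

Bait families are assembled by case-insensitive substring matching of
curated keywords (e.g. 'methyltransferase'; 'reductase'/'dehydrogenase';
'P450'/'oxidase'/'hydroxylase'/'monooxygenase') against each transcript's
free-text functional description, typically a SwissProt best-hit title.
Substring — not token — semantics is deliberate: it recovers compound names
such as 'O-methyltransferase' at the cost of occasional false positives,
which a screen-then-assay workflow tolerates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqio_orf import ProteinRecord

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class KeywordScope:
    """A named set of case-insensitive annotation keywords (any-substring)."""

    name: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ConfigError(f"scope {self.name!r}: at least one keyword required")
        if any(not k for k in self.keywords):
            raise ConfigError(f"scope {self.name!r}: empty keyword")
        object.__setattr__(self, "keywords", tuple(self.keywords))

    def matches(self, description: str | None) -> bool:
        if not description:
            return False
        low = description.lower()
        return any(k.lower() in low for k in self.keywords)


# The three scopes used in the discovery screen.
METHYLTRANSFERASE_SCOPE = KeywordScope("methyltransferase-scope", ("methyltransferase",))
REDUCTASE_SCOPE = KeywordScope("reductase-scope", ("reductase", "dehydrogenase"))
OXIDASE_SCOPE = KeywordScope(
    "oxidase-scope", ("P450", "oxidase", "hydroxylase", "monooxygenase")
)


class AnnotationTable:
    """Per-transcript functional descriptions, keyed by transcript id."""

    def __init__(self, frame: pd.DataFrame):
        if not {"transcript_id", "description"} <= set(frame.columns):
            raise ConfigError(
                "annotation table requires 'transcript_id' and 'description' columns"
            )
        if frame["transcript_id"].duplicated().any():
            dups = frame.loc[frame["transcript_id"].duplicated(), "transcript_id"]
            raise ConfigError(f"duplicate transcript ids in annotation: {list(dups[:5])}")
        self._desc: dict[str, str] = {
            str(t): ("" if pd.isna(d) else str(d))
            for t, d in zip(frame["transcript_id"], frame["description"])
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_records(cls, rows: Sequence[tuple[str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(rows, columns=["transcript_id", "description"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._desc.items()), columns=["transcript_id", "description"]
        ).to_csv(path, sep="\t", index=False)

    def description(self, transcript_id: str) -> str | None:
        return self._desc.get(transcript_id)

    def __len__(self) -> int:
        return len(self._desc)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._desc


def select_baits(
    table: AnnotationTable,
    scope: KeywordScope,
    proteins: Sequence[ProteinRecord],
) -> list[ProteinRecord]:
    """Proteins whose source transcript's description matches the scope.

    All ORFs of a keyword-matched transcript become baits (annotation is at
    transcript level). Returned with role='bait' and the matched description
    attached, in stable order by (source transcript id, protein id).
    Proteins whose transcript is absent from the table are skipped and
    logged.
    """
    missing: list[str] = []
    selected: list[ProteinRecord] = []
    for prot in proteins:
        tid = prot.source_transcript or prot.id
        desc = table.description(tid)
        if desc is None:
            missing.append(tid)
            continue
        if scope.matches(desc):
            selected.append(
                ProteinRecord(
                    id=prot.id,
                    taxon=prot.taxon,
                    seq=prot.seq,
                    source_transcript=prot.source_transcript,
                    frame=prot.frame,
                    strand=prot.strand,
                    start=prot.start,
                    end=prot.end,
                    annotation=desc,
                    role="bait",
                )
            )
    if missing:
        logger.info(
            "%d protein(s) had no annotation row (first: %s)",
            len(missing),
            missing[0],
        )
    selected.sort(key=lambda p: (p.source_transcript or p.id, p.id))
    return selected
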