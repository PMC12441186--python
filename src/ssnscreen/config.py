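"""Run configuration: taxon grouping and screen parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


class TaxonConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonConfig:
    """Producer-lineage vs non-producer grouping of the taxa under study.

    The default mirrors the six-transcriptome design of the screen this
    package implements: the focal producer (kratom, *Mitragyna speciosa*)
    plus two further producers of the Naucleeae tribe, against three
    non-producing relatives.
    """

    focal: str = "M_speciosa"
    producers: frozenset[str] = frozenset(
        {"M_speciosa", "U_guianensis", "U_rhynchophylla"}
    )
    nonproducers: frozenset[str] = frozenset(
        {"C_pubescens", "C_arabica", "C_roseus"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "producers", frozenset(self.producers))
        object.__setattr__(self, "nonproducers", frozenset(self.nonproducers))
        if self.focal not in self.producers:
            raise TaxonConfigError(f"focal taxon {self.focal!r} must be a producer")
        overlap = self.producers & self.nonproducers
        if overlap:
            raise TaxonConfigError(f"taxa in both groups: {sorted(overlap)}")

    @property
    def all_taxa(self) -> frozenset[str]:
        return self.producers | self.nonproducers

    def require_known(self, taxon: str) -> None:
        if taxon not in self.all_taxa:
            raise TaxonConfigError(f"unknown taxon label {taxon!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaxonConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            focal=d["focal"],
            producers=frozenset(d["producers"]),
            nonproducers=frozenset(d["nonproducers"]),
        )
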