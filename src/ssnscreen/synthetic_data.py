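"""Synthetic multi-taxon transcriptomes with planted family structure.

The generator emulates the study design the screen was built for: six
transcriptomes split into a producer lineage (a focal taxon plus two
relatives) and three non-producers. Protein families are planted in three
flavours:

* shared families — an ancestral protein drawn i.i.d. from BLOSUM62
  background frequencies, present in every taxon, each copy mutated
  independently at ``sub_rate_shared`` per site;
* lineage-specific (NSC) families — present only in producer taxa. Each
  descends from one shared family's ancestor via heavy divergence
  (``nsc_parent_divergence``), so at low network thresholds the planted
  family clusters with its parent (which reaches into non-producers) and
  detaches only part-way up the sweep — giving a non-trivial emergence
  threshold, exactly the behaviour the positive-control logic validates;
* focal-private genes — independent sequences in the focal taxon only.

Proteins are reverse-translated with uniform synonymous codons, wrapped in
UTRs and an ATG...stop structure, and re-checked against the ORF rule so
that every emitted transcript yields back exactly its planted protein.
Annotations carry reductase/dehydrogenase keywords for family genes plus
near-miss decoys (e.g. 'reduced', 'dehydration') that deliberately exercise
substring-matching semantics. Expression profiles make planted pathway
genes (the focal members of NSC families) co-vary with the bait/control
gene at a configured target correlation.

The generation-time separation check measures, for every planted NSC
family, the minimum within-family and maximum cross-family bit score over
all emitted proteins and requires a sweep threshold to fit strictly between
them; recovery of every planted family as one NSC cluster is then forced by
construction, and the measured interval is recorded in SimTruth so tests
can assert the control's emergence threshold falls inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .coexpression import ExpressionMatrix
from .config import TaxonConfig
from .pairalign import AlignParams, bit_score, raw_score
from .seqio_orf import OrfRule, Transcript, extract_orfs, write_fasta

# BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff)
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_AA = tuple(BLOSUM62_BACKGROUND)
_BG = np.array([BLOSUM62_BACKGROUND[a] for a in _AA])
_BG = _BG / _BG.sum()

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"), "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"), "M": ("ATG",), "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "W": ("TGG",),
    "Y": ("TAT", "TAC"), "V": ("GTT", "GTC", "GTA", "GTG"),
}
_STOPS = ("TAA", "TAG", "TGA")

TISSUES = ("young_leaf", "mature_leaf", "stem", "root")

# keyworded descriptions cycled over family genes (reductase screen scope)
_FAMILY_DESCRIPTIONS = (
    "putative isoflavone reductase",
    "alcohol dehydrogenase 2",
    "cinnamoyl-CoA reductase 1",
    "short-chain dehydrogenase/reductase",
    "aldo-keto reductase family protein",
)
_NSC_DESCRIPTIONS = (
    "isoflavone reductase-like protein",
    "NADPH-dependent codeinone reductase",
    "zinc-binding dehydrogenase family protein",
)
# near-miss decoys: share word stems with keywords but contain none of them
_DECOY_DESCRIPTIONS = (
    "reduced seed dormancy 5 protein",
    "dehydration-responsive element-binding protein",
    "ATP synthase subunit beta",
    "ribosomal protein L12",
)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic screen."""

    seed: int = 0
    taxa: TaxonConfig = field(default_factory=TaxonConfig)
    n_shared_families: int = 5
    n_nsc_families: int = 3
    n_focal_private: int = 4
    family_size: int = 1  # genes per taxon per family
    ancestral_len: int = 350
    sub_rate_shared: float = 0.08
    sub_rate_nsc_within: float = 0.08
    nsc_parent_divergence: float = 0.65
    utr_len: int = 50
    orf_min_len: int = 100
    replicates: int = 3
    expr_r_target: float = 0.95
    expr_noise_floor: float = 1.0
    floor: float = 50.0
    sweep_start: float = 50.0
    sweep_step: float = 5.0
    sweep_stop: float = 200.0
    check_separation: bool = True

    def __post_init__(self) -> None:
        for r in (self.sub_rate_shared, self.sub_rate_nsc_within, self.nsc_parent_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError("substitution rates must lie in [0, 1]")
        if self.n_nsc_families > self.n_shared_families:
            raise ValueError("each planted NSC family needs a distinct parent shared family")
        if not 0.0 < self.expr_r_target <= 1.0:
            raise ValueError("expr_r_target must lie in (0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Complete bookkeeping of what was planted."""

    family_of: Mapping[str, str]  # transcript id -> family name
    nsc_families: tuple[str, ...]
    nsc_members: Mapping[str, tuple[str, ...]]  # family -> transcript ids
    pathway_transcripts: tuple[str, ...]  # focal NSC members (coexpressed)
    control_transcript: str | None  # the positive-control analog
    bait_transcript: str | None  # coexpression bait (== control here)
    forced_interval: Mapping[str, tuple[float, float]]  # family -> (max_cross, min_within) bits
    target_r: Mapping[str, float]  # pathway transcript -> configured bait correlation

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_of": dict(self.family_of),
            "nsc_families": list(self.nsc_families),
            "nsc_members": {k: list(v) for k, v in self.nsc_members.items()},
            "pathway_transcripts": list(self.pathway_transcripts),
            "control_transcript": self.control_transcript,
            "bait_transcript": self.bait_transcript,
            "forced_interval": {k: list(v) for k, v in self.forced_interval.items()},
            "target_r": dict(self.target_r),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimResult:
    transcripts: dict[str, list[Transcript]]  # taxon -> transcripts
    annotation: AnnotationTable  # focal taxon only
    expression: ExpressionMatrix  # focal transcripts x samples
    truth: SimTruth
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for taxon in sorted(self.transcripts):
            write_fasta(self.transcripts[taxon], out / f"{taxon}.transcripts.fasta")
        self.annotation.to_tsv(out / "annotation.tsv")
        self.expression.to_tsv(out / "expression.tsv")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# Worked micro example: a 12-gene, 4-taxon fixture small enough that every
# pipeline output (ORFs, edges, partitions, labels, ranks, correlations) can
# be checked exactly. Sequence blocks are frozen literals; the network
# structure they induce under default alignment parameters:
#   * a shared family (K_sh, U_sh, C1_sh, C2_sh) with within-family edges
#     ~168-178 bits, reaching into both non-producers;
#   * a lineage-specific pair (K_nsc, U_nsc; 169.9 bits) attached to the
#     shared family by ~52-60-bit links — merged at threshold 50, a clean
#     NSC at 100;
#   * a focal-only pair (K_fs1, K_fs2; 145.2 bits) that splits by 150;
#   * four unrelated singletons (background <20 bits).

_M_CORE1 = "PITFRVPSNIGYKSICLASKPGVWSDIANMPVEGIDNICMHTFETSGEMNDASMFSILNR"
_M_CORE2 = "MILPKLLEAHDGTCAQEKLSMGSNARFININFIGEKGRRVYFQVSFIQRYIDELDTPFHK"
_M_LINK = "LKRHAIENRLNYLGLAVISRIIVLIQELIA"
_M_CORE3 = "SYNLRMQKFPRYCALGSSEVELQVNAHVWPWWLEPKGRPQVCRTNDLTDESVINACNMRLFLDSFPNRVG"
_M_JUNK = {
    "K_orph": "EIKVEYALKRNHVLVSISARSSCLKTLHGHKTICCPSRALNSENYNENRAADALMGEITT",
    "U_orph": "ADCCLHAGLRTAYRTYVSSKSNLLTIGKQNIHCGGEGMEVYIELTKSLKEFDFTNKRFRV",
    "C1_orph": "NVSLSSVQLRKDLLILPSILVRRRKHSMEYPQGENNVHGFLVSIGVFVRTKRLMAISEII",
    "C2_orph": "EYSRVTQTRVMKRYACNSDYKAAAKSCTASVPFTADRIPKTNFDQFVKAKAWFDRDVISK",
}


def _subst(s: str, positions: Sequence[int]) -> str:
    """Replace each listed position with the alphabetically first other residue."""
    out = list(s)
    for p in positions:
        for a in _AA:
            if a != out[p]:
                out[p] = a
                break
    return "".join(out)


@dataclass
class MicroExample:
    taxa: TaxonConfig
    rule: OrfRule
    proteins: dict[str, str]  # gene -> protein sequence
    transcripts: dict[str, list[Transcript]]  # taxon -> transcripts (id == gene)
    annotation: AnnotationTable
    expression: ExpressionMatrix
    thresholds: tuple[float, float, float]
    control: str
    bait: str


def make_worked_micro_example() -> MicroExample:
    """The 12-gene, 4-taxon fixture (deterministic, no configuration)."""
    taxa = TaxonConfig(
        focal="K", producers=frozenset({"K", "U"}), nonproducers=frozenset({"C1", "C2"})
    )
    proteins = {
        "K_sh": "M" + _M_CORE1 + _M_LINK,
        "U_sh": "M" + _subst(_M_CORE1, [5, 20, 40]) + _M_LINK,
        "C1_sh": "M" + _subst(_M_CORE1, [10, 30]) + _M_LINK,
        "C2_sh": "M" + _subst(_M_CORE1, [15]) + _subst(_M_LINK, [7]),
        "K_nsc": "M" + _M_CORE2 + _M_LINK,
        "U_nsc": "M" + _subst(_M_CORE2, [3, 25, 50]) + _subst(_M_LINK, [4, 19]),
        "K_fs1": "M" + _M_CORE3,
        "K_fs2": "M" + _subst(_M_CORE3, [10, 24, 33, 47, 61]),
        "K_orph": "M" + _M_JUNK["K_orph"],
        "U_orph": "M" + _M_JUNK["U_orph"],
        "C1_orph": "M" + _M_JUNK["C1_orph"],
        "C2_orph": "M" + _M_JUNK["C2_orph"],
    }
    rule = OrfRule(min_len=50)
    cfg = SimConfig(seed=7, utr_len=30, orf_min_len=50)
    rng = np.random.default_rng(cfg.seed)
    transcripts: dict[str, list[Transcript]] = {t: [] for t in sorted(taxa.all_taxa)}
    for gene in proteins:
        taxon = gene.split("_")[0]
        transcripts[taxon].append(_embed(rng, gene, taxon, proteins[gene], cfg))
    annotation = AnnotationTable.from_records(
        [
            ("K_sh", "alcohol dehydrogenase 2"),
            ("K_nsc", "putative isoflavone reductase"),
            ("K_fs1", "isoflavone reductase-like protein"),
            ("K_fs2", "NADPH-dependent reductase"),
            ("K_orph", "aldo-keto reductase family protein"),
        ]
    )
    expression = ExpressionMatrix(
        pd.DataFrame(
            {
                "young_leaf": [5.0, 10.0, 20.0, 0.0, 1.0],
                "mature_leaf": [5.0, 2.0, 4.0, 8.0, 9.0],
                "stem": [5.0, 4.0, 8.0, 6.0, 3.0],
                "root": [5.0, 0.0, 0.0, 10.0, 7.0],
            },
            index=["K_sh", "K_nsc", "K_fs1", "K_fs2", "K_orph"],
        )
    )
    return MicroExample(
        taxa=taxa,
        rule=rule,
        proteins=proteins,
        transcripts=transcripts,
        annotation=annotation,
        expression=expression,
        thresholds=(50.0, 100.0, 150.0),
        control="K_nsc",
        bait="K_nsc",
    )


def _draw_protein(rng: np.random.Generator, length: int) -> str:
    aa = rng.choice(len(_AA), size=length, p=_BG)
    prot = "M" + "".join(_AA[i] for i in aa[1:])
    return prot


def _mutate(rng: np.random.Generator, prot: str, rate: float) -> str:
    """Per-site substitution; position 0 (the start M) is preserved."""
    out = [prot[0]]
    for c in prot[1:]:
        if rng.random() < rate:
            while True:
                n = _AA[rng.choice(len(_AA), p=_BG)]
                if n != c:
                    break
            out.append(n)
        else:
            out.append(c)
    return "".join(out)


def _random_utr(rng: np.random.Generator, length: int, forbid_atg: bool) -> str:
    for _ in range(200):
        utr = "".join(rng.choice(("A", "C", "G", "T"), size=length))
        if not forbid_atg or "ATG" not in utr:
            return utr
    raise GenerationError("could not draw an ATG-free UTR")


def _reverse_translate(rng: np.random.Generator, prot: str) -> str:
    codons = [_CODONS[c][rng.integers(len(_CODONS[c]))] for c in prot]
    return "".join(codons)


def _embed(
    rng: np.random.Generator, tid: str, taxon: str, prot: str, cfg: SimConfig
) -> Transcript:
    """Wrap a protein into a transcript that decodes back to exactly it."""
    rule = OrfRule(min_len=cfg.orf_min_len)
    for _ in range(100):
        seq = (
            _random_utr(rng, cfg.utr_len, forbid_atg=True)
            + _reverse_translate(rng, prot)
            + _STOPS[rng.integers(len(_STOPS))]
            + _random_utr(rng, cfg.utr_len, forbid_atg=False)
        )
        t = Transcript(id=tid, taxon=taxon, seq=seq)
        orfs = extract_orfs(t, rule)
        if len(orfs) == 1 and orfs[0].seq == prot:
            return t
    raise GenerationError(f"could not embed {tid} without spurious ORFs")


def _separation_check(
    proteins: Mapping[str, tuple[str, str]],  # tid -> (family, protein seq)
    nsc_members: Mapping[str, tuple[str, ...]],
    cfg: SimConfig,
) -> dict[str, tuple[float, float]]:
    """Measured (max cross-family, min within-family) bit scores per NSC family."""
    params = AlignParams()
    intervals: dict[str, tuple[float, float]] = {}
    schedule = np.arange(cfg.sweep_start, cfg.sweep_stop + 1e-9, cfg.sweep_step)
    for fam, members in nsc_members.items():
        within = []
        cross = []
        for i, a in enumerate(members):
            seq_a = proteins[a][1]
            for b in members[i + 1 :]:
                within.append(bit_score(raw_score(seq_a, proteins[b][1], AlignParams())))
            for tid, (other_fam, seq_b) in proteins.items():
                if other_fam != fam:
                    cross.append(bit_score(raw_score(seq_a, seq_b, params)))
        min_within = float(min(within))
        max_cross = float(max(cross))
        intervals[fam] = (max_cross, min_within)
        if cfg.check_separation:
            fits = [t for t in schedule if max_cross < t <= min_within]
            if not fits:
                raise GenerationError(
                    f"planted family {fam}: no sweep threshold separates "
                    f"max cross-family score {max_cross:.1f} from min within-family "
                    f"score {min_within:.1f}; lower nsc_parent_divergence or widen the schedule"
                )
    return intervals


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Generate transcriptomes, annotations, expression and ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxa
    producers = sorted(taxa.producers)
    all_taxa = sorted(taxa.all_taxa)
    focal = taxa.focal

    family_of: dict[str, str] = {}
    proteins: dict[str, tuple[str, str]] = {}  # tid -> (family, protein)
    per_taxon_prots: dict[str, list[tuple[str, str]]] = {t: [] for t in all_taxa}
    descriptions: list[tuple[str, str]] = []

    def add_gene(tid: str, taxon: str, family: str, prot: str) -> None:
        family_of[tid] = family
        proteins[tid] = (family, prot)
        per_taxon_prots[taxon].append((tid, prot))

    # shared families: ancestral protein in every taxon
    shared_ancestors: list[str] = []
    for f in range(cfg.n_shared_families):
        fam = f"shared{f}"
        anc = _draw_protein(rng, cfg.ancestral_len)
        shared_ancestors.append(anc)
        for taxon in all_taxa:
            for k in range(cfg.family_size):
                tid = f"{taxon}_{fam}_{k}"
                add_gene(tid, taxon, fam, _mutate(rng, anc, cfg.sub_rate_shared))
                if taxon == focal:
                    descriptions.append(
                        (tid, _FAMILY_DESCRIPTIONS[f % len(_FAMILY_DESCRIPTIONS)])
                    )

    # planted NSC families: producer lineage only, diverged from a shared parent
    nsc_members: dict[str, tuple[str, ...]] = {}
    for f in range(cfg.n_nsc_families):
        fam = f"nsc{f}"
        anc = _mutate(rng, shared_ancestors[f], cfg.nsc_parent_divergence)
        members = []
        for taxon in producers:
            for k in range(cfg.family_size):
                tid = f"{taxon}_{fam}_{k}"
                add_gene(tid, taxon, fam, _mutate(rng, anc, cfg.sub_rate_nsc_within))
                members.append(tid)
                if taxon == focal:
                    descriptions.append(
                        (tid, _NSC_DESCRIPTIONS[f % len(_NSC_DESCRIPTIONS)])
                    )
        nsc_members[fam] = tuple(members)

    # focal-private genes: half keyword-matched baits, half near-miss decoys
    for f in range(cfg.n_focal_private):
        fam = f"private{f}"
        tid = f"{focal}_{fam}_0"
        add_gene(tid, focal, fam, _draw_protein(rng, cfg.ancestral_len))
        if f % 2 == 0:
            descriptions.append((tid, _FAMILY_DESCRIPTIONS[(f // 2) % len(_FAMILY_DESCRIPTIONS)]))
        else:
            descriptions.append((tid, _DECOY_DESCRIPTIONS[f % len(_DECOY_DESCRIPTIONS)]))

    # foreign private decoys give homolog retrieval a non-family pool
    for taxon in all_taxa:
        if taxon == focal:
            continue
        for f in range(2):
            fam = f"{taxon}_private{f}"
            tid = f"{taxon}_{fam}_0"
            add_gene(tid, taxon, fam, _draw_protein(rng, cfg.ancestral_len))

    forced = _separation_check(proteins, nsc_members, cfg)

    # embed every protein into a transcript
    transcripts: dict[str, list[Transcript]] = {}
    for taxon in all_taxa:
        transcripts[taxon] = [
            _embed(rng, tid, taxon, prot, cfg)
            for tid, prot in sorted(per_taxon_prots[taxon])
        ]

    annotation = AnnotationTable.from_records(sorted(descriptions))

    # expression: focal transcripts x (tissue x replicate), FPKM-like
    pathway = tuple(
        tid for fam in sorted(nsc_members) for tid in nsc_members[fam]
        if tid.startswith(focal + "_")
    )
    control = pathway[0] if pathway else None
    samples = [f"{t}_r{r+1}" for t in TISSUES for r in range(cfg.replicates)]
    tissue_means_bait = np.array([120.0, 30.0, 60.0, 10.0])
    bait_profile = np.repeat(tissue_means_bait, cfg.replicates) + rng.normal(
        0.0, 2.0, size=len(samples)
    )
    bait_profile = np.clip(bait_profile, 0.0, None)
    sig_sd = float(bait_profile.std(ddof=1))
    noise_sd = max(
        sig_sd * np.sqrt(1.0 / cfg.expr_r_target**2 - 1.0), cfg.expr_noise_floor
    )
    rows: dict[str, np.ndarray] = {}
    target_r: dict[str, float] = {}
    focal_tids = sorted(tid for tid, _ in per_taxon_prots[focal])
    for tid in focal_tids:
        if tid == control:
            rows[tid] = bait_profile
        elif tid in pathway:
            scale = float(rng.uniform(0.5, 2.0))
            prof = scale * bait_profile + rng.normal(0.0, noise_sd * scale, len(samples))
            rows[tid] = np.clip(prof, 0.0, None)
            target_r[tid] = cfg.expr_r_target
        else:
            means = rng.uniform(0.0, 100.0, size=len(TISSUES))
            prof = np.repeat(means, cfg.replicates) + rng.normal(0.0, 5.0, len(samples))
            rows[tid] = np.clip(prof, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([rows[t] for t in focal_tids]), index=focal_tids, columns=samples
        )
    )

    truth = SimTruth(
        family_of=family_of,
        nsc_families=tuple(sorted(nsc_members)),
        nsc_members=nsc_members,
        pathway_transcripts=pathway,
        control_transcript=control,
        bait_transcript=control,
        forced_interval=forced,
        target_r=target_r,
    )
    return SimResult(
        transcripts=transcripts,
        annotation=annotation,
        expression=expr,
        truth=truth,
        config=cfg,
    )
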