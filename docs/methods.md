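# Methods

## Screening model

The pipeline operationalizes a phylogenetic presence/absence argument: a
gene family responsible for a lineage-restricted metabolite should be
conserved within the producing lineage and absent (or strongly diverged)
outside it. Concretely, for a focal producer species and a set of producer
and non-producer relatives:

- the focal candidate space is restricted by functional annotation keywords
  (an enzyme-class prior, not a homology requirement);
- each foreign transcriptome contributes only the *closest* homolog of each
  bait, so the network stays small and every bait is represented in every
  taxon that has anything resembling it;
- the sequence similarity network is thresholded upward until components
  free of non-producer genes appear. Because components can only split as
  the threshold rises, "no non-producer member" is a monotone property and
  each gene's emergence threshold is well defined;
- a known pathway gene acts as positive control: it must emerge in a
  lineage-specific cluster at some threshold, otherwise the sweep (or the
  scoring convention) is suspect.

## Sequence handling

**ORF rule.** Every ORF starting at an ATG and translating to at least
`min_len` residues (default 100, counting the initial Met, excluding the
stop) is reported. Within one reading frame and stop codon, only the
5'-most ATG is reported (longest-per-stop); alternative downstream starts
would flood the network with near-duplicate nodes. ORFs running off the 3'
end are kept by default because assembled transcripts are frequently
3'-incomplete; `require_stop` disables this. Assemblies are treated as
oriented; `scan_reverse_strand` adds the minus strand. Codons containing N
translate to X and never terminate an ORF.

**Alignment.** `Bio.Align.PairwiseAligner` with BLOSUM62 and affine gaps,
open 11 / extend 1 in the NCBI convention (a gap of length *k* costs
11 + *k*). Local mode drives homolog retrieval and network edges; global
mode drives percent-identity reporting (identical columns over all
alignment columns, rounded to integer percent). The X row/column of the
matrix is zeroed so unknown residues are neutral. Scores and identities are
symmetric by construction (the pair is canonicalized before traceback).
Ties in best-homolog retrieval break to the lexicographically smallest id.

**Edge score units.** Network thresholds are bit scores obtained from raw
scores by the Karlin–Altschul transform, bits = (λS − ln K)/ln 2 with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041. This reproduces
the magnitude regime of the alignment-score thresholds used by SSN tools
(floors near 50, emergence between roughly 100 and 170) without claiming to
replicate any particular web service bit-for-bit; raw scores remain
available via `AlignParams`.

## Network and sweep

Nodes are deduplicated exactly (one representative per identical
taxon+sequence, multiplicity recorded) before the O(n²) all-vs-all pass;
edges below the floor (default 50 bits) are never stored, so sweeping below
the floor is an error rather than silently wrong. Components are
`networkx` connected components; partitions are reported in deterministic
order (clusters sorted by smallest member id). Classification is a pure
function of taxon composition:

| label | condition |
|---|---|
| shared | ≥ 1 member from a non-producer taxon |
| focal_specific | every member from the focal taxon |
| NSC | no non-producer member, ≥ 1 non-focal producer member |

Singletons at a given threshold are "unclustered". The stricter NSC
reading (a non-focal producer must be present) is used because focal-only
clusters are reported separately as candidates in their own right.

The default sweep schedule is start 50, step 5, stop 200 — spanning the
threshold regime where lineage-specific clusters emerge under these score
units, with the increment at which emergence thresholds are convention-
ally quoted.

## Candidate ranking

Candidates at a chosen threshold are focal genes in NSC clusters, focal
genes in focal-specific clusters, and unclustered focal genes. They are
ordered by label priority (NSC > focal_specific > unclustered), then by
Pearson r against the bait profile descending (undefined r last), then id.
This fusion rule is a convention of this package — the original screening
style treats cluster membership and coexpression as parallel evidence
streams — and is labelled as such. When no threshold is given, the
pipeline reports at the sweep threshold with the largest number of
NSC-resident focal genes (smallest on ties): the analogue of raising the
cutoff until the lineage-specific candidates have emerged. Pearson r is
the plain sample coefficient over all samples (replicates as samples, no
log transform by default; both alternatives are flags). Zero-variance
profiles yield r = None, never NaN.

## Synthetic data generator

The generator emulates the six-transcriptome study design: one focal
producer, two further producers, three non-producers.

- **Shared families** (default 5): an ancestral protein drawn i.i.d. from
  BLOSUM62 background frequencies (length 350), copied into every taxon
  with independent per-site substitution at rate 0.08 — within-family
  identity ≈ 85%, a typical ortholog regime, giving within-family edges of
  several hundred bits.
- **Planted NSC families** (default 3): present only in producer taxa.
  Each descends from one shared family's ancestor at divergence 0.65, so
  its members connect to the parent family at roughly 60–130 bits: merged
  with a non-producer-containing cluster at the floor, detaching mid-sweep.
  This makes the emergence threshold non-trivial — exactly the behaviour
  the positive-control logic is meant to validate.
- **Focal-private genes** (default 4): independent sequences; half carry
  scope keywords (becoming unclustered candidates), half carry near-miss
  decoy annotations ("reduced…", "dehydration…") that deliberately probe
  substring-matching semantics.
- Substitutions draw replacement residues from the BLOSUM62 background
  (excluding the current residue); there are no indels by default, keeping
  within/cross identities analytically controllable.
- Proteins are reverse-translated with uniform synonymous codons, wrapped
  in an ATG-free 5' UTR, a random stop codon and a 3' UTR, and re-checked:
  a transcript is re-drawn until the ORF rule recovers exactly the planted
  protein, so generator and pipeline are consistent by construction.
- **Expression**: four tissues × 3 replicates of FPKM-like values. The
  bait/control gene peaks in young leaf; planted pathway genes are scaled
  copies of the bait profile plus Gaussian noise calibrated to a target
  correlation of 0.95; all other genes get independent profiles.

**Separation check.** At generation time the minimum within-family and
maximum cross-family bit scores of every planted NSC family are measured
over all emitted proteins. Generation fails unless some sweep threshold
lies strictly between them; when it passes, recovery of each planted family
as exactly one NSC cluster is forced, and the measured interval is stored
in `SimTruth` so tests can assert the control's emergence threshold falls
inside it rather than pinning an arbitrary number.

What the generator does *not* emulate: realistic phylogenetic branch
lengths, codon usage bias, indels and fragmented assemblies, paralog
turnover, or count-based expression noise. Passing tests therefore
demonstrate the correctness of the screening computation under controlled
separation, not the sensitivity of the screen on real transcriptomes,
where within/cross score distributions overlap and keyword annotation is
noisy.

## Numerical and determinism choices

- All randomness flows from a single `numpy` generator seeded by
  `SimConfig.seed`; fixed seed ⇒ byte-identical outputs (asserted).
- Iteration is in sorted-id order everywhere; TSV floats are written with
  fixed formats, so every CLI stage re-runs byte-identically.
- The worked micro example (12 genes, 4 taxa) uses frozen literal sequence
  blocks; its 16 edge scores, partitions at thresholds 50/100/150, control
  emergence (100) and Pearson table are asserted exactly against hand or
  independent-oracle computation.
- Problem sizes in tests and the acceptance script (53 transcripts, 43
  network nodes, ~500-pair oracle cross-checks) were chosen so a full run
  completes in seconds while still exercising every stage at non-trivial
  scale.

## Known limitations

- The scoring convention (BLOSUM62, 11/1, Karlin–Altschul constants) is a
  documented choice, not a replication of any specific service; reported
  identity percentages can shift by a point or two under other conventions.
- Best-homolog retrieval is exact all-vs-all (no heuristic seeding); it is
  quadratic and intended for bait-scoped candidate sets, not whole
  proteome-vs-proteome search.
- Keyword scoping inherits the annotation table's quality; substring
  matching is deliberately permissive (screen-then-assay logic).
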