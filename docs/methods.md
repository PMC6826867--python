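# Methods

## Signature model

A conserved signature indel (CSI) is modelled as a maximal block of
alignment columns whose gap pattern bipartitions the rows: one set of
rows carries residues across the whole block while the complementary set
carries gaps. The residue-bearing rows are called *bearers*; whether the
bearer state is derived (an insertion) or ancestral (a deletion) is
decided separately by outgroup polarization. A candidate becomes a
signature record only if it passes three independent criteria:

1. **Uniform length.** Every bearer shares the identical block length.
   Blocks with ragged boundaries — an adjacent column where a nested
   subset or superset of the same rows is gapped, i.e. bearers of
   unequal indel lengths — are reported as one non-uniform candidate and
   rejected, rather than split into shorter artifacts.
2. **Flank conservation.** On each side of the block, the nearest
   `window` columns that are non-gap in a majority of rows are examined
   (moving outward); a column is *conserved* when the modal
   non-ambiguous residue is shared by at least `conservation_fraction`
   of its non-gap rows and fewer than half of the rows are gapped. At
   least `min_conserved` conserved columns are required per side.
3. **Taxonomic specificity.** The clade tested is the smallest named
   clade (in a user-supplied taxonomy) containing every bearer species.
   The call succeeds iff no species outside that clade carries the
   indel and the number of in-clade absences, beyond an optional named
   allowlist, is at most `tolerance`.

Candidates closer than `max_edge_distance` columns to either alignment
terminus are excluded as terminal-extension artifacts. Rows that are
entirely gap across the block and its flanking window are treated as
missing data: excluded from both bearer and non-bearer sets and listed
on the record. Single-sequence candidates (bearer set of size 1 or
n−1) are retained but flagged; in practice the zero-tolerance
specificity rule eliminates them whenever their genus contains other
sampled species.

### Defaults and why

| parameter | default | range | rationale |
|---|---|---|---|
| `window` | 45 columns/side | 40–50 | midpoint of the conventional 40–50-residue neighbourhood; per-side asymmetry is not supported for lack of any use case |
| `min_conserved` | 4 | ≥ 1 | the weaker bound of the conventional "four to five" rule; 5 reachable by configuration |
| `conservation_fraction` | 0.8 | (0, 1] | strict enough to reproduce figure-style conserved flank blocks, loose enough to tolerate one divergent row in a ~15-row alignment; ambiguity codes X/B/Z never count as matches |
| `max_edge_distance` | 20 columns | ≥ 0 | all credible published signatures are internal |
| `tolerance` | 0 | ≥ 0 | "uniquely shared" taken literally; documented exceptions (e.g. one deep-branching species lacking a class-level signature) are representable either with tolerance 1 or a named allowlist |
| hit filter `e_max` | 1e-20 | — | the standard high-scoring-homolog threshold for this kind of screen |
| screen depth `top_n` | 250 (hard cap 500) | — | the conventional screening depth range; the lower bound is the default, the upper bound is enforced as a ceiling |
| scoring | BLOSUM62, gap open 11 / extend 1 | — | protein BLAST defaults; a gap of length *k* costs 11 + *k* |
| `slack` | 3 columns | — | alignment wobble absorbed when locating the indel in a screened hit; conserved flanks anchor the window, so larger drift indicates a real mismatch |
| flank identity floor | 30% | — | below this the hit's flanks are not credibly homologous and the call is ambiguous |

Flank conservation is counted over **alignment columns**, not reference
residues: when outgroup rows carry unrelated gaps, majority-gap columns
are skipped rather than charged against the window, which keeps the rule
stable under outgroup sampling. The "indel position" range reported on
records is the extracted signature window (indel ± `flank_residues`,
default 45) in ungapped coordinates of the reference row (the first
bearer by default).

## Polarization and deletions

Insertion versus deletion is decided purely from outgroup character
states: if every scorable outgroup row lacks residues in the block the
bearer state is derived (insertion); if every outgroup carries residues,
the gap state is derived (deletion); disagreement or no scorable
outgroup yields *ambiguous* (the record then carries `ambiguous`
polarity rather than being discarded; no minimum outgroup count beyond
≥ 1 is enforced, and the support count is always reported). For
deletions the specificity call is evaluated for the gap-carrying lineage
set rather than the residue-carrying one.

## Paralogs

When within-species gene duplications are present (labelled via FASTA
headers, a sidecar table, or inferred by single-linkage clustering at
50% pairwise identity computed with the screening aligner), specificity
is evaluated per homolog group: rows of other groups are ignored, and
the record is flagged *paralog-restricted* when a bearer species has
rows in another group lacking the indel.

## The homolog screen

Each retained hit (E-value strictly below `e_max`, best `top_n` kept,
ties broken by id) is aligned to the ungapped signature window with a
hand-written three-state (Gotoh) semi-global dynamic program: the window
is aligned globally, end gaps on the hit are free — signature windows
are short fragments of long subjects. Tie-breaking is deterministic
(substitution preferred over gap, leftmost placement). The hit's state
at the indel block — residues across the full span, a contiguous gap of
exactly the signature length within `slack` columns, or anything else —
maps to `has_indel` / `lacks_indel` / `ambiguous` (inverted for
deletion-type signatures). A hit set is *uniquely shared* iff every
in-clade hit has the indel and no out-of-clade hit does. E-values are
read from the tabular input and never recomputed. In tests the aligner
is checked against exhaustive alignment enumeration on tiny pairs and
against an independently implemented aligner (Biopython's
`PairwiseAligner`) on longer ones; enumerating all semi-global affine
alignments at 12+12 residues is combinatorially infeasible, which is why
the longer cross-check uses the independent implementation instead.

## The simulator

`simulate_family` evolves a root sequence (uniform over the 20 amino
acids, default 400 residues) down a fixed tree whose branch lengths are
per-variable-site substitution probabilities. Defaults:

* **Taxonomy** — six *Caenorhabditis* species plus *Diploscapter pachys*
  (family Rhabditoidea), four further Chromadorea (including
  *Strongyloides ratti*), a three-species Enoplea clade, and four
  apicomplexan outgroups; every named clade has ≥ 2 species so that a
  coincidental single-lineage indel can never satisfy the
  zero-tolerance specificity rule.
* **Site classes** — a fraction (default 0.4) of root positions is
  frozen (invariant in every lineage); the planted signature's flanks
  (`flank_freeze_width`, default 10 residues per side) and the planted
  block itself are always frozen, which is what gives a planted
  signature the conserved flanks the detection rule requires.
* **Planted signature** — inserted or deleted on the stem branch of the
  target clade; planting inside another signature's frozen zone or
  within 20 residues of a terminus is a specification error.
* **Background indels** — Poisson (default mean 0.3 events per terminal
  branch, lengths 1–5, insertions and deletions equally likely), placed
  on terminal branches only and never inside frozen zones.
  Single-lineage placement reflects the dominant pattern among real
  non-signature indels and keeps the planted signature's gap pattern
  clean; clade-internal background indels are a modelled-away
  complication (see limitations).
* **Paralogs** — optionally, each species of a clade gains a second
  homolog group that branches off at the clade stem *before* the
  signature event and evolves with extra divergence.

The true, gap-annotated alignment is emitted by construction, so
pipeline tests do not depend on any external MSA tool; generation is a
pure function of the seed (same seed, byte-identical output) and a
self-check verifies the emitted truth against the emitted sequences.
`generate_hit_set` mutates the signature window outside its frozen
flanks to synthesize screened hit sets with truth labels and E-values
monotone in realized divergence; `make_benchmark_suite` assembles
independent families with a stated planted fraction and a truth
manifest, optionally cycling an explicit list of target clades (used to
reproduce a per-level census).

**What passing closed-loop tests shows — and does not.** The benchmark
demonstrates that the implementation is faithful to the signature
definition: everything planted under that definition is recovered
exactly, and nothing else is called. It does not demonstrate robustness
to the hazards of real data that the generator deliberately omits:
alignment errors (the true alignment is used), non-uniform substitution
processes, rate heterogeneity beyond frozen/variable, homoplasious
indels arising independently in unrelated lineages, incomplete or
mis-annotated proteomes, and clade-internal background indels.

## Supermatrix utility

Family selection counts a genome only when it contributes exactly one
member (duplicated genomes are disqualified *before* the coverage test —
the stricter of the two possible readings of the 80% rule); families
present in at least ⌈0.8 × roster⌉ genomes are concatenated with gap
padding for absent genomes, and columns whose gap fraction exceeds 0.5
are trimmed (a deliberately simple, documented stand-in for heuristic
alignment trimmers — it removes padding-dominated columns, not
poorly-aligned ones). Output is relaxed PHYLIP/FASTA plus a
RAxML-style partition file remapped to post-trim coordinates; tree
inference itself is delegated to external tools.

## Numerical and format choices

* Coordinates are 1-based inclusive everywhere; printed ranges use an
  ASCII hyphen.
* Gap character `-` canonical; `.` normalized on input. Species names
  are carried in FASTA/Clustal headers as `id|species|group` with
  underscores for spaces (Clustal ids cannot contain whitespace); a
  sidecar TSV overrides header-derived labels.
* The Clustal writer is hand-rolled because the library writer truncates
  identifiers at 30 characters, which would break the header convention
  on re-read.
* All-gap columns are removed at load time with a logged notice;
  normalization is idempotent.
* The dash-identity renderer prints gaps as blanks, distinct from
  identity dashes, and boxes the signature columns with `[` `]`; a
  decoder inverts the rendering exactly, which is asserted
  property-style in tests. The per-signature bundle format (YAML front
  matter + alignment block + screen summary, versioned
  `csiscan-signature/1`) is this package's own; it is not a faithful
  reproduction of any historical signature-file format.
* DP traceback uses a 1e-9 score tolerance when re-deriving the optimal
  path; scores themselves are exact sums of integer matrix entries.

## Problem sizes

The shipped analyses and the acceptance script run at desk scale by
choice: 100-family benchmarks at ~18 rows × ~400 residues, 500
random alignments for the scanner oracle, 300 random pairs for the
aligner cross-check, 52 families for the census demonstration. All
complete in seconds on one CPU; the same code paths scale linearly in
alignment width and quadratically in sequence length only inside the
pairwise aligner.

## Known limitations

* The substitution model is uniform replacement at variable sites — no
  empirical rate matrix, no among-site rate variation, no coalescent
  within-species variation. The pipeline under test is pattern-based,
  so model realism buys nothing for correctness testing, but simulated
  divergence percentages should not be read as evolutionary distances.
* Nucleotide-level signatures, statistical significance of indel
  placement, MSA construction and tree inference are out of scope.
* The specificity call is LCA-based: a candidate whose bearers span two
  unrelated clades is reported against their joint ancestor (and
  normally fails on exceptions) rather than as two independent calls.
* With no outgroup in an alignment, polarity is `ambiguous` and records
  carry it as such; downstream consumers that require strict
  insertion/deletion typing must supply outgroups.
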