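# Methods

This note documents the models behind each hsfkit stage, the parameters
that matter, the synthetic-data generator's scope, and the numerical
choices made where the design was genuinely open.

## Profile screen

The candidate screen replaces a profile-HMM + BLASTP step with an ungapped
position-specific scoring model.  From a seed alignment of reference Hsf
domain rows, columns whose gap fraction reaches 0.5 are dropped and each
remaining column emits residue *a* with probability

    e_j(a) = (c_j(a) + w · b(a)) / (n_j + w)

where `c_j` are observed counts, `n_j` the non-gap count, `b` the
background (uniform 1/20 by default, overridable with proteome
frequencies) and `w` the pseudocount weight (default 1).  A window of a
target scores `Σ_j log2(e_j(x_{i+j}) / b(x_{i+j}))` bits; unknown residues
(X) contribute 0.

**Why no insert/delete states:** the screen is a high-recall filter in
front of explicit domain validation; the DBD region it targets is
strongly conserved and close to fixed-length, so gapless scoring loses
essentially nothing while keeping the stage exactly reproducible.

Significance is empirical.  Each target is residue-shuffled 1000 times
(seeded); all shuffled window scores form the null.  A window with score
*s* gets per-window tail probability `P = (1 + #{null ≥ s}) / (n_null + 1)`
and `E = P × W` with `W` the number of windows scanned across the
database.  With 1000 shuffles per target the floor is
`W / (1000·W + 1) < 10⁻³`, so a hit that beats every null clears the
default `E < 0.001` retention threshold.  Nulls are streamed and counted
against the sorted candidate scores, never stored.

## Domain annotation

- **DBD**: best-scoring profile window, accepted above a score floor of
  0.5 × the profile's maximum attainable bitscore (a shuffled-composition
  decoy scores far below half-maximum, a true domain with ≤ 12%
  substitutions stays well above).  Secondary-structure elements
  (α1-β1-β2-α2-α3-β3-β4) are called from per-column scores in the hit
  window: full when ≥ 80% of an element's columns score positively,
  partial when some do, absent when none do.  Both thresholds are
  parameters.
- **HR-A/HR-B**: a heptad (period abcdefg) passes when its a/d positions
  are hydrophobic (Φ = {L,I,V,F,M,A}; per-heptad a/d fraction ≥ 0.75,
  which with two positions means both).  Maximal same-phase chains of
  ≥ 2 heptads are collected C-terminal of the DBD; HR-A is the earliest
  run, HR-B the next non-overlapping run, and the insert is the residue
  count strictly between them.  A single contiguous run long enough for
  both (the insert-free class-B architecture) is split so HR-B takes the
  final two heptads.  Alanine is included in Φ and the 0.75 threshold is
  configurable because no published heptad-calling rule exists for this
  family; the values were fixed once from the canonical coiled-coil
  definition.
- **Classification**: insert bands B: 0–2, C: 3–13, A: ≥ 14 interpolate
  the canonical 0/7/21 inserts; the bands partition all nonnegative
  integers, so classification is total.  Inserts outside canonical ± 2
  are flagged (`in_band=False`), never rejected — real sequences drift.
- **Family filter**: candidates lacking either domain are excluded with a
  reason; among candidates whose gene models overlap on the same
  chromosome and strand the longest protein is kept, ties broken
  lexicographically by id (the survey's goal is a non-redundant,
  full-length set).

## Motif scanners and physico-chemistry

The scanners are transparent positional rules, not re-implementations of
the neural/matrix predictors used for the same purpose in survey papers;
family-wide NLS/NES counts therefore are not comparable figures, and the
test suite instead proves each scanner equivalent to an independent
regular-expression oracle.

- **AHA**: core FWxx[F/L]; the trailing hydrophobic (F/I/L within 3
  residues) is optional by default because several published class-A
  motifs lack it.  The reported match is the 5-residue core.
- **NLS**: monopartite — any 4-mer with ≥ 3 K/R, overlapping windows
  merged to maximal runs; bipartite — a 3-mer with ≥ 2 K/R, a 6–14
  residue spacer, then a 5-mer with ≥ 3 K/R (shortest spacer reported).
- **NES**: Φ-x(0,5)-Φ-x(0,4)-Φ-x(0,2)-Φ with Φ = {L,I,V,F,M}, greedy
  longest-spacer-first semantics (equal to a greedy regex).  The gap
  bounds admit both widely spaced and contiguous hydrophobic positions,
  as published wheat NES annotations contain both extremes.
- **ER / LFGV**: the C-terminal tetrapeptide is matched against an
  editable lexicon (shipped defaults taken from published wheat Hsf
  signals); LFGV is searched only in the C-terminal half, where the
  class-B repressor motif resides.
- **MW**: ExPASy-convention average residue masses + 18.0153 Da water;
  X residues are excluded with a warning.  **pI**: bisection on the
  Henderson–Hasselbalch net charge (EMBOSS pKa set: N-term 8.6, C-term
  3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5); the charge
  is strictly decreasing in pH, so bisection converges to |q| < 10⁻⁴.

## Phylogeny and subclass assignment

Trees are built on the N-proximal region (DBD through HR-B end).  Rather
than a de-novo multiple alignment, rows are stacked on domain anchors:
each of the five segments (DBD, linker, HR-A, insert, HR-B) is padded
with trailing gaps to its maximum length — deterministic, and appropriate
because the region is strongly conserved.  Distances are p-distances
under pairwise deletion (sites with a gap in either row skipped) with the
Poisson multiple-hit correction d = −ln(1 − p).  Neighbor joining uses
the standard Q-criterion with lowest-index tie-breaks; negative branch
estimates are clamped to 0 and flagged.  Bootstrap supports come from
column resampling with replacement (default 1000 replicates, seeded;
replicates that saturate a distance are redrawn), and are invariant to
taxon input order.

A query inherits the subclass of the best-identity reference inside its
smallest well-supported (bootstrap > 50) enclosing clade, provided that
identity reaches the threshold (default 90%, applied to the anchored
N-terminal region; configurable because full-length cross-species
identities above 90% are implausible).  When the best identity falls
short, the query's largest well-supported reference-free clade is deemed
novel and all of its queries share one new label: class letter + the next
unused index (so a reference-free class-C clade beside C1/C2 references
becomes C3).  Queries with no supported enclosing clade are unresolved.

## Genome context

- **Chromosome statistics** cover the 21 chromosomes (1A..7D) plus an
  unanchored bin (U, excluded from group totals).
- **Homeolog triads**: candidate triples take one gene per subgenome
  letter (A/B/D) within the same subclass; a triple is accepted when all
  three pairwise global identities (Needleman–Wunsch, matches / aligned
  columns) reach the threshold (default 0.90).  Genes join one group at
  most, resolved greedily by descending mean identity.  Group numbers are
  recorded only when the three chromosomes agree — ancient inter-group
  translocations (e.g. the wheat 4A/5A exchange) otherwise leave
  bona-fide triads spanning group numbers, which is why matching is by
  subgenome letter.  `count_complete_triads` gives the sequence-free
  tally from an annotation table (per subclass, min of the three
  subgenome counts — correct because any within-subclass A/B/D
  combination is admissible).
- **Gene structure**: exon/intron spans are derived by exact anchoring of
  the cDNA in the genomic sequence, preferring GT..AG-bounded gaps and
  shorter introns; this is a deliberate synthetic-data contract, not a
  full spliced aligner — mismatched real data raises an error rather
  than guessing.  The conserved-intron-in-DBD check projects the protein
  DBD span onto CDS coordinates (3 nt per residue, plus a 5' UTR offset)
  and asks whether any splice junction falls strictly inside.

## Expression profiling

TPM matrices are genes × (organ, treatment) with leaf/root organs and
control, H₂O₂, HS, ABA, SA, PEG treatments.  The heatmap transform is
log₂(TPM + 1).  Response calls compare each treatment with the
within-organ control: up when (t + ε)/(c + ε) ≥ 2 and t ≥ 1 TPM, down
when the ratio ≤ 1/2 and c ≥ 1 TPM, not_expressed when both sides sit
below 1 TPM, else insensitive (ε = 0.01).  The pseudocounts, fold
threshold and floor are configuration keys; the calls are descriptive
categories, deliberately not differential-expression tests.  qRT-PCR
folds use 2^(−ΔΔCt); the calibrator sample returns exactly 1.

## Synthetic-data generator

Each synthetic gene is N-tail + DBD consensus + linker + HR-A (3 heptads)
+ class insert (21/0/7 by default) + HR-B (2 heptads) + C-tail.  Tails,
linkers and inserts draw from a polar alphabet (S,T,N,Q,E,D,G,P,H) that
cannot seed spurious heptads, NES, NLS or AHA matches, so the planted
motifs are provably the only ones in the scanned C-terminal region.
Motif payloads follow class biology: AHA is planted only in class A, LFGV
only in class B (a contradictory plan is rejected), ER tetrapeptides in
designated subclasses.  Subclasses descend from seeded ancestors carrying
barcode substitutions (default rate 0.12 — between-subclass N-terminal
identity ≈ 78%, safely below the 90% assignment threshold); members add
per-sequence substitutions (default 0.02 — within-subclass identity
≈ 96%).  Substitutions respect position classes (polar stays polar,
heptad a/d anchors and planted motifs are protected) unless `hard_mode`
lifts protection.  Decoys are residue-shuffled member compositions.

Allohexaploid families triplicate each base gene onto nA/nB/nD
chromosomes, each copy mutated at (1 − identity)/2 so pairwise identity
≈ the target (default 0.97); leading groups can be emitted as singletons
or pairs to model post-polyploid gene loss.  Gene models reverse-translate
members, inserting one GT..AG intron between codons in the middle of the
DBD (length uniform on 80–5836 bp, the published wheat extremes);
designated subclasses (default C3) stay intronless.  Expression matrices
follow a class design — leaf: A up under H₂O₂/HS, B under H₂O₂/HS/ABA,
C under ABA; root: A under H₂O₂ only — with baseline 0.5 TPM ("hardly
detectable"), induced mean 40 TPM, root-specific genes at 8 TPM root
baseline and ~0 in leaf, and multiplicative log-normal noise (default
σ = 0.2, σ = 0 reproduces the design table exactly).

The DBD consensus, its element layout and the heptad templates are
synthetic constructions shipped as package data; only the element order
follows the published domain architecture.  All generators are
byte-deterministic under a fixed seed.

**What passing tests show — and don't.**  The generator emulates the
family's modular architecture, not real evolutionary sequence variation:
no indels inside domains, no compositional bias, no alternative splicing,
no partial-length proteins beyond the element-deletion constructs.  Exact
recovery on synthetic data therefore validates the pipeline's logic and
thresholds, not its recall on a real proteome, where profile-HMM searches
with insert states would be the stronger screen.

## Problem sizes

The shipped defaults keep every stage interactive: screens run 12 planted
genes against 100 decoys with 1000 shuffles per target (~10 s), NJ
recovery uses 100 random additive matrices of 4–10 taxa, bootstrap tests
use 25–100 replicates (the 1000-replicate default remains for analyses),
and the scanner/oracle suite covers 1000 random sequences up to 200
residues.

## Known limitations

- The screen is gapless; domains interrupted by insertions score poorly.
- NLS/NES rules are consensus approximations; their counts are not
  comparable with matrix/neural predictors.
- The ER-signal lexicon is curated data, not a learned rule.
- The spliced anchorer requires exact exon matches (by design).
- pI depends on the chosen pKa set; values differ between conventions by
  a few tenths of a unit.
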