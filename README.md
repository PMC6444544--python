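# hsfkit

Genome-wide identification, classification and expression profiling of plant
**heat shock transcription factor (Hsf)** families, built for allopolyploid
genomes such as bread wheat (*Triticum aestivum*, subgenomes A/B/D).

Plant Hsfs share a modular architecture: an N-terminal DNA-binding domain
(DBD, secondary-structure layout α1-β1-β2-α2-α3-β3-β4), an oligomerization
domain of two hydrophobic heptad repeats (HR-A and HR-B), and C-terminal
regulatory signals (NLS, NES, the class-A activator motif AHA, the class-B
repressor tetrapeptide LFGV, ER retention tetrapeptides).  The number of
residues inserted between HR-A and HR-B defines the three classes:

| class | canonical HR-A/HR-B insert |
|-------|----------------------------|
| A     | 21 residues                |
| B     | 0 residues                 |
| C     | 7 residues                 |

hsfkit implements the whole survey pipeline as a tested library:

- **`profile_search`** — position-specific scoring profile (log₂-odds PSSM)
  built from a seed alignment; proteome screening with empirical E-values
  calibrated on residue-shuffled targets (default threshold E < 0.001).
- **`domain_annotation`** — DBD localisation with per-element
  (α1…β4) presence calls, heptad-repeat detection of HR-A/HR-B
  (hydrophobic a/d positions, Φ = {L,I,V,F,M,A}), insert-band
  classification (B: 0–2, C: 3–13, A: ≥ 14), and the family retention
  filter (no DBD / no HR-A/B / overlapping gene models).
- **`motif_annotation`** — scanners for AHA (FWxx[F/L]), mono/bipartite
  NLS, leucine-rich NES, LFGV and C-terminal ER signals; average-mass MW
  and Henderson–Hasselbalch pI.
- **`phylogeny_classify`** — pairwise-deletion p-distances with Poisson
  correction d = −ln(1 − p), neighbor joining, column-bootstrap supports,
  and reference-anchored subclass assignment (clade bootstrap > 50,
  identity > 90%) including novel-subclass detection.
- **`genome_context`** — chromosome statistics over the seven homeologous
  groups, A/B/D homeolog-triad detection from pairwise identity, exon/intron
  derivation by spliced (GT..AG) anchoring of cDNA in genomic sequence, and
  the conserved-intron-in-DBD check.
- **`expression_analysis`** — TPM matrices over organ × treatment
  (leaf/root × control, H₂O₂, HS, ABA, SA, PEG), log₂ heatmap transform,
  fold-change response calls (up / down / insensitive / not_expressed) and
  the qRT-PCR 2^(−ΔΔCt) calculator.
- **`synthetic_data`** — a seedable generator of Hsf families,
  allohexaploid triads, gene models and expression matrices with complete
  truth tables, so every stage is testable without downloads.

The package bundles the published 82-gene wheat Hsf annotation table
(gene, chromosome, transcript, length, MW) as
`hsfkit/data/tahsf_family.tsv` for the genome-context statistics.

## Worked example

```python
from hsfkit import (FamilySpec, generate_family, run_pipeline,
                    load_family_table, chromosome_counts,
                    count_complete_triads, classify_by_insert)

# synthetic proteome: 8 planted Hsfs across four subclasses + 50 decoys
spec = FamilySpec(counts={"A1": 2, "A2": 2, "B1": 2, "C1": 2},
                  decoy_count=50, seed=1)
fam = generate_family(spec)
result = run_pipeline(fam.proteome, fam.seed_alignment, fam.seed_labels, seed=1)
print(f"screened {len(fam.proteome)} proteins -> retained {len(result.retained)}")
for cand in result.retained[:2]:
    c = cand.classification
    print(f"{cand.record.id}: insert={c.insert_length} class={c.hsf_class}")
```

prints

```
screened 58 proteins -> retained 8
SynHsfA1-1: insert=21 class=A
SynHsfA1-2: insert=21 class=A
```

— the screen kept exactly the 8 planted Hsfs (every decoy rejected at
E < 0.001), and the heptad caller measured the 21-residue class-A insert.
On the published wheat table:

```python
table = load_family_table()          # 82 genes
per_chrom, per_group, unanchored = chromosome_counts(table["chromosome"])
per_chrom["3B"], per_chrom["5A"]     # (8, 8)   densest chromosomes
per_group[5], per_group[3]           # (19, 18) densest homeologous groups
count_complete_triads(table)         # 21       complete A/B/D triads
```

A `hsfkit` console script exposes the same stages
(`simulate`, `run`, `tree`, `triads`, `expression`, `convert`).

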