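"""Seedable generator of synthetic Hsf families with full truth tables.

Every pipeline stage can be exercised without downloads: the generator
emits proteomes whose genes follow the modular Hsf architecture —
N-terminal tail, DNA-binding domain (DBD), linker, HR-A heptads,
class-specific insert (21 residues for class A, none for B, 7 for C),
HR-B heptads and a C-terminal tail carrying planted regulatory motifs
(AHA for class A only, LFGV for class B only) — alongside decoys,
allohexaploid triads on A/B/D subgenome chromosomes, two-exon gene models
with a conserved intron inside the DBD, and treatment x organ TPM matrices
following a class-specific response design.

The DBD consensus and its secondary-structure element layout are a
synthetic construction shipped as package data (only the element order
α1-β1-β2-α2-α3-β3-β4 follows the published domain architecture).  All
outputs are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression_analysis import ExpressionMatrix, ORGANS, TREATMENTS
from .motif_annotation import MotifHit
from .sequence_io import GeneModel, ProteinRecord

# residues used for tails, linkers and inserts: no K/R (would seed spurious
# NLS), no hydrophobics (would seed spurious heptads or NES), no F/W
POLAR = "STNQEDGPH"
HEPTAD_A = "LADLESK"   # HR-A period; a/d anchors are L
HEPTAD_B = "LQNLEGK"   # HR-B period
LINKER = "STNQEDSGHPSTNQE"
N_HEPTADS_A = 3
N_HEPTADS_B = 2

#: Planted motif payloads (AHA payload carries the FWxx[FL] core).
MOTIF_SEQ = {"AHA": "FWEQF", "NLS": "KKRR", "LFGV": "LFGV", "ER": "AEKL",
             "NES": "LDLQLLM"}

DEFAULT_MOTIF_PLAN = {"A": ("NLS", "AHA"), "B": ("NLS", "LFGV"), "C": ("NLS",)}
DEFAULT_COUNTS = {"A1": 3, "A2": 3, "B1": 3, "B2": 3, "C1": 3, "C2": 3}

_CODONS = {
    "A": ("GCT", "GCC", "GCA"), "R": ("CGT", "CGC", "AGA"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "E": ("GAA", "GAG"), "Q": ("CAA", "CAG"), "G": ("GGT", "GGC", "GGA"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC", "ATA"),
    "L": ("CTT", "CTC", "CTA", "TTA"), "K": ("AAA", "AAG"),
    "M": ("ATG",), "F": ("TTT", "TTC"), "P": ("CCT", "CCC", "CCA"),
    "S": ("TCT", "TCC", "TCA"), "T": ("ACT", "ACC", "ACA"),
    "W": ("TGG",), "Y": ("TAT", "TAC"), "V": ("GTT", "GTC", "GTA"),
}


def dbd_template() -> tuple[str, tuple[str, ...]]:
    """Synthetic DBD consensus and its per-column element labels."""
    from importlib.resources import files

    residues, labels = [], []
    with (files("hsfkit.data") / "dbd_template.tsv").open() as fh:
        next(fh)
        for line in fh:
            r, el = line.split()
            residues.append(r)
            labels.append(el)
    return "".join(residues), tuple(labels)


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for a synthetic Hsf family.

    ``counts`` maps subclass (A1, B2, ...) to member count;
    ``insert_lengths`` holds the canonical HR-A/HR-B inserts per class;
    ``substitution_rate`` is the per-sequence residue substitution
    probability outside protected positions; ``subclass_divergence`` the
    rate of the seeded substitutions that differentiate subclass ancestors;
    ``triad_identity`` the target pairwise identity of homeolog copies;
    ``reference_free`` lists subclasses emitted without a reference (to
    exercise novel-subclass detection); ``er_subclasses`` get a C-terminal
    ER retention tetrapeptide; ``hard_mode`` lifts motif/anchor protection.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    insert_lengths: dict[str, int] = field(
        default_factory=lambda: {"A": 21, "B": 0, "C": 7})
    substitution_rate: float = 0.02
    subclass_divergence: float = 0.12
    triad_identity: float = 0.97
    decoy_count: int = 100
    motif_plan: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PLAN))
    reference_free: tuple[str, ...] = ()
    er_subclasses: tuple[str, ...] = ("A2",)
    family_prefix: str = "SynHsf"
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.subclass_divergence):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if any(c < 0 for c in self.counts.values()) or self.decoy_count < 0:
            raise ValueError("counts must be nonnegative")
        for cls, motifs in self.motif_plan.items():
            if "AHA" in motifs and cls != "A":
                raise ValueError("AHA is exclusive to class A")
            if "LFGV" in motifs and cls != "B":
                raise ValueError("LFGV is exclusive to class B")


@dataclass
class GeneTruth:
    """Ground truth for one generated gene (all positions 1-based)."""

    gene_id: str
    hsf_class: str
    subclass: str
    dbd_span: tuple[int, int]
    hra_span: tuple[int, int]
    hrb_span: tuple[int, int]
    insert_length: int
    motifs: list[MotifHit]
    chromosome: str = "U"
    triad_id: str | None = None
    root_specific: bool = False
    exons: tuple[tuple[int, int], ...] | None = None  # gene-local coords
    intron_in_dbd: bool = False
    cds_offset: int = 0


@dataclass
class SyntheticFamily:
    """A generated family: proteome (members then decoys) plus truth."""

    members: list[ProteinRecord]
    decoys: list[ProteinRecord]
    references: list[ProteinRecord]
    reference_subclasses: dict[str, str]
    truth: dict[str, GeneTruth]
    seed_alignment: list[str]
    seed_labels: tuple[str, ...]
    spec: FamilySpec

    @property
    def proteome(self) -> list[ProteinRecord]:
        return self.members + self.decoys


def _rand_polar(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(POLAR), size=n))


def _mutate(
    seq: list[str], rate: float, rng: np.random.Generator,
    protected: set[int], alphabet_for: dict[int, str],
) -> None:
    """In-place substitutions at the given per-position rate.

    Each eligible position draws its replacement from its own alphabet
    (polar positions stay polar, hydrophobic anchors stay hydrophobic) so
    structural and motif truth survives mutation.
    """
    if rate <= 0:
        return
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        i = int(i)
        if i in protected:
            continue
        alpha = alphabet_for.get(i, "ACDEFGHIKLMNPQRSTVWY")
        choices = [c for c in alpha if c != seq[i]]
        if choices:
            seq[i] = choices[int(rng.integers(len(choices)))]


class _Architect:
    """Builds subclass ancestor layouts and derives member sequences."""

    def __init__(self, spec: FamilySpec):
        self.spec = spec
        self.dbd, self.dbd_labels = dbd_template()

    def ancestor(self, subclass: str, rng: np.random.Generator):
        """Sequence layout of a subclass ancestor plus bookkeeping spans."""
        spec = self.spec
        cls = subclass[0]
        insert_len = spec.insert_lengths[cls]
        n_tail = int(rng.integers(20, 61))
        c_tail_len = int(rng.integers(60, 121))

        parts = {
            "n_tail": _rand_polar(rng, n_tail),
            "dbd": self.dbd,
            "linker": LINKER,
            "hra": HEPTAD_A * N_HEPTADS_A,
            "insert": _rand_polar(rng, insert_len),
            "hrb": HEPTAD_B * N_HEPTADS_B,
            "c_tail": _rand_polar(rng, c_tail_len),
        }

        # plant motifs into the C-tail (positions local to the tail)
        tail = list(parts["c_tail"])
        planted: list[tuple[str, int]] = []  # (kind, local 0-based start)
        plan = list(spec.motif_plan.get(cls, ()))
        if subclass in spec.er_subclasses:
            plan.append("ER")
        offsets = {"NLS": 0.15, "NES": 0.35, "AHA": 0.55, "LFGV": 0.75}
        for kind in plan:
            payload = MOTIF_SEQ[kind]
            if kind == "ER":
                lo = len(tail) - len(payload)
            else:
                lo = int(offsets[kind] * len(tail))
            tail[lo:lo + len(payload)] = list(payload)
            planted.append((kind, lo))
        parts["c_tail"] = "".join(tail)

        # subclass barcode: seeded divergence over DBD + linker + tails
        seq = list("".join(parts.values()))
        spans = {}
        pos = 0
        for name, s in parts.items():
            spans[name] = (pos, pos + len(s))
            pos += len(s)
        protected, alphabets = self._position_rules(spans, planted)
        bar_rng = rng
        _mutate(seq, spec.subclass_divergence, bar_rng, protected, alphabets)
        return "".join(seq), spans, planted, protected, alphabets

    def _position_rules(self, spans, planted):
        """Protected positions and per-position substitution alphabets."""
        protected: set[int] = set()
        alphabets: dict[int, str] = {}
        for name in ("n_tail", "insert", "c_tail", "linker"):
            lo, hi = spans[name]
            for i in range(lo, hi):
                alphabets[i] = POLAR
        for name in ("hra", "hrb"):
            lo, hi = spans[name]
            for i in range(lo, hi):
                phase = (i - lo) % 7
                if phase in (0, 3):   # a/d anchors stay hydrophobic
                    protected.add(i)
                else:
                    alphabets[i] = POLAR
        if not self.spec.hard_mode:
            tl, _ = spans["c_tail"]
            for kind, local in planted:
                protected.update(
                    range(tl + local, tl + local + len(MOTIF_SEQ[kind]))
                )
        return protected, alphabets

    def truth_from_layout(self, gene_id, subclass, seq, spans, planted):
        tl = spans["c_tail"][0]
        motifs = []
        for kind, local in planted:
            payload = MOTIF_SEQ[kind]
            hit_kind = {"NLS": "NLS_mono"}.get(kind, kind)
            motifs.append(MotifHit(hit_kind, tl + local + 1,
                                   seq[tl + local:tl + local + len(payload)]))
        return GeneTruth(
            gene_id=gene_id,
            hsf_class=subclass[0],
            subclass=subclass,
            dbd_span=(spans["dbd"][0] + 1, spans["dbd"][1]),
            hra_span=(spans["hra"][0] + 1, spans["hra"][1]),
            hrb_span=(spans["hrb"][0] + 1, spans["hrb"][1]),
            insert_length=spans["insert"][1] - spans["insert"][0],
            motifs=motifs,
        )


def reference_seed_alignment(
    n: int = 8, mutation_rate: float = 0.02, seed: int = 7
) -> tuple[list[str], tuple[str, ...]]:
    """Seed alignment of DBD-like reference rows with element labels.

    Rows are lightly mutated copies of the synthetic DBD consensus; the
    label tuple marks each column's secondary-structure element (loops "-").
    """
    consensus, labels = dbd_template()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        row = list(consensus)
        _mutate(row, mutation_rate, rng, set(), {})
        rows.append("".join(row))
    return rows, labels


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate a family proteome plus truth table.

    Each subclass receives a seeded ancestor (shared barcode mutations);
    members and one reference per subclass derive from it by per-sequence
    substitutions at ``spec.substitution_rate`` outside protected positions.
    Decoys are residue-shuffled member compositions.  Byte-identical outputs
    for a fixed seed.
    """
    arch = _Architect(spec)
    rng = np.random.default_rng(spec.seed)
    members: list[ProteinRecord] = []
    references: list[ProteinRecord] = []
    ref_subclasses: dict[str, str] = {}
    truth: dict[str, GeneTruth] = {}

    for subclass in sorted(spec.counts):
        count = spec.counts[subclass]
        if count == 0:
            continue
        anc_seq, spans, planted, protected, alphabets = arch.ancestor(
            subclass, rng)
        for i in range(1, count + 1):
            gid = f"{spec.family_prefix}{subclass}-{i}"
            seq = list(anc_seq)
            _mutate(seq, spec.substitution_rate, rng, protected, alphabets)
            seq = "".join(seq)
            members.append(ProteinRecord(gid, seq, f"synthetic Hsf {subclass}"))
            truth[gid] = arch.truth_from_layout(gid, subclass, seq, spans, planted)
        if subclass not in spec.reference_free:
            rid = f"Ref{subclass}"
            seq = list(anc_seq)
            _mutate(seq, spec.substitution_rate, rng, protected, alphabets)
            references.append(ProteinRecord(
                rid, "".join(seq), f"reference Hsf {subclass}"))
            ref_subclasses[rid] = subclass

    decoys: list[ProteinRecord] = []
    pool = members if members else None
    for i in range(1, spec.decoy_count + 1):
        if pool is not None:
            template = pool[int(rng.integers(len(pool)))].sequence
        else:
            template = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                           size=int(rng.integers(150, 400))))
        arr = np.array(list(template))
        rng.shuffle(arr)
        decoys.append(ProteinRecord(
            f"decoy-{i}", "".join(arr), "shuffled composition decoy"))

    seed_rows, seed_labels = reference_seed_alignment()
    return SyntheticFamily(
        members=members, decoys=decoys, references=references,
        reference_subclasses=ref_subclasses, truth=truth,
        seed_alignment=seed_rows, seed_labels=seed_labels, spec=spec,
    )


# ---------------------------------------------------------------------------
# allohexaploid genomes

def generate_allohexaploid(
    spec: FamilySpec,
    n_singleton_groups: int = 0,
    n_pair_groups: int = 0,
) -> SyntheticFamily:
    """Triplicate a base family onto A/B/D subgenome chromosomes.

    ``spec.counts`` gives the number of homeolog *groups* per subclass; each
    group becomes a triad of copies diverged to ``spec.triad_identity``
    pairwise, on chromosomes nA/nB/nD of one homeologous group number.
    The first ``n_singleton_groups`` groups (in generation order) emit only
    the A-subgenome copy and the next ``n_pair_groups`` only A and B,
    modelling gene loss after polyploidy.
    """
    base = generate_family(replace(spec, decoy_count=0))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 104729]))
    copy_rate = (1.0 - spec.triad_identity) / 2.0

    members: list[ProteinRecord] = []
    truth: dict[str, GeneTruth] = {}
    arch = _Architect(spec)
    group_no = 0
    seen_groups = 0
    counters: dict[str, int] = {}
    for rec in base.members:
        t = base.truth[rec.id]
        group_no = group_no % 7 + 1
        n_copies = 1 if seen_groups < n_singleton_groups else (
            2 if seen_groups < n_singleton_groups + n_pair_groups else 3)
        seen_groups += 1
        triad_id = f"grp{seen_groups}" if n_copies == 3 else None
        # reconstruct mutation rules from the truth spans
        spans = {
            "n_tail": (0, t.dbd_span[0] - 1),
            "dbd": (t.dbd_span[0] - 1, t.dbd_span[1]),
            "linker": (t.dbd_span[1], t.hra_span[0] - 1),
            "hra": (t.hra_span[0] - 1, t.hra_span[1]),
            "insert": (t.hra_span[1], t.hrb_span[0] - 1),
            "hrb": (t.hrb_span[0] - 1, t.hrb_span[1]),
            "c_tail": (t.hrb_span[1], len(rec.sequence)),
        }
        planted = [
            (m.kind.replace("NLS_mono", "NLS"),
             m.position - 1 - spans["c_tail"][0])
            for m in t.motifs
        ]
        protected, alphabets = arch._position_rules(spans, planted)
        for ci, sub in zip(range(n_copies), "ABD"):
            counters[t.subclass] = counters.get(t.subclass, 0) + 1
            gid = f"{spec.family_prefix}{t.subclass}-{counters[t.subclass]}"
            seq = list(rec.sequence)
            _mutate(seq, copy_rate, rng, protected, alphabets)
            seq = "".join(seq)
            members.append(ProteinRecord(gid, seq, f"homeolog copy {sub}"))
            gt = arch.truth_from_layout(gid, t.subclass, seq, spans, planted)
            gt.chromosome = f"{group_no}{sub}"
            gt.triad_id = triad_id
            truth[gid] = gt

    return SyntheticFamily(
        members=members, decoys=base.decoys, references=base.references,
        reference_subclasses=base.reference_subclasses, truth=truth,
        seed_alignment=base.seed_alignment, seed_labels=base.seed_labels,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# gene models

def generate_gene_models(
    family: SyntheticFamily,
    intron_range: tuple[int, int] = (80, 5836),
    intronless_subclasses: tuple[str, ...] = ("C3",),
    seed: int | None = None,
) -> dict[str, dict]:
    """Reverse-translate family members into genomic/cDNA pairs + models.

    Every gene outside ``intronless_subclasses`` receives one GT..AG intron
    inside its DBD codons (the conserved Hsf DBD intron); intron lengths are
    drawn uniformly from ``intron_range`` (default spanning the published
    wheat extremes, 80-5836 bp).  Returns per-gene dicts with keys
    ``cdna``, ``genomic``, ``model`` (:class:`GeneModel`) and updates the
    family truth with exon coordinates.
    """
    rng = np.random.default_rng(
        family.spec.seed if seed is None else seed)
    out: dict[str, dict] = {}
    chrom_cursor: dict[str, int] = {}
    for rec in family.members:
        t = family.truth[rec.id]
        codons = [
            _CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
            for aa in rec.sequence
        ]
        cds = "".join(codons) + "TAA"
        cdna = cds  # no UTRs by default; cds_offset stays 0
        if t.subclass in intronless_subclasses:
            genomic = cdna
            exons_local = ((1, len(genomic)),)
            t.intron_in_dbd = False
        else:
            # junction between two codons strictly inside the DBD
            mid_codon = (t.dbd_span[0] + t.dbd_span[1]) // 2
            cut = mid_codon * 3  # 0-based nt offset into the CDS
            ilen = int(rng.integers(intron_range[0], intron_range[1] + 1))
            intron = "GT" + "".join(
                rng.choice(list("ACGT"), size=ilen - 4)) + "AG"
            genomic = cdna[:cut] + intron + cdna[cut:]
            exons_local = ((1, cut), (cut + ilen + 1, len(genomic)))
            t.intron_in_dbd = True
        t.exons = exons_local
        chrom = t.chromosome
        offset = chrom_cursor.get(chrom, 0)
        chrom_cursor[chrom] = offset + len(genomic) + 10000
        model_chrom = chrom if chrom != "U" else "U"
        model = GeneModel(
            rec.id, model_chrom, "+",
            tuple((s + offset, e + offset) for s, e in exons_local),
        )
        out[rec.id] = {"cdna": cdna, "genomic": genomic, "model": model}
    return out


# ---------------------------------------------------------------------------
# expression

#: Class-level induction design: treatments with strong induction per organ.
DEFAULT_DESIGN = {
    "leaf": {"A": ("H2O2", "HS"), "B": ("H2O2", "HS", "ABA"), "C": ("ABA",)},
    "root": {"A": ("H2O2",), "B": ("H2O2", "HS", "ABA"), "C": ("ABA",)},
}
BASELINE_TPM = 0.5     # below the 1-TPM expression floor: hardly detectable
INDUCED_TPM = 40.0
ROOT_SPECIFIC_BASELINE = 8.0


def expected_call(
    t: GeneTruth, organ: str, treatment: str,
    design: dict = DEFAULT_DESIGN,
) -> str:
    """The design-table response call for a gene x organ x treatment cell."""
    if t.root_specific and organ == "leaf":
        return "not_expressed"
    induced = treatment in design[organ].get(t.hsf_class, ())
    if induced:
        return "up"
    if t.root_specific:  # elevated root baseline, uninduced
        return "insensitive" if ROOT_SPECIFIC_BASELINE >= 1.0 else "not_expressed"
    return "not_expressed" if BASELINE_TPM < 1.0 else "insensitive"


def generate_expression(
    family: SyntheticFamily,
    sigma: float = 0.2,
    design: dict = DEFAULT_DESIGN,
    root_specific: tuple[str, ...] = (),
    seed: int | None = None,
) -> ExpressionMatrix:
    """TPM matrix following the class x treatment x organ design.

    Cell means are ``BASELINE_TPM`` except for induced cells
    (``INDUCED_TPM``); genes named in ``root_specific`` keep a higher root
    baseline and are flat-zero in leaf.  Values carry multiplicative
    log-normal noise with the given sigma (sigma=0 reproduces the design
    exactly).  Marks ``root_specific`` in the family truth.
    """
    rng = np.random.default_rng(
        family.spec.seed if seed is None else seed)
    genes = [r.id for r in family.members]
    for g in root_specific:
        family.truth[g].root_specific = True
    cols = pd.MultiIndex.from_product(
        [ORGANS, TREATMENTS], names=("organ", "treatment"))
    data = np.zeros((len(genes), len(cols)))
    for gi, g in enumerate(genes):
        t = family.truth[g]
        for ci, (organ, treatment) in enumerate(cols):
            if t.root_specific and organ == "leaf":
                mean = 0.05
            else:
                base = ROOT_SPECIFIC_BASELINE if (
                    t.root_specific and organ == "root") else BASELINE_TPM
                induced = treatment in design[organ].get(t.hsf_class, ())
                mean = INDUCED_TPM if induced else base
            noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            data[gi, ci] = mean * noise
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols))
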