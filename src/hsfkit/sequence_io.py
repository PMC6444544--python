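"""Readers/writers and naming conventions shared by every pipeline stage.

All user-facing coordinates are 1-based inclusive (the convention of published
Hsf annotation tables, e.g. "(126)RRKP" meaning a motif starting at residue
126).  Internal arithmetic uses 0-based half-open spans; :func:`to_internal`
and :func:`to_external` convert losslessly between the two.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues; unknowns are mapped to X.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(STANDARD_RESIDUES) | {"X"}

#: Valid chromosome labels for an allohexaploid (bread wheat style) genome;
#: "U" denotes an unanchored scaffold.
CHROMOSOMES = tuple(f"{n}{s}" for n in range(1, 8) for s in "ABD") + ("U",)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# coordinate conversions

def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive ``(start, end)`` -> 0-based half-open ``(lo, hi)``."""
    return start - 1, end


def to_external(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open ``(lo, hi)`` -> 1-based inclusive ``(start, end)``."""
    return lo + 1, hi


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and free-text provenance."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in _VALID]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"record {self.id!r}: illegal residue {c!r} at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneName:
    """Structured Hsf gene name, e.g. ``TaHsfA2-10``.

    ``family`` is the prefix up to and including "Hsf" (``TaHsf``, ``SynHsf``),
    ``hsf_class`` one of A/B/C, ``subclass`` the class letter plus digits
    (``A2``), and ``index`` the member number within the subclass.
    """

    family: str
    hsf_class: str
    subclass: str
    index: int

    def __post_init__(self) -> None:
        if self.hsf_class not in "ABC":
            raise ValueError(f"class must be A, B or C, got {self.hsf_class!r}")
        if not self.subclass.startswith(self.hsf_class):
            raise ValueError(
                f"subclass {self.subclass!r} does not begin with class "
                f"letter {self.hsf_class!r}"
            )
        if self.index < 1:
            raise ValueError("index must be a positive integer")

    def __str__(self) -> str:  # en-dash on output, as in published tables
        return f"{self.family}{self.subclass}–{self.index}"

    def ascii(self) -> str:
        """Hyphenated form, convenient for file names and FASTA ids."""
        return f"{self.family}{self.subclass}-{self.index}"


_NAME_RE = re.compile(r"^([A-Za-z]*Hsf)([ABC])(\d+)[-–](\d+)$")


def parse_gene_name(name: str) -> GeneName:
    """Parse ``<family>Hsf<class><subclass>-<index>`` (hyphen or en-dash)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a recognisable Hsf gene name: {name!r}")
    family, cls, sub_digits, idx = m.groups()
    return GeneName(family, cls, cls + sub_digits, int(idx))


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic placement: chromosome, strand and exon spans.

    Exons are 1-based inclusive genomic coordinates, sorted ascending and
    non-overlapping.
    """

    id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {self.id!r}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in exons:
            if s < 1 or e < s:
                raise ValueError(f"gene {self.id!r}: bad exon span ({s},{e})")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class AnnotationRow:
    """One row of the per-gene annotation table (the published-table layout).

    Motif strings are formatted ``(pos)SEQ`` with 1-based positions.
    """

    gene: str
    chromosome: str
    transcript_id: str
    aa_length: int
    mw_kda: float
    nes: list[tuple[int, str]] = field(default_factory=list)
    nls: list[tuple[int, str]] = field(default_factory=list)
    aha: list[tuple[int, str]] = field(default_factory=list)
    er: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValueError(f"{self.gene}: mw_kda must be positive")
        for kind in ("nes", "nls", "aha", "er"):
            for pos, seq in getattr(self, kind):
                if not 1 <= pos <= self.aa_length:
                    raise ValueError(
                        f"{self.gene}: {kind.upper()} position {pos} outside "
                        f"[1, {self.aa_length}]"
                    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased; nonstandard residues (B, Z, J, U, O, *) are
    mapped to X with a warning.  Duplicate ids and empty sequences are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {i} ({rec.id!r}) has an empty sequence")
        cleaned = []
        for j, c in enumerate(seq):
            if c in _VALID:
                cleaned.append(c)
            elif c.isalpha() or c == "*":
                logger.warning(
                    "record %s: nonstandard residue %r at %d mapped to X",
                    rec.id, c, j + 1,
                )
                cleaned.append("X")
            else:
                raise FormatError(
                    f"record {rec.id!r}: illegal character {c!r} at position {j + 1}"
                )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, "".join(cleaned), desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (one per mRNA/transcript) from a GFF3 file.

    Exons are grouped per transcript and returned sorted; coordinates stay
    1-based inclusive per GFF3.  An exon outside its parent's span, an
    unknown strand, or overlapping exons raise :class:`FormatError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = []
        for ex in db.children(mrna, featuretype="exon", order_by="start"):
            if ex.start < mrna.start or ex.end > mrna.end:
                raise FormatError(
                    f"{mrna.id}: exon {ex.start}-{ex.end} outside parent span "
                    f"{mrna.start}-{mrna.end}"
                )
            exons.append((ex.start, ex.end))
        if mrna.strand not in "+-":
            raise FormatError(f"{mrna.id}: unknown strand {mrna.strand!r}")
        chrom = mrna.seqid
        try:
            models.append(GeneModel(mrna.id, chrom, mrna.strand, tuple(exons)))
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit minimal GFF3 (mRNA + exon features) for the given gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chromosome}\thsfkit\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.id}\n"
            )
            for i, (xs, xe) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chromosome}\thsfkit\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={m.id}.exon{i};Parent={m.id}\n"
                )


# ---------------------------------------------------------------------------
# annotation table

_TABLE_COLUMNS = (
    "gene", "chromosome", "transcript_id", "aa_length", "mw_kda",
    "nes", "nls", "aha", "er",
)


def _format_motifs(hits: list[tuple[int, str]]) -> str:
    return "".join(f"({pos}){seq}" for pos, seq in hits)


def write_annotation_table(rows: Sequence[AnnotationRow], path: str | Path) -> None:
    """Write the per-gene annotation table as TSV.

    Fixed column order gene, chromosome, transcript, AA, MW (kDa, 2 decimals),
    NES, NLS, AHA, ER; motif cells are ``(pos)SEQ`` runs, empty when absent.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join([
                    r.gene, r.chromosome, r.transcript_id, str(r.aa_length),
                    f"{r.mw_kda:.2f}",
                    _format_motifs(r.nes), _format_motifs(r.nls),
                    _format_motifs(r.aha), _format_motifs(r.er),
                ]) + "\n"
            )


def load_family_table(path: str | Path | None = None):
    """Load a published Hsf family annotation table as a DataFrame.

    With no argument, loads the bread-wheat (TaHsf) family table bundled with
    the package (gene, chromosome, transcript_id, aa_length, mw_kda for the
    82 published genes).
    """
    import pandas as pd

    if path is None:
        from importlib.resources import files

        path = files("hsfkit.data") / "tahsf_family.tsv"
        with path.open() as fh:
            return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
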