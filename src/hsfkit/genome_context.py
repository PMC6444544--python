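"""Chromosome statistics, homeolog triads and intron-exon structure.

A bread-wheat-style allohexaploid carries three subgenomes (A, B, D) in
seven homeologous chromosome groups; a homeolog triad is one high-identity
gene copy on each subgenome.  Gene structures are derived by anchoring a
cDNA exactly into its genomic sequence, preferring GT..AG-bounded gaps, and
the conserved-intron-in-DBD check projects the protein DBD span onto the
CDS to ask whether an intron splits it.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

from .sequence_io import GeneModel, parse_gene_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomeologGroup:
    """A triad: one gene per subgenome, same subclass, high identity.

    ``group_number`` (1-7) is set when the three chromosomes share their
    homeologous group number; ancient inter-group translocations (e.g. the
    wheat 4A/5A exchange) leave it unset.
    """

    group_id: str
    members: dict[str, str]  # subgenome letter -> gene id
    group_number: int | None
    min_identity_pct: float

    def __post_init__(self) -> None:
        if set(self.members) != {"A", "B", "D"}:
            raise ValueError("a triad needs exactly one member per subgenome")


@dataclass(frozen=True)
class GeneStructure:
    """Exon and intron spans, 1-based inclusive on the genomic sequence."""

    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        expect = tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )
        if self.introns != expect:
            raise ValueError("introns must be exactly the gaps between exons")
        if any(e < s for s, e in self.introns):
            raise ValueError("intron length must be >= 1")

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.introns)

    @property
    def intron_count(self) -> int:
        return len(self.introns)


# ---------------------------------------------------------------------------
# chromosome statistics

def chromosome_counts(
    genes: list[GeneModel] | pd.Series,
) -> tuple[dict[str, int], dict[int, int], int]:
    """Per-chromosome counts, per-homeologous-group totals and the U count.

    Returns ``(per_chromosome, per_group, unanchored)``.  Unanchored genes
    (chromosome "U") are excluded from chromosome and group totals and
    reported separately.  Every named chromosome (1A..7D) appears in the
    map, zero-count ones included.
    """
    if isinstance(genes, pd.Series):
        labels = list(genes)
    else:
        labels = [g.chromosome for g in genes]
    per_chrom = {f"{n}{s}": 0 for n in range(1, 8) for s in "ABD"}
    unanchored = 0
    for c in labels:
        if c == "U":
            unanchored += 1
        elif c in per_chrom:
            per_chrom[c] += 1
        else:
            raise ValueError(f"unknown chromosome label {c!r}")
    per_group = {
        n: sum(per_chrom[f"{n}{s}"] for s in "ABD") for n in range(1, 8)
    }
    return per_chrom, per_group, unanchored


def count_complete_triads(table: pd.DataFrame) -> int:
    """Complete homeolog triads derivable from a (gene, chromosome) table.

    Within each subclass, the number of disjoint triples with one member on
    each subgenome equals min(#A, #B, #D) — any within-subclass combination
    is an admissible triple, so maximum matching is the minimum count.
    Unanchored genes never participate.
    """
    total = 0
    for _, grp in table.groupby(
        table["gene"].map(lambda g: parse_gene_name(g).subclass)
    ):
        sub = {s: 0 for s in "ABD"}
        for c in grp["chromosome"]:
            if c != "U":
                sub[c[1]] += 1
        total += min(sub.values())
    return total


# ---------------------------------------------------------------------------
# homeolog triads with sequences

@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -0.5
    return a


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity: matches / aligned columns (gaps count)."""
    aln = _aligner().align(seq_a, seq_b)[0]
    a_row, b_row = aln[0], aln[1]
    matches = sum(x == y for x, y in zip(a_row, b_row))
    return matches / len(a_row)


def find_homeolog_groups(
    genes: list[tuple[str, str, str]],
    identity_threshold: float = 0.90,
) -> tuple[list[HomeologGroup], list[tuple[str, ...]]]:
    """Detect homeolog triads from (gene_id, chromosome, sequence) entries.

    Candidate triples take one gene per subgenome letter within the same
    subclass (gene ids must parse as Hsf names); a triple is accepted when
    all three pairwise global identities reach the threshold.  Genes join at
    most one group, resolved greedily by descending mean identity (ties by
    member ids).  Returns (groups, leftover pairs) where a leftover pair is
    a 2-subgenome combination meeting the threshold whose third copy is
    missing.
    """
    by_subclass: dict[str, dict[str, list[tuple[str, str]]]] = {}
    seqs = {g: s for g, _, s in genes}
    for gid, chrom, _ in genes:
        if chrom == "U":
            continue
        sub = parse_gene_name(gid).subclass
        by_subclass.setdefault(sub, {s: [] for s in "ABD"})[chrom[1]].append(
            (gid, chrom)
        )

    @lru_cache(maxsize=None)
    def ident(a: str, b: str) -> float:
        if a > b:
            a, b = b, a
        return global_identity(seqs[a], seqs[b])

    candidates = []
    for sub, pools in by_subclass.items():
        for (ga, ca), (gb, cb), (gd, cd) in itertools.product(
            pools["A"], pools["B"], pools["D"]
        ):
            pij = [ident(ga, gb), ident(ga, gd), ident(gb, gd)]
            if min(pij) >= identity_threshold:
                mean_ident = sum(pij) / 3
                candidates.append(
                    (mean_ident, (ga, gb, gd), (ca, cb, cd), min(pij))
                )
    candidates.sort(key=lambda c: (-c[0], c[1]))

    used: set[str] = set()
    groups: list[HomeologGroup] = []
    for mean_ident, (ga, gb, gd), (ca, cb, cd), min_ident in candidates:
        if used & {ga, gb, gd}:
            continue
        used.update((ga, gb, gd))
        numbers = {int(c[0]) for c in (ca, cb, cd)}
        groups.append(HomeologGroup(
            group_id=f"triad{len(groups) + 1}",
            members={"A": ga, "B": gb, "D": gd},
            group_number=numbers.pop() if len(numbers) == 1 else None,
            min_identity_pct=100.0 * min_ident,
        ))

    # incomplete high-identity pairs among leftovers
    pairs: list[tuple[str, ...]] = []
    for sub, pools in by_subclass.items():
        for sa, sb in itertools.combinations("ABD", 2):
            for (ga, _), (gb, _) in itertools.product(pools[sa], pools[sb]):
                if ga in used or gb in used:
                    continue
                if ident(ga, gb) >= identity_threshold:
                    pairs.append(tuple(sorted((ga, gb))))
    logger.info("homeolog grouping: %d triads, %d leftover pairs",
                len(groups), len(pairs))
    return groups, sorted(set(pairs))


# ---------------------------------------------------------------------------
# gene structure

def derive_gene_structure(cdna: str, genomic: str, min_intron: int = 4) -> GeneStructure:
    """Derive exon/intron spans by exact anchoring of the cDNA in the genomic.

    The cDNA must be the exact exon concatenation of the genomic sequence.
    At each candidate junction the splice is preferred when the excised gap
    starts with GT and ends with AG; among GT..AG solutions the shortest
    intron wins.  Unreconstructable cDNA raises ValueError.
    """
    cdna = cdna.upper()
    genomic = genomic.upper()
    if not cdna or not genomic:
        raise ValueError("empty sequence")

    n, m = len(cdna), len(genomic)

    def match_len(i: int, g: int) -> int:
        k = 0
        while i + k < n and g + k < m and cdna[i + k] == genomic[g + k]:
            k += 1
        return k

    from functools import lru_cache as _lru

    @_lru(maxsize=None)
    def solve(i: int, g: int, require_gtag: bool) -> tuple[tuple[int, int], ...] | None:
        """Exon 0-based half-open spans covering cdna[i:] from genomic[g:]."""
        k = match_len(i, g)
        if i + k == n and g + k == m:
            return ((g, m),)
        # try exon ends from the longest match downward
        for e in range(k, 0, -1):
            ni, ng = i + e, g + e
            rest = cdna[ni:]
            if not rest:
                continue  # trailing genomic left over: not a valid final exon
            # candidate next-exon starts
            start = ng + min_intron
            while True:
                g2 = genomic.find(rest[0], start)
                if g2 < 0:
                    break
                intron = genomic[ng:g2]
                ok_gtag = intron.startswith("GT") and intron.endswith("AG")
                if (not require_gtag or ok_gtag):
                    tail = solve(ni, g2, require_gtag)
                    if tail is not None:
                        return ((g, ng),) + tail
                start = g2 + 1
        return None

    spans = solve(0, 0, True)
    if spans is None:
        spans = solve(0, 0, False)
    if spans is None:
        raise ValueError("cDNA cannot be reconstructed from the genomic sequence")
    exons = tuple((s + 1, e) for s, e in spans)
    introns = tuple(
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
    )
    return GeneStructure(exons, introns)


def intron_in_dbd(
    structure: GeneStructure,
    dbd_protein_span: tuple[int, int],
    cds_offset: int = 0,
) -> tuple[bool, int | None]:
    """Does an intron interrupt the DBD's coding region?

    ``dbd_protein_span`` is 1-based inclusive on the protein;
    ``cds_offset`` is the number of cDNA bases (5' UTR) before the CDS.
    Returns (flag, 0-based intron index) for the first intron whose
    splice junction falls strictly inside the DBD's CDS projection.
    """
    p_start, p_end = dbd_protein_span
    nt_start = cds_offset + (p_start - 1) * 3  # 0-based, inclusive
    nt_end = cds_offset + p_end * 3            # 0-based, exclusive
    spliced = 0
    for idx, (s, e) in enumerate(structure.exons[:-1]):
        spliced += e - s + 1
        # junction after this exon sits between spliced-1 and spliced
        if nt_start < spliced < nt_end:
            return True, idx
    return False, None
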