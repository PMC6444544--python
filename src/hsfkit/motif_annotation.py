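"""C-terminal regulatory-motif scanners and physico-chemical calculators.

Scanners cover the class-A activator (AHA) motif, mono- and bipartite
nuclear localization signals (NLS), the leucine-rich nuclear export signal
(NES), C-terminal ER membrane retention tetrapeptides, and the class-B
repressor tetrapeptide LFGV.  The NLS/NES rules are consensus
approximations in the spirit of the dedicated predictors (cNLS Mapper,
NetNES), expressed as transparent positional rules.

All reported positions are 1-based.  The scanners are written as explicit
positional logic rather than regular expressions so that a regex oracle can
serve as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

BASIC = frozenset("KR")
NES_PHI = frozenset("LIVFM")

#: Default C-terminal ER membrane retention tetrapeptides, seeded from
#: published wheat Hsf annotations; user-extensible (data, not code).
DEFAULT_ER_LEXICON = (
    "AEKL", "AQKM", "DRVL", "SAQK", "SAEK", "EQLK", "GNMK", "SHRM", "ERCG",
)


@dataclass(frozen=True)
class MotifHit:
    """kind in {AHA, NLS_mono, NLS_bipartite, NES, ER, LFGV}; 1-based start."""

    kind: str
    position: int
    matched: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class PhysChem:
    aa_length: int
    mw_da: float
    pi: float

    def __post_init__(self) -> None:
        if self.mw_da < 18.02:
            raise ValueError("mw below a single water mass")
        if not 0 < self.pi < 14:
            raise ValueError("pI out of range")


def _seq(x: str | ProteinRecord) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else x


# ---------------------------------------------------------------------------
# AHA

def scan_aha(seq: str | ProteinRecord, trailing_optional: bool = True) -> list[MotifHit]:
    """Scan for the activator motif F-W-x-x-(F|L).

    The matched string is the 5-residue core.  A trailing hydrophobic
    element (F, I or L within the next 3 residues) is part of the fuller
    consensus but optional by default, because several published class-A
    motifs lack it; set ``trailing_optional=False`` to require it.
    Non-overlapping matches are reported left to right.
    """
    s = _seq(seq)
    hits: list[MotifHit] = []
    i = 0
    while i + 5 <= len(s):
        if s[i] == "F" and s[i + 1] == "W" and s[i + 4] in "FL":
            has_trailing = any(
                s[j] in "FIL" for j in range(i + 5, min(i + 8, len(s)))
            )
            if has_trailing or trailing_optional:
                hits.append(MotifHit("AHA", i + 1, s[i:i + 5]))
                i += 5  # non-overlapping on the core
                continue
        i += 1
    return hits


# ---------------------------------------------------------------------------
# NLS

def _count_basic(s: str) -> int:
    return sum(c in BASIC for c in s)


def scan_nls(seq: str | ProteinRecord) -> list[MotifHit]:
    """Scan for basic-residue nuclear localization signals.

    Monopartite: any 4-residue window with >= 3 K/R; overlapping windows are
    merged into maximal runs.  Bipartite: a 3-residue window with >= 2 K/R,
    a 6-14 residue spacer, then a 5-residue window with >= 3 K/R.
    """
    s = _seq(seq)
    n = len(s)
    hits: list[MotifHit] = []

    # monopartite windows, merged into maximal runs
    win_ok = [i for i in range(n - 3) if _count_basic(s[i:i + 4]) >= 3]
    i = 0
    while i < len(win_ok):
        start = win_ok[i]
        end = start + 4
        while i + 1 < len(win_ok) and win_ok[i + 1] <= end:
            i += 1
            end = win_ok[i] + 4
        hits.append(MotifHit("NLS_mono", start + 1, s[start:end]))
        i += 1

    # bipartite
    for i in range(n - 2):
        if _count_basic(s[i:i + 3]) < 2:
            continue
        for spacer in range(6, 15):
            j = i + 3 + spacer
            if j + 5 > n:
                break
            if _count_basic(s[j:j + 5]) >= 3:
                hits.append(MotifHit("NLS_bipartite", i + 1, s[i:j + 5]))
                break  # shortest spacer per anchor
    hits.sort(key=lambda h: (h.position, h.kind))
    return hits


# ---------------------------------------------------------------------------
# NES

#: NES spacer bounds: Φ x(g1) Φ x(g2) Φ x(g3) Φ, each gap a (min, max) range.
NES_GAPS = ((0, 5), (0, 4), (0, 2))


def _nes_match_at(s: str, i: int, gaps=NES_GAPS) -> int | None:
    """End (exclusive) of the greedy NES match starting at ``i``, or None.

    Pattern: Φ x(0,5) Φ x(0,4) Φ x(0,2) Φ with Φ in {L,I,V,F,M}; spacers are
    tried longest-first so the result equals a greedy regular-expression
    match.  Published wheat NES annotations need the 0 lower bound and a
    first spacer of up to 5 (their hydrophobic positions may be contiguous
    or widely spaced).
    """
    if i >= len(s) or s[i] not in NES_PHI:
        return None
    (a1, b1), (a2, b2), (a3, b3) = gaps
    for g1 in range(b1, a1 - 1, -1):
        p2 = i + 1 + g1
        if p2 >= len(s) or s[p2] not in NES_PHI:
            continue
        for g2 in range(b2, a2 - 1, -1):
            p3 = p2 + 1 + g2
            if p3 >= len(s) or s[p3] not in NES_PHI:
                continue
            for g3 in range(b3, a3 - 1, -1):
                p4 = p3 + 1 + g3
                if p4 < len(s) and s[p4] in NES_PHI:
                    return p4 + 1
    return None


def scan_nes(seq: str | ProteinRecord) -> list[MotifHit]:
    """Scan for leucine-rich nuclear export signals.

    For each start position the greedy (longest-spacer-first) match is
    taken; matches that end inside an earlier reported match are suppressed.
    """
    s = _seq(seq)
    hits: list[MotifHit] = []
    covered_end = -1
    for i in range(len(s)):
        end = _nes_match_at(s, i)
        if end is None or end <= covered_end:
            continue
        hits.append(MotifHit("NES", i + 1, s[i:end]))
        covered_end = end
    return hits


# ---------------------------------------------------------------------------
# C-terminal signals

def scan_c_terminal_signals(
    seq: str | ProteinRecord,
    er_lexicon: tuple[str, ...] = DEFAULT_ER_LEXICON,
    lfgv: str = "LFGV",
) -> list[MotifHit]:
    """ER retention and LFGV repressor tetrapeptide scan.

    ER: the C-terminal tetrapeptide is matched against a configurable
    lexicon.  LFGV: exact tetrapeptide search restricted to the C-terminal
    half of the protein (the repressor motif of class-B Hsfs sits in the
    C-terminal domain).
    """
    s = _seq(seq)
    if len(s) < 4:
        raise ValueError("sequence shorter than 4 residues")
    hits: list[MotifHit] = []
    tail = s[-4:]
    if tail in set(er_lexicon):
        hits.append(MotifHit("ER", len(s) - 3, tail))
    half = len(s) // 2
    pos = s.find(lfgv, half)
    if pos >= 0:
        hits.append(MotifHit("LFGV", pos + 1, lfgv))
    hits.sort(key=lambda h: h.position)
    return hits


# ---------------------------------------------------------------------------
# physico-chemical calculators

#: ExPASy-standard average residue masses (Da) of amino-acid residues in a
#: peptide chain (water already removed).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


def compute_mw(seq: str | ProteinRecord) -> float:
    """Average (not monoisotopic) molecular weight in Da.

    Sum of average residue masses plus one water.  X residues carry no
    defined mass and are excluded with a warning.
    """
    s = _seq(seq)
    if not s:
        raise ValueError("empty sequence")
    n_x = s.count("X")
    if n_x:
        logger.warning("%d unknown residue(s) X excluded from MW", n_x)
    return sum(AVERAGE_RESIDUE_MASS[c] for c in s if c != "X") + WATER_MASS


#: pKa values (EMBOSS set) for the ionizable groups used in the net-charge
#: model: N/C termini plus D, E, C, Y (acidic) and H, K, R (basic).
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}


def net_charge(seq: str | ProteinRecord, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Strictly decreasing in pH, which guarantees bisection convergence for the
    isoelectric point.
    """
    s = _seq(seq)
    pos = 10 ** -ph / (10 ** -PKA["Nterm"] + 10 ** -ph)
    neg = 10 ** -PKA["Cterm"] / (10 ** -PKA["Cterm"] + 10 ** -ph)
    for c in s:
        if c in ("D", "E", "C", "Y"):
            neg += 10 ** -PKA[c] / (10 ** -PKA[c] + 10 ** -ph)
        elif c in ("H", "K", "R"):
            pos += 10 ** -ph / (10 ** -PKA[c] + 10 ** -ph)
    return pos - neg


def compute_pi(seq: str | ProteinRecord, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the net-charge function."""
    s = _seq(seq)
    if not s:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-8:
        mid = (lo + hi) / 2
        q = net_charge(s, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def physchem(seq: str | ProteinRecord) -> PhysChem:
    s = _seq(seq)
    return PhysChem(len(s), compute_mw(s), compute_pi(s))
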