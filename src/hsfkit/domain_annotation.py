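"""DBD and HR-A/B domain calling, insert counting and class assignment.

The DNA-binding domain (DBD) is located with an element-labelled scoring
profile; its secondary-structure elements (α1-β1-β2-α2-α3-β3-β4) are called
full/partial/absent from per-column scores.  The oligomerization domain is
found as two arrays of hydrophobic heptad repeats (HR-A, HR-B) C-terminal of
the DBD; the residue count strictly between them assigns the Hsf class:
~21 residues for class A, none for class B, ~7 for class C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .profile_search import ProfileModel, window_scores
from .sequence_io import GeneModel, ProteinRecord

logger = logging.getLogger(__name__)

#: DBD secondary-structure elements in N- to C-terminal order.
DBD_ELEMENTS = ("a1", "b1", "b2", "a2", "a3", "b3", "b4")

#: Hydrophobic residues accepted at heptad a/d positions.
HYDROPHOBIC = frozenset("LIVFMA")

#: Canonical HR-A/HR-B insert length per class.
CANONICAL_INSERT = {"A": 21, "B": 0, "C": 7}


@dataclass(frozen=True)
class DomainHit:
    """A located domain: kind DBD or HRAB, 1-based inclusive span, score.

    For DBD hits, ``element_presence`` maps each secondary-structure element
    to full / partial / absent.
    """

    kind: str
    span: tuple[int, int]
    score: float
    element_presence: dict[str, str] | None = None


@dataclass(frozen=True)
class HRABAnnotation:
    """HR-A and HR-B spans (1-based inclusive) and the insert between them."""

    hr_a_span: tuple[int, int]
    hr_b_span: tuple[int, int]
    insert_length: int

    def __post_init__(self) -> None:
        if self.hr_a_span[1] >= self.hr_b_span[0]:
            raise ValueError("HR-A must end before HR-B starts")
        expect = self.hr_b_span[0] - self.hr_a_span[1] - 1
        if self.insert_length != expect:
            raise ValueError(
                f"insert_length {self.insert_length} inconsistent with spans "
                f"(expected {expect})"
            )


@dataclass(frozen=True)
class HsfClassification:
    hsf_class: str
    insert_length: int
    in_band: bool
    rationale: str


@dataclass
class AnnotatedCandidate:
    """A candidate protein bundled with its domain annotations."""

    record: ProteinRecord
    dbd: DomainHit | None = None
    hrab: HRABAnnotation | None = None
    classification: HsfClassification | None = None
    gene_model: GeneModel | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# DBD detection

def detect_dbd(
    dbd_profile: ProfileModel,
    protein: ProteinRecord,
    score_floor_fraction: float = 0.5,
    full_threshold: float = 0.8,
) -> DomainHit | None:
    """Locate the DBD as the best-scoring profile window above a floor.

    The floor defaults to half the profile's maximum attainable bitscore.
    Element presence: an element is ``full`` when at least
    ``full_threshold`` of its columns score positively in the hit window,
    ``partial`` when some do, ``absent`` when none do.  A profile without
    per-column element labels yields hits with ``element_presence`` None.
    """
    scores = window_scores(dbd_profile, protein.sequence)
    if scores.size == 0:
        return None
    best = int(np.argmax(scores))
    floor = score_floor_fraction * dbd_profile.max_score
    if scores[best] < floor:
        return None

    m = len(dbd_profile)
    labels = dbd_profile.column_labels
    if labels is None:
        return DomainHit("DBD", (best + 1, best + m), float(scores[best]), None)
    from .profile_search import _encode  # noqa: PLC0415

    idx = _encode(protein.sequence[best:best + m])
    lo_x = np.concatenate([dbd_profile.log_odds, np.zeros((m, 1))], axis=1)
    col_scores = lo_x[np.arange(m), idx]
    presence: dict[str, str] = {}
    for el in DBD_ELEMENTS:
        cols = [j for j, lab in enumerate(labels) if lab == el]
        if not cols:
            presence[el] = "absent"
            continue
        pos_frac = np.mean(col_scores[cols] > 0)
        if pos_frac >= full_threshold:
            presence[el] = "full"
        elif pos_frac > 0:
            presence[el] = "partial"
        else:
            presence[el] = "absent"
    return DomainHit("DBD", (best + 1, best + m), float(scores[best]), presence)


# ---------------------------------------------------------------------------
# heptad-repeat (HR-A/B) detection

def _is_heptad(seq: str, start: int, threshold: float) -> bool:
    """True when the heptad starting at ``start`` (0-based) passes the a/d rule."""
    if start + 7 > len(seq):
        return False
    ad = (seq[start], seq[start + 3])
    frac = sum(c in HYDROPHOBIC for c in ad) / 2
    return frac >= threshold


def _heptad_runs(seq: str, lo: int, threshold: float) -> list[tuple[int, int, int]]:
    """Maximal chains of consecutive heptads (same phase) from 0-based ``lo``.

    Returns (start, end_exclusive, n_heptads), sorted by start.
    """
    ok = [_is_heptad(seq, s, threshold) for s in range(len(seq))]
    runs = []
    for s in range(lo, len(seq)):
        if ok[s] and (s - 7 < lo or not ok[s - 7]):
            n = 0
            while s + 7 * (n + 1) <= len(seq) and ok[s + 7 * n]:
                n += 1
            runs.append((s, s + 7 * n, n))
    runs.sort()
    return runs


def detect_hrab(
    protein: ProteinRecord,
    search_start: int = 1,
    ad_threshold: float = 0.75,
    min_heptads_a: int = 2,
    min_heptads_b: int = 2,
) -> HRABAnnotation | None:
    """Find HR-A and HR-B heptad arrays C-terminal of ``search_start`` (1-based).

    Each HR is a maximal run of consecutive 7-residue periods whose a/d
    positions are hydrophobic (fraction >= ``ad_threshold`` per heptad).
    HR-A is the earliest qualifying run, HR-B the next non-overlapping run
    after it; the insert is the residue count strictly between them.  When a
    single contiguous run long enough for both is found (the insert-free,
    class-B architecture), it is split so HR-B takes the final
    ``min_heptads_b`` heptads.
    """
    seq = protein.sequence
    lo = search_start - 1
    runs = [r for r in _heptad_runs(seq, lo, ad_threshold) if r[2] >= min_heptads_a]
    if not runs:
        return None
    a_start, a_end, a_n = runs[0]
    b_candidates = [r for r in runs if r[0] >= a_end and r[2] >= min_heptads_b]
    if b_candidates:
        b_start, b_end, _ = b_candidates[0]
    elif a_n >= min_heptads_a + min_heptads_b:
        # contiguous HR-A/HR-B with no insert: split the single run
        b_start = a_end - 7 * min_heptads_b
        b_end = a_end
        a_end = b_start
    else:
        return None
    return HRABAnnotation(
        hr_a_span=(a_start + 1, a_end),
        hr_b_span=(b_start + 1, b_end),
        insert_length=b_start - a_end,
    )


# ---------------------------------------------------------------------------
# classification and family filtering

def classify_by_insert(
    insert_length: int, band_tolerance: int = 2
) -> HsfClassification:
    """Assign the Hsf class from the HR-A/HR-B insert length.

    Bands interpolate the canonical 0 (B), 7 (C) and 21 (A) residue inserts:
    B for 0-2, C for 3-13, A for >= 14.  ``in_band`` flags inserts within
    ``band_tolerance`` of a canonical value; out-of-band inserts are flagged
    but never rejected.
    """
    if insert_length < 0:
        raise ValueError("insert length must be nonnegative")
    if insert_length <= 2:
        cls = "B"
    elif insert_length <= 13:
        cls = "C"
    else:
        cls = "A"
    canonical = CANONICAL_INSERT[cls]
    in_band = abs(insert_length - canonical) <= band_tolerance
    note = (
        f"insert {insert_length} ~ canonical {canonical} (class {cls})"
        if in_band
        else f"insert {insert_length} outside canonical {canonical}±{band_tolerance}"
    )
    return HsfClassification(cls, insert_length, in_band, note)


def apply_family_filter(
    candidates: list[AnnotatedCandidate],
) -> tuple[list[AnnotatedCandidate], list[tuple[str, str]]]:
    """Apply the family retention filter.

    Drops candidates lacking a DBD or an HR-A/B annotation; among candidates
    whose gene models overlap on the same chromosome and strand, keeps the
    longest protein (ties broken lexicographically by id).  Returns the
    retained list and an exclusion report of (id, reason) pairs.
    """
    exclusions: list[tuple[str, str]] = []
    with_domains: list[AnnotatedCandidate] = []
    for c in candidates:
        if c.dbd is None:
            exclusions.append((c.record.id, "no DBD"))
        elif c.hrab is None:
            exclusions.append((c.record.id, "no HR-A/B"))
        else:
            with_domains.append(c)

    # overlap resolution on gene models
    def overlaps(a: GeneModel, b: GeneModel) -> bool:
        if a.chromosome != b.chromosome or a.strand != b.strand:
            return False
        (s1, e1), (s2, e2) = a.span, b.span
        return s1 <= e2 and s2 <= e1

    retained: list[AnnotatedCandidate] = []
    # stable preference order: longest protein first, then id
    ranked = sorted(
        with_domains, key=lambda c: (-len(c.record.sequence), c.record.id)
    )
    for c in ranked:
        clash = None
        if c.gene_model is not None:
            for r in retained:
                if r.gene_model is not None and overlaps(c.gene_model, r.gene_model):
                    clash = r
                    break
        if clash is None:
            retained.append(c)
        else:
            exclusions.append(
                (c.record.id, f"overlaps retained gene {clash.record.id}")
            )
    retained.sort(key=lambda c: c.record.id)
    logger.info(
        "family filter: %d retained, %d excluded", len(retained), len(exclusions)
    )
    return retained, exclusions
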