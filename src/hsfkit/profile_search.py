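"""Candidate screening by position-specific scoring profile.

A profile is built from a seed alignment of reference Hsf domain regions and
slid across every protein of a proteome.  Window scores are log2-odds sums
(emission over background), and significance is calibrated empirically by
scoring shuffled versions of the targets; a candidate is kept when its best
window is more extreme than essentially all shuffled windows.

This is a deliberately gapless screen: it serves as a high-recall filter in
front of explicit domain validation, so insert/delete states of a full
profile HMM are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequence_io import STANDARD_RESIDUES, ProteinRecord

logger = logging.getLogger(__name__)

_RES_INDEX = {c: i for i, c in enumerate(STANDARD_RESIDUES)}
_N_RES = len(STANDARD_RESIDUES)


@dataclass(frozen=True)
class ProfileModel:
    """Column-wise emission model over the 20 standard residues.

    ``emissions`` has shape (length, 20) and each row sums to 1;
    ``background`` sums to 1.  ``column_labels`` optionally carries a label
    per column (used to map secondary-structure elements onto hits).
    """

    emissions: np.ndarray
    background: np.ndarray
    pseudocount_weight: float
    column_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        em = np.asarray(self.emissions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "emissions", em)
        object.__setattr__(self, "background", bg)
        if em.ndim != 2 or em.shape[1] != _N_RES:
            raise ValueError("emissions must be (length, 20)")
        if not np.allclose(em.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each emission column must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount_weight > 0 and not (em > 0).all():
            raise ValueError("pseudocounted emissions must be positive")
        if self.column_labels is not None and len(self.column_labels) != len(em):
            raise ValueError("column_labels length mismatch")

    def __len__(self) -> int:
        return len(self.emissions)

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 20) matrix of log2(emission / background)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.emissions / self.background)

    @property
    def max_score(self) -> float:
        """Best attainable window bitscore (per-column maxima summed)."""
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class ProfileHit:
    """An ungapped window hit: 1-based inclusive span on the target."""

    seq_id: str
    start: int
    end: int
    bitscore: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be nonnegative")


def build_profile(
    seed_alignment: list[str],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
    column_labels: list[str] | None = None,
) -> ProfileModel:
    """Build a profile from equal-length gapped sequences.

    Columns whose gap fraction reaches ``max_gap_fraction`` are dropped
    (at the default 0.5, a half-gapped column is removed).
    Emission for residue a in a column is ``(count_a + w * bg_a) / (n_eff + w)``
    where ``n_eff`` is the number of non-gap residues in that column and
    ``w`` the pseudocount weight.  The default background is uniform 1/20;
    pass observed proteome frequencies to override.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    length = len(seed_alignment[0])
    if any(len(row) != length for row in seed_alignment):
        raise ValueError("seed alignment rows must have equal length")
    if background is None:
        bg = np.full(_N_RES, 1.0 / _N_RES)
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    rows = [row.upper() for row in seed_alignment]
    keep: list[int] = []
    for j in range(length):
        gaps = sum(1 for row in rows if row[j] in "-.")
        if gaps / len(rows) < max_gap_fraction:
            keep.append(j)
    if not keep:
        raise ValueError("no columns left after gap-column removal")

    w = float(pseudocount_weight)
    if w < 0:
        raise ValueError("pseudocount_weight must be nonnegative")
    emissions = np.zeros((len(keep), _N_RES))
    for out_j, j in enumerate(keep):
        counts = np.zeros(_N_RES)
        n_eff = 0
        for row in rows:
            c = row[j]
            if c in "-.":
                continue
            n_eff += 1
            if c in _RES_INDEX:
                counts[_RES_INDEX[c]] += 1
            else:  # X or other unknowns: spread over the background
                counts += bg
        emissions[out_j] = (counts + w * bg) / (n_eff + w)
    labels = None
    if column_labels is not None:
        if len(column_labels) != length:
            raise ValueError("column_labels must match alignment length")
        labels = tuple(column_labels[j] for j in keep)
    return ProfileModel(emissions, bg, w, labels)


def _encode(seq: str) -> np.ndarray:
    """Residue indices; X and unknowns get a sentinel scored at 0 bits."""
    return np.fromiter(
        (_RES_INDEX.get(c, _N_RES) for c in seq), dtype=np.int64, count=len(seq)
    )


def _scores_from_idx(lo_x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Window bitscores given the X-padded log-odds and encoded residues."""
    m = lo_x.shape[0]
    if idx.size < m:
        return np.empty(0)
    per_pos = lo_x[np.arange(m)[None, :], idx[
        np.arange(idx.size - m + 1)[:, None] + np.arange(m)[None, :]
    ]]
    return per_pos.sum(axis=1)


def _lo_x(model: ProfileModel) -> np.ndarray:
    """Log-odds matrix with an extra zero column for X/unknown residues."""
    return np.concatenate(
        [model.log_odds, np.zeros((len(model), 1))], axis=1)


def window_scores(model: ProfileModel, seq: str) -> np.ndarray:
    """Bitscores of every window of ``seq`` (empty if shorter than model)."""
    if len(seq) < len(model):
        return np.empty(0)
    return _scores_from_idx(_lo_x(model), _encode(seq))


def scan_profile(model: ProfileModel, target: ProteinRecord) -> list[ProfileHit]:
    """Score every ungapped window of the target; sort by descending bitscore.

    A target shorter than the profile yields an empty list (logged), not an
    error.
    """
    scores = window_scores(model, target.sequence)
    if scores.size == 0:
        logger.info("target %s shorter than profile; skipped", target.id)
        return []
    order = np.argsort(-scores, kind="stable")
    m = len(model)
    return [
        ProfileHit(target.id, int(i) + 1, int(i) + m, float(scores[i]))
        for i in order
    ]


def estimate_evalue(
    hit_score: float, null_scores: list[float] | np.ndarray, n_targets: int
) -> float:
    """Empirical E-value of a window score.

    ``null_scores`` are window bitscores of shuffled decoys with the same
    length distribution as the real targets.  The per-window tail probability
    is ``P = (1 + #{null >= score}) / (n_null + 1)`` and the expected number
    of false hits is ``E = P * n_targets`` where ``n_targets`` counts the
    window comparisons performed across the database.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("empty null score set: calibrate with shuffled decoys")
    p = (1 + int(np.count_nonzero(null >= hit_score))) / (null.size + 1)
    return p * n_targets


def screen_proteome(
    model: ProfileModel,
    proteome: list[ProteinRecord],
    e_threshold: float = 0.001,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Return the targets with at least one window at E below the threshold.

    The null distribution pools the window scores of ``n_shuffles``
    residue-shuffled copies of every target, so the empirical E-value floor
    ``W / (n_shuffles * W + 1)`` (W = windows scanned) sits just below 1/n_shuffles.
    Null scores are streamed and only counted against the candidate scores,
    never stored.  Deterministic for a fixed seed.
    """
    best = np.array([
        float(window_scores(model, t.sequence).max(initial=-np.inf))
        for t in proteome
    ])
    m = len(model)
    total_windows = sum(max(len(t.sequence) - m + 1, 0) for t in proteome)
    order = np.argsort(best)
    sorted_best = best[order]

    rng = np.random.default_rng(seed)
    n_null = 0
    # ge_counts[i] accumulates #{null >= sorted_best[i]}
    ge_counts = np.zeros(len(proteome), dtype=np.int64)
    lo_x = _lo_x(model)
    for t in proteome:
        if len(t.sequence) < m:
            continue
        idx = _encode(t.sequence)
        for _ in range(n_shuffles):
            rng.shuffle(idx)
            scores = _scores_from_idx(lo_x, idx)
            n_null += scores.size
            # nulls >= sorted_best[i]  <=>  nulls strictly right of insertion point
            ge_counts += scores.size - np.searchsorted(
                np.sort(scores), sorted_best, side="left"
            )
    if n_null == 0:
        raise ValueError("no null windows: all targets shorter than the profile")

    evalues = np.empty(len(proteome))
    evalues[order] = (1 + ge_counts) / (n_null + 1) * total_windows
    kept = [
        t for t, e, b in zip(proteome, evalues, best)
        if np.isfinite(b) and e < e_threshold
    ]
    logger.info(
        "screen: %d/%d targets below E<%g (null windows=%d)",
        len(kept), len(proteome), e_threshold, n_null,
    )
    return kept
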