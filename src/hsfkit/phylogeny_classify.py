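"""Distance phylogeny of Hsf N-terminal regions and subclass assignment.

Distances between aligned rows are p-distances under pairwise deletion
(sites with a gap in either row are skipped), corrected for multiple hits
with the Poisson transform d = -ln(1 - p).  Trees are built with
neighbor joining and internal edges receive bootstrap supports from
column-resampled replicates.  Queries inherit the subclass of the reference
sharing their smallest well-supported clade; well-supported clades with no
reference found a new subclass label (this is how a reference-free clade of
class-C wheat genes acquires a novel subclass name).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        if (v < 0).any():
            raise ValueError("negative distances")


@dataclass(frozen=True)
class SubclassAssignment:
    gene_id: str
    subclass: str  # e.g. "A2", or "novel:C3", or "unresolved"
    supporting_reference: str | None
    identity_pct: float | None
    clade_bootstrap: float | None
    conflict: str | None = None


# ---------------------------------------------------------------------------
# distances

def extract_n_terminal_region(
    protein, dbd_span: tuple[int, int], hrab_span: tuple[int, int]
) -> str:
    """Residues from the DBD start through the HR-B end (1-based inclusive).

    This N-proximal region (DBD + linker + oligomerization domain) is the
    conserved part used for tree building.
    """
    if dbd_span is None or hrab_span is None:
        raise ValueError("both DBD and HR-A/B spans are required")
    seq = protein.sequence if hasattr(protein, "sequence") else protein
    start, end = dbd_span[0], hrab_span[1]
    if end > len(seq):
        raise ValueError(f"HR-B end {end} beyond protein length {len(seq)}")
    if start < 1 or start > end:
        raise ValueError(f"bad region ({start}, {end})")
    return seq[start - 1:end]


def build_anchored_alignment(
    sequences: dict[str, str],
    spans: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]],
) -> dict[str, str]:
    """Stack N-terminal regions into alignment rows using domain anchors.

    ``spans`` maps id -> (dbd_span, hra_span, hrb_span), 1-based inclusive.
    Each of the five segments (DBD, linker, HR-A, insert, HR-B) is padded
    with trailing gaps to its maximum length across genes, so domain
    boundaries — not a de-novo aligner — define the coordinate system.
    Pairwise deletion then ignores the padding.
    """
    segmented: dict[str, list[str]] = {}
    for gid, (dbd, hra, hrb) in spans.items():
        s = sequences[gid]
        segmented[gid] = [
            s[dbd[0] - 1:dbd[1]],
            s[dbd[1]:hra[0] - 1],
            s[hra[0] - 1:hra[1]],
            s[hra[1]:hrb[0] - 1],
            s[hrb[0] - 1:hrb[1]],
        ]
    widths = [
        max(len(seg[k]) for seg in segmented.values()) for k in range(5)
    ]
    return {
        gid: "".join(seg[k].ljust(widths[k], "-") for k in range(5))
        for gid, seg in segmented.items()
    }


def pdistance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites with a gap ('-' or '.') in either row are excluded from both the
    numerator and the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows must have equal length")
    compared = mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "-." or b in "-.":
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("zero comparable sites under pairwise deletion")
    return mismatches / compared


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), defined on [0, 1)."""
    if not 0 <= p < 1:
        raise ValueError(f"p must be in [0, 1), got {p}")
    return -math.log1p(-p)


def distance_matrix(
    alignment: dict[str, str], correction: str = "poisson"
) -> DistanceMatrix:
    """Pairwise-deletion distances for a labelled alignment."""
    taxa = tuple(alignment)
    n = len(taxa)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = pdistance(alignment[taxa[i]], alignment[taxa[j]])
            d = poisson_correct(p) if correction == "poisson" else p
            v[i, j] = v[j, i] = d
    return DistanceMatrix(taxa, v)


# ---------------------------------------------------------------------------
# neighbor joining

def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lowest-index pair, so the result is
    deterministic.  Negative branch-length estimates are clamped to zero and
    flagged (node attribute ``clamped``).  On additive matrices the
    generating tree's topology and branch lengths are recovered exactly.
    The returned tree is unrooted in spirit: the root is a trifurcation.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among the minima
        flat = np.argmin(q)
        fi, fj = divmod(int(flat), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            child.length = max(float(ln), 0.0)
            child.clamped = ln < 0
            parent.append(child)
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0])
        for fk, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # final trifurcation: pendant lengths from the three-point formulas
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, ln in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(float(ln), 0.0)
        nodes[k].clamped = ln < 0
        root.append(nodes[k])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the smaller-side leaf set
    (represented canonically by frozenset of names on one side)."""
    all_taxa = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_taxa) - 1:
            other = all_taxa - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> dict[frozenset[str], float]:
    """Bootstrap supports (percent) for the bipartitions of the full-data tree.

    Columns are resampled with replacement; each replicate is run through the
    same distance + NJ pipeline.  Replicates whose resampled columns leave a
    pair with zero comparable sites, or a saturated distance, are redrawn.
    Deterministic for a fixed seed and invariant to taxon input order
    (taxa are processed in sorted order internally).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    alignment = {k: alignment[k] for k in sorted(alignment)}
    length = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)
    full = build_nj_tree(distance_matrix(alignment, correction))
    targets = bipartitions(full)
    counts = {part: 0 for part in targets}
    done = 0
    attempts = 0
    while done < n_replicates:
        attempts += 1
        if attempts > 50 * n_replicates:
            raise RuntimeError("bootstrap: too many degenerate replicates")
        cols = rng.integers(0, length, size=length)
        resampled = {
            k: "".join(v[c] for c in cols) for k, v in alignment.items()
        }
        try:
            rep = build_nj_tree(distance_matrix(resampled, correction))
        except ValueError:
            continue
        rep_parts = bipartitions(rep)
        for part in targets:
            if part in rep_parts:
                counts[part] += 1
        done += 1
    return {part: 100.0 * c / n_replicates for part, c in counts.items()}


def annotate_supports(
    tree: TreeNode, supports: dict[frozenset[str], float]
) -> TreeNode:
    """Attach bootstrap supports to the matching internal nodes in place."""
    all_taxa = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.support = supports[key]
    return tree


# ---------------------------------------------------------------------------
# subclass assignment

def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identity over pairwise-deletion-comparable sites."""
    return 100.0 * (1.0 - pdistance(row_a, row_b))


def assign_subclasses(
    tree: TreeNode,
    query_ids: list[str],
    reference_subclasses: dict[str, str],
    alignment: dict[str, str],
    supports: dict[frozenset[str], float] | None = None,
    min_support: float = 50.0,
    min_identity: float = 90.0,
    insert_classes: dict[str, str] | None = None,
) -> list[SubclassAssignment]:
    """Reference-anchored subclass labels for query leaves.

    Ancestors are climbed from each query leaf.  The first clade with
    bootstrap support above ``min_support`` that contains a reference
    decides: when the best N-terminal identity to a reference in that clade
    reaches ``min_identity`` the query takes that reference's subclass
    (flagged ``class_conflict`` if the label letter disagrees with the
    query's insert-based class); otherwise the query is novel, and all
    queries sharing its largest well-supported reference-free clade receive
    one new label — class letter plus the next integer after the largest
    existing index for that letter.  Queries with no well-supported
    ancestor at all are unresolved.
    """
    leaf_names = {t.name for t in tree.tips()}
    missing = [q for q in query_ids if q not in leaf_names]
    if missing:
        raise ValueError(f"queries absent from tree: {missing}")
    if supports is not None:
        annotate_supports(tree, supports)

    def node_support(node: TreeNode) -> float | None:
        return getattr(node, "support", None)

    def references_in(node: TreeNode) -> list[str]:
        return [t.name for t in node.tips() if t.name in reference_subclasses]

    # next free subclass index per class letter
    next_index: dict[str, int] = {}
    for sub in reference_subclasses.values():
        letter, digits = sub[0], sub[1:]
        idx = int(digits) if digits.isdigit() else 0
        next_index[letter] = max(next_index.get(letter, 0), idx)
    novel_labels: dict[int, str] = {}  # id(node) -> label

    def novel_label_for(node: TreeNode, fallback_letter: str | None) -> str:
        key = id(node)
        if key not in novel_labels:
            letter = None
            if insert_classes:
                letters = {insert_classes.get(t.name) for t in node.tips()} - {None}
                if len(letters) == 1:
                    letter = letters.pop()
            if letter is None:
                letter = fallback_letter or "X"
            next_index[letter] = next_index.get(letter, 0) + 1
            novel_labels[key] = f"{letter}{next_index[letter]}"
        return novel_labels[key]

    results: list[SubclassAssignment] = []
    for q in query_ids:
        leaf = tree.find(q)
        decided = None
        ref_free_clade: TreeNode | None = None  # largest supported, no refs
        saw_support = False
        for anc in leaf.ancestors():
            if anc.is_root():
                break
            sup = node_support(anc)
            if sup is None or sup <= min_support:
                continue
            saw_support = True
            refs = references_in(anc)
            if not refs:
                ref_free_clade = anc
                continue
            idents = {
                r: percent_identity(alignment[q], alignment[r]) for r in refs
            }
            best = max(sorted(idents), key=lambda r: idents[r])
            if idents[best] >= min_identity:
                conflict = None
                label = reference_subclasses[best]
                if insert_classes and q in insert_classes and \
                        label[0] != insert_classes[q]:
                    conflict = "class_conflict"
                decided = SubclassAssignment(
                    q, label, best, idents[best], sup, conflict
                )
            else:
                node = ref_free_clade if ref_free_clade is not None else leaf
                letter = insert_classes.get(q) if insert_classes else None
                decided = SubclassAssignment(
                    q, novel_label_for(node, letter), None, idents[best],
                    sup, "novel",
                )
            break
        if decided is None:
            if saw_support and ref_free_clade is not None:
                letter = insert_classes.get(q) if insert_classes else None
                sup = node_support(ref_free_clade)
                decided = SubclassAssignment(
                    q, novel_label_for(ref_free_clade, letter), None, None,
                    sup, "novel",
                )
            else:
                decided = SubclassAssignment(
                    q, "unresolved", None, None, None, "no_supported_clade"
                )
        results.append(decided)
    logger.info(
        "subclass assignment: %d queries, %d unresolved",
        len(results), sum(r.subclass == "unresolved" for r in results),
    )
    return results
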