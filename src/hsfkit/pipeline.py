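"""End-to-end orchestration: screen, annotate, classify, report.

Thin glue over the stage modules, mirroring a genome-wide Hsf survey:
profile screen of the proteome, DBD/HR-A/B validation with the family
retention filter, insert-based classification, C-terminal motif and
physico-chemical annotation, and the final annotation table rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import domain_annotation as da
from . import motif_annotation as ma
from .profile_search import ProfileModel, build_profile, screen_proteome
from .sequence_io import AnnotationRow, GeneModel, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    candidates: list[ProteinRecord]
    retained: list[da.AnnotatedCandidate]
    exclusions: list[tuple[str, str]]
    rows: list[AnnotationRow] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        return [c.record.id for c in self.retained]


def annotate_candidate(
    record: ProteinRecord,
    dbd_profile: ProfileModel,
    gene_model: GeneModel | None = None,
) -> da.AnnotatedCandidate:
    """Domain-annotate one candidate: DBD, HR-A/B, insert classification."""
    cand = da.AnnotatedCandidate(record, gene_model=gene_model)
    cand.dbd = da.detect_dbd(dbd_profile, record)
    if cand.dbd is not None:
        cand.hrab = da.detect_hrab(record, search_start=cand.dbd.span[1] + 1)
    if cand.hrab is not None:
        cand.classification = da.classify_by_insert(cand.hrab.insert_length)
    return cand


def motif_annotations(cand: da.AnnotatedCandidate) -> dict[str, list[ma.MotifHit]]:
    """Scan the C-terminal region (past HR-B) of a retained candidate.

    Positions are reported on the full protein.  The ER scan always looks
    at the true C-terminus; NLS/NES/AHA/LFGV are restricted to the region
    C-terminal of the oligomerization domain, where these signals sit.
    """
    seq = cand.record.sequence
    offset = cand.hrab.hr_b_span[1] if cand.hrab else 0
    tail = seq[offset:]

    def shift(hits):
        return [ma.MotifHit(h.kind, h.position + offset, h.matched)
                for h in hits]

    out = {
        "AHA": shift(ma.scan_aha(tail)),
        "NLS": shift(ma.scan_nls(tail)),
        "NES": shift(ma.scan_nes(tail)),
    }
    ct = ma.scan_c_terminal_signals(seq) if len(seq) >= 4 else []
    out["ER"] = [h for h in ct if h.kind == "ER"]
    out["LFGV"] = [h for h in ct if h.kind == "LFGV"]
    return out


def run_pipeline(
    proteome: list[ProteinRecord],
    seed_alignment: list[str],
    seed_labels: list[str] | tuple[str, ...] | None = None,
    gene_models: dict[str, GeneModel] | None = None,
    e_threshold: float = 0.001,
    pseudocount_weight: float = 1.0,
    seed: int = 0,
) -> PipelineResult:
    """Screen a proteome and annotate the retained Hsf family."""
    profile = build_profile(
        seed_alignment, pseudocount_weight=pseudocount_weight,
        column_labels=list(seed_labels) if seed_labels else None,
    )
    candidates = screen_proteome(
        profile, proteome, e_threshold=e_threshold, seed=seed)
    logger.info("screen retained %d/%d candidates", len(candidates),
                len(proteome))

    annotated = [
        annotate_candidate(
            rec, profile,
            gene_models.get(rec.id) if gene_models else None,
        )
        for rec in candidates
    ]
    retained, exclusions = da.apply_family_filter(annotated)

    rows: list[AnnotationRow] = []
    for cand in retained:
        motifs = motif_annotations(cand)
        rec = cand.record
        model = cand.gene_model
        rows.append(AnnotationRow(
            gene=rec.id,
            chromosome=model.chromosome if model else "U",
            transcript_id="",
            aa_length=len(rec.sequence),
            mw_kda=ma.compute_mw(rec.sequence) / 1000.0,
            nes=[(h.position, h.matched) for h in motifs["NES"]],
            nls=[(h.position, h.matched) for h in motifs["NLS"]],
            aha=[(h.position, h.matched) for h in motifs["AHA"]],
            er=[(h.position, h.matched) for h in motifs["ER"]],
        ))
    return PipelineResult(candidates, retained, exclusions, rows)
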