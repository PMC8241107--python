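"""Reconciling homology-scan hits with predicted epitopes by coordinates.

A scan hit is *recovered* (full match) when its subject interval and an
in-tier predicted peptide on the same protein coincide up to a small
overhang: one interval must contain the other with at most
``overhang_max_aa`` residues of total overhead (experimental epitopes vary
in length while predictions are fixed-length, so containment is tested in
both directions).  Intervals that intersect without meeting the overhang
budget are *partial*; disjoint intervals do not match.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .alignment import MimicryHit
from .io_formats import PipelineConfig
from .mhc import PredictedPeptide


class OverlapClass(Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


def classify_overlap(pred_start: int, pred_end: int, hit_start: int,
                     hit_end: int, overhang_max: int = 3) -> OverlapClass:
    """Classify the coordinate relation of a prediction and a hit interval
    (1-based inclusive, same protein).

    FULL when either interval contains the other with total overhang
    <= overhang_max; PARTIAL when they merely intersect; NONE when disjoint.
    """
    if pred_end < pred_start or hit_end < hit_start:
        raise ValueError("inverted interval")
    # containment either way with bounded total overhang
    if hit_start >= pred_start and hit_end <= pred_end:
        if (hit_start - pred_start) + (pred_end - hit_end) <= overhang_max:
            return OverlapClass.FULL
    if pred_start >= hit_start and pred_end <= hit_end:
        if (pred_start - hit_start) + (hit_end - pred_end) <= overhang_max:
            return OverlapClass.FULL
    if hit_start <= pred_end and pred_start <= hit_end:
        return OverlapClass.PARTIAL
    return OverlapClass.NONE


@dataclass
class HitRecovery:
    epitope_id: str
    subject_accession: str
    organism: str
    hit_start: int
    hit_end: int
    best_class: OverlapClass
    best_pred_start: int | None = None
    best_pred_end: int | None = None


_CLASS_ORDER = {OverlapClass.FULL: 0, OverlapClass.PARTIAL: 1, OverlapClass.NONE: 2}


def recover_hits(predictions: list[PredictedPeptide], hits: list[MimicryHit],
                 cfg: PipelineConfig | None = None,
                 ) -> tuple[dict[str, dict[str, int]], list[HitRecovery]]:
    """Label every hit by its best overlap class over the in-tier predictions
    on the same protein, and aggregate per organism.

    Returns (summary, details) where summary maps organism ->
    {recovered, partial, unrecovered} with counts conserved (their sum is
    the organism's hit count).
    """
    cfg = cfg or PipelineConfig()
    by_protein: dict[str, list[PredictedPeptide]] = {}
    for p in predictions:
        by_protein.setdefault(p.protein_accession, []).append(p)

    details: list[HitRecovery] = []
    summary: dict[str, dict[str, int]] = {}
    for h in hits:
        a = h.alignment
        best = OverlapClass.NONE
        best_pred: PredictedPeptide | None = None
        for p in by_protein.get(h.subject_accession, []):
            oc = classify_overlap(p.start, p.end, a.subject_start, a.subject_end,
                                  cfg.overhang_max_aa)
            if _CLASS_ORDER[oc] < _CLASS_ORDER[best]:
                best, best_pred = oc, p
                if best is OverlapClass.FULL:
                    break
        org = h.organism.organism_name if h.organism else "unannotated"
        details.append(HitRecovery(
            epitope_id=h.epitope_id, subject_accession=h.subject_accession,
            organism=org, hit_start=a.subject_start, hit_end=a.subject_end,
            best_class=best,
            best_pred_start=best_pred.start if best_pred else None,
            best_pred_end=best_pred.end if best_pred else None,
        ))
        s = summary.setdefault(org, {"recovered": 0, "partial": 0, "unrecovered": 0})
        if best is OverlapClass.FULL:
            s["recovered"] += 1
        elif best is OverlapClass.PARTIAL:
            s["partial"] += 1
        else:
            s["unrecovered"] += 1
    return summary, details


def recovery_to_frame(details: list[HitRecovery]):
    import pandas as pd

    cols = ["organism", "subject_accession", "epitope_id", "hit_start",
            "hit_end", "overlap_class", "pred_start", "pred_end"]
    return pd.DataFrame([{
        "organism": d.organism, "subject_accession": d.subject_accession,
        "epitope_id": d.epitope_id, "hit_start": d.hit_start,
        "hit_end": d.hit_end, "overlap_class": d.best_class.value,
        "pred_start": d.best_pred_start, "pred_end": d.best_pred_end,
    } for d in details], columns=cols)
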