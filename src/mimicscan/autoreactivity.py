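"""Two-round autoreactivity screen of top-tier predicted peptides.

Round 1 aligns each candidate peptide against the full autoantigen panel
and keeps every antigen attaining the maximal local-alignment score (ties
are all carried forward).  Round 2 re-aligns the peptide against each
round-1 winner and confirms the pair when the Karlin-Altschul e-value
(m = peptide length, n = antigen length) falls below the significance bound
(default 1e-3).  Peptides shorter than the minimum alignable length
(default 10 residues) cannot be assessed and are reported as too short;
candidates homologous to the experimental epitope pool are excluded before
round 1 so the screen only reports novel autoreactive peptides.

Both rounds use the package's single internal aligner and e-value
statistic; absolute e-values therefore differ from the LALIGN values a
web-server run would print.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import ScoringScheme, compute_evalue, smith_waterman
from .io_formats import EpitopeRecord, PipelineConfig, ProteinRecord
from .mhc import PredictedPeptide, exclude_homologous_to_experimental

logger = logging.getLogger(__name__)


@dataclass
class AutoreactivityResult:
    peptide: PredictedPeptide
    candidate_antigens: list[str] = field(default_factory=list)
    confirmed_antigen: str | None = None
    round1_score: int | None = None
    round2_evalue: float | None = None
    status: str = "not_significant"   # confirmed | not_significant | too_short | excluded_homologous


def round1_best_antigens(peptide: str, antigens: list[ProteinRecord],
                         scheme: ScoringScheme | None = None,
                         ) -> tuple[list[str], int]:
    """All antigens attaining the maximal local-alignment score to the
    peptide, with that score.  Winner set is independent of panel order."""
    if not antigens:
        raise ValueError("empty antigen panel")
    scheme = scheme or ScoringScheme()
    scores: dict[str, int] = {}
    for ag in antigens:
        alns = smith_waterman(peptide, ag.sequence, scheme,
                              query_id="peptide", subject_id=ag.accession)
        scores[ag.accession] = alns[0].score if alns else 0
    best = max(scores.values())
    winners = sorted(acc for acc, sc in scores.items() if sc == best)
    return winners, best


def round2_confirm(peptide: str, antigen: ProteinRecord,
                   cfg: PipelineConfig | None = None,
                   scheme: ScoringScheme | None = None,
                   ) -> tuple[float | None, str]:
    """Confirmation alignment: returns (evalue, status)."""
    cfg = cfg or PipelineConfig()
    scheme = scheme or ScoringScheme()
    if len(peptide) < cfg.min_align_len:
        return None, "too_short"
    alns = smith_waterman(peptide, antigen.sequence, scheme,
                          query_id="peptide", subject_id=antigen.accession)
    if not alns:
        return None, "not_significant"
    ev = compute_evalue(alns[0].score, len(peptide), len(antigen.sequence), scheme)
    return ev, ("confirmed" if ev < cfg.autoreactivity_evalue_max else "not_significant")


def autoreactivity_screen(predictions: list[PredictedPeptide],
                          antigens: list[ProteinRecord],
                          experimental: list[EpitopeRecord],
                          cfg: PipelineConfig | None = None,
                          scheme: ScoringScheme | None = None,
                          ) -> list[AutoreactivityResult]:
    """Run the full screen on tier-selected, allele-filtered predictions.

    For each peptide: exclude if homologous to the experimental pool, else
    round 1 against the antigen panel, then round 2 on every round-1
    winner.  ``confirmed_antigen`` holds the lowest-e-value confirmed
    winner (ties broken by antigen id); when several winners confirm, all
    their e-values are evaluated and the best retained.
    """
    cfg = cfg or PipelineConfig()
    scheme = scheme or ScoringScheme()
    surviving = exclude_homologous_to_experimental(predictions, experimental, cfg, scheme)
    surviving_keys = {(p.protein_accession, p.start, p.peptide) for p in surviving}
    results = []
    for p in predictions:
        if (p.protein_accession, p.start, p.peptide) not in surviving_keys:
            results.append(AutoreactivityResult(peptide=p, status="excluded_homologous"))
            continue
        if len(p.peptide) < cfg.min_align_len:
            results.append(AutoreactivityResult(peptide=p, status="too_short"))
            continue
        winners, score = round1_best_antigens(p.peptide, antigens, scheme)
        by_acc = {ag.accession: ag for ag in antigens}
        confirmed: list[tuple[float, str]] = []
        best_ev: float | None = None
        for acc in winners:
            ev, status = round2_confirm(p.peptide, by_acc[acc], cfg, scheme)
            if ev is not None and (best_ev is None or ev < best_ev):
                best_ev = ev
            if status == "confirmed":
                confirmed.append((ev, acc))
        if confirmed:
            confirmed.sort()
            results.append(AutoreactivityResult(
                peptide=p, candidate_antigens=winners, round1_score=score,
                confirmed_antigen=confirmed[0][1], round2_evalue=confirmed[0][0],
                status="confirmed"))
        else:
            results.append(AutoreactivityResult(
                peptide=p, candidate_antigens=winners, round1_score=score,
                round2_evalue=best_ev, status="not_significant"))
    return results


def confirmations_per_antigen(results: list[AutoreactivityResult]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in results:
        if r.status == "confirmed":
            counts[r.confirmed_antigen] = counts.get(r.confirmed_antigen, 0) + 1
    return counts


def results_to_frame(results: list[AutoreactivityResult]):
    import pandas as pd

    cols = ["peptide", "protein_accession", "start", "candidate_antigens",
            "confirmed_antigen", "round1_score", "round2_evalue", "status"]
    return pd.DataFrame([{
        "peptide": r.peptide.peptide,
        "protein_accession": r.peptide.protein_accession,
        "start": r.peptide.start,
        "candidate_antigens": ";".join(r.candidate_antigens),
        "confirmed_antigen": r.confirmed_antigen or "",
        "round1_score": r.round1_score,
        "round2_evalue": r.round2_evalue,
        "status": r.status,
    } for r in results], columns=cols)
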