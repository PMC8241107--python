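"""Peptide generation, MHC binding scoring and percentile-rank tier selection.

Trained MHC-binding predictors (the NetMHC consensus family behind IEDB's
TepiTool) are deliberately out of scope; scoring goes through the pluggable
:class:`BindingScorer` interface so real predictors can be plugged in.  The
shipped baseline is a per-allele position-specific scoring matrix (PSSM)
over a 9-mer binding core: class I 9-mers are scored directly, longer class
II peptides take the maximum over sliding core offsets.  Toy matrices are
drawn from a seeded random process, optionally with planted high-affinity
motifs so that rank-recovery behaviour can be exercised end to end.

Percentile ranks are computed within-protein (against that protein's own
peptides): within each (protein, allele) group of size N a peptide of
competition rank r gets percentile 100*r/N, and ``best_rank`` aggregates
alleles by minimum after exclusions.  This differs from TepiTool's global
background pool, which is not available; printed rank values from trained
predictors are therefore qualitative anchors only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .alignment import (ScoringScheme, compute_evalue, encode,
                        passes_mimicry_filter, smith_waterman)
from .io_formats import CANONICAL_AA, EpitopeRecord, PipelineConfig, ProteinRecord

logger = logging.getLogger(__name__)

CORE_LENGTH = 9


@dataclass
class PredictedPeptide:
    """A fixed-length peptide scored against one allele."""

    protein_accession: str
    start: int                  # 1-based position in the source protein
    peptide: str
    allele: str
    raw_score: float            # higher = stronger predicted binding
    mhc_class: str              # "I" or "II"
    percentile_rank: float = float("nan")   # lower = better, in (0, 100]
    best_rank: float = float("nan")         # min percentile over panel alleles

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1


class BindingScorer:
    """Interface contract: deterministic, total over supported alleles."""

    supported_alleles: list[str]

    def score(self, peptide: str, allele: str) -> float:  # pragma: no cover
        raise NotImplementedError


class PSSMScorer(BindingScorer):
    """Baseline per-allele PSSM scorer over a 9-mer core.

    ``matrices`` maps allele -> (9 x 21) array indexed by core position and
    residue (canonical alphabet order, final column = X scoring 0).
    """

    def __init__(self, matrices: dict[str, np.ndarray]):
        for allele, m in matrices.items():
            if m.shape != (CORE_LENGTH, len(CANONICAL_AA) + 1):
                raise ValueError(f"matrix for {allele} must be 9 x 21, got {m.shape}")
        self.matrices = matrices
        self.supported_alleles = list(matrices)

    @classmethod
    def random(cls, alleles: list[str], seed: int = 0,
               motifs: dict[str, str] | None = None,
               motif_strength: float = 5.0) -> "PSSMScorer":
        """Seeded random matrices, optionally boosting a planted 9-mer motif
        for specific alleles so peptides containing it rank first."""
        rng = np.random.default_rng(seed)
        matrices = {}
        for allele in alleles:
            m = rng.normal(0.0, 1.0, size=(CORE_LENGTH, len(CANONICAL_AA) + 1))
            m[:, -1] = 0.0  # ambiguous residue is neutral
            matrices[allele] = m
        for allele, motif in (motifs or {}).items():
            if allele not in matrices:
                raise KeyError(f"motif allele {allele!r} not in panel")
            if len(motif) != CORE_LENGTH:
                raise ValueError("planted motifs must be 9-mers")
            for pos, aa in enumerate(encode(motif)):
                matrices[allele][pos, aa] += motif_strength
        return cls(matrices)

    def score(self, peptide: str, allele: str) -> float:
        try:
            m = self.matrices[allele]
        except KeyError:
            raise KeyError(f"unsupported allele {allele!r}") from None
        idx = encode(peptide)
        if len(idx) < CORE_LENGTH:
            raise ValueError(f"peptide shorter than the {CORE_LENGTH}-mer core")
        return max(
            float(m[np.arange(CORE_LENGTH), idx[off:off + CORE_LENGTH]].sum())
            for off in range(len(idx) - CORE_LENGTH + 1)
        )


def save_pssm(matrix: np.ndarray, path) -> None:
    """Write a PSSM as plain text: 20 rows (canonical alphabet order) x core
    positions; the X column is dropped on output and restored as zeros."""
    np.savetxt(path, matrix[:, :len(CANONICAL_AA)].T, fmt="%.6f")


def load_pssm(path) -> np.ndarray:
    rows = np.loadtxt(path)
    if rows.shape != (len(CANONICAL_AA), CORE_LENGTH):
        raise ValueError(f"expected a 20 x {CORE_LENGTH} text matrix, got {rows.shape}")
    m = np.zeros((CORE_LENGTH, len(CANONICAL_AA) + 1))
    m[:, :len(CANONICAL_AA)] = rows.T
    return m


# ---------------------------------------------------------------------------
# peptide generation and scoring
# ---------------------------------------------------------------------------

def generate_peptides(protein: ProteinRecord, length: int,
                      overlap: int) -> list[tuple[int, str]]:
    """Overlapping fixed-length windows: starts 1, 1+step, ... with
    step = length - overlap, duplicate peptide strings removed (first kept).
    A protein shorter than ``length`` yields an empty list."""
    if overlap >= length:
        raise ValueError("overlap must be smaller than the peptide length")
    step = length - overlap
    seen: set[str] = set()
    out = []
    for start in range(1, len(protein) - length + 2, step):
        pep = protein.sequence[start - 1:start - 1 + length]
        if pep in seen:
            continue
        seen.add(pep)
        out.append((start, pep))
    return out


def score_panel(peptides: list[tuple[int, str]], panel: list[str],
                scorer: BindingScorer, protein_accession: str,
                mhc_class: str) -> list[PredictedPeptide]:
    """One PredictedPeptide per (peptide, allele)."""
    unsupported = [a for a in panel if a not in scorer.supported_alleles]
    if unsupported:
        raise KeyError(f"scorer does not support alleles: {unsupported}")
    return [
        PredictedPeptide(protein_accession=protein_accession, start=start,
                         peptide=pep, allele=allele,
                         raw_score=scorer.score(pep, allele),
                         mhc_class=mhc_class)
        for start, pep in peptides
        for allele in panel
    ]


def percentile_ranks(scored: list[PredictedPeptide]) -> list[PredictedPeptide]:
    """Percentile ranks within each (protein, allele) group.

    Competition ranking by descending raw score (ties share the smaller
    rank); percentile = 100*r/N.  ``best_rank`` is then the minimum
    percentile over that peptide's alleles.
    """
    groups: dict[tuple[str, str], list[PredictedPeptide]] = {}
    for p in scored:
        groups.setdefault((p.protein_accession, p.allele), []).append(p)
    ranked: list[PredictedPeptide] = []
    for members in groups.values():
        scores = sorted((m.raw_score for m in members), reverse=True)
        n = len(members)
        for m in members:
            # competition rank: 1 + number of strictly better scores
            r = 1 + sum(1 for s in scores if s > m.raw_score)
            ranked.append(replace(m, percentile_rank=100.0 * r / n))
    return _recompute_best_rank(ranked)


def _recompute_best_rank(predictions: list[PredictedPeptide]) -> list[PredictedPeptide]:
    best: dict[tuple[str, int, str], float] = {}
    for p in predictions:
        key = (p.protein_accession, p.start, p.peptide)
        cur = best.get(key)
        if cur is None or p.percentile_rank < cur:
            best[key] = p.percentile_rank
    return [replace(p, best_rank=best[(p.protein_accession, p.start, p.peptide)])
            for p in predictions]


def apply_allele_exclusions(predictions: list[PredictedPeptide],
                            excluded: list[str]) -> list[PredictedPeptide]:
    """Remove predictions for excluded alleles and recompute best_rank from
    the surviving alleles.  Excluded alleles absent from the panel warn."""
    present = {p.allele for p in predictions}
    for allele in excluded:
        if allele not in present:
            logger.warning("excluded allele %s not present in predictions", allele)
    keep = [p for p in predictions if p.allele not in set(excluded)]
    return _recompute_best_rank(keep)


def select_tier(predictions: list[PredictedPeptide],
                tier_pct: float) -> list[PredictedPeptide]:
    """Unique peptides with best_rank <= tier_pct, sorted by best_rank.

    Collapses the per-allele rows to one representative per (protein, start,
    peptide), keeping the allele that attains the best rank.
    """
    best: dict[tuple[str, int, str], PredictedPeptide] = {}
    for p in predictions:
        if p.best_rank > tier_pct:
            continue
        key = (p.protein_accession, p.start, p.peptide)
        cur = best.get(key)
        if cur is None or p.percentile_rank < cur.percentile_rank:
            best[key] = p
    return sorted(best.values(),
                  key=lambda p: (p.best_rank, p.protein_accession, p.start, p.allele))


def exclude_homologous_to_experimental(
        predictions: list[PredictedPeptide],
        experimental: list[EpitopeRecord],
        cfg: PipelineConfig | None = None,
        scheme: ScoringScheme | None = None) -> list[PredictedPeptide]:
    """Drop predicted peptides with substantial homology to the experimental
    pool, to avoid re-discovering the screen's own inputs.

    "Substantial homology" is operationalised as the composite mimicry
    filter (same thresholds as the proteome scan) applied to the optimal
    local alignment of each experimental epitope (query) against the
    predicted peptide (subject); the e-value database size is the total
    residue count of the candidate peptide set.  Removals are logged.
    """
    cfg = cfg or PipelineConfig()
    scheme = scheme or ScoringScheme()
    if not predictions or not experimental:
        return list(predictions)
    db_len = sum(len(p.peptide) for p in predictions)
    kept = []
    for p in predictions:
        homologous = False
        for epi in experimental:
            alns = smith_waterman(epi.sequence, p.peptide, scheme,
                                  query_id=epi.epitope_id, subject_id=p.peptide)
            if not alns:
                continue
            aln = alns[0]
            aln.evalue = compute_evalue(aln.score, len(epi.sequence), db_len, scheme)
            if passes_mimicry_filter(aln, cfg):
                homologous = True
                logger.info("prediction %s@%d homologous to experimental %s; removed",
                            p.protein_accession, p.start, epi.epitope_id)
                break
        if not homologous:
            kept.append(p)
    return kept


def predictions_to_frame(predictions: list[PredictedPeptide], cfg: PipelineConfig):
    """Prediction table with tier flags (top10/top2/top1/top0.5)."""
    import pandas as pd

    rows = []
    for p in predictions:
        rows.append({
            "protein_accession": p.protein_accession, "start": p.start,
            "peptide": p.peptide, "mhc_class": p.mhc_class, "allele": p.allele,
            "raw_score": p.raw_score, "percentile_rank": p.percentile_rank,
            "best_rank": p.best_rank,
            "top10": p.best_rank <= 10.0, "top2": p.best_rank <= 2.0,
            "top1": p.best_rank <= cfg.class2_highlight_pct,
            "top0.5": p.best_rank <= cfg.autoreact_tier_pct,
        })
    cols = ["protein_accession", "start", "peptide", "mhc_class", "allele",
            "raw_score", "percentile_rank", "best_rank", "top10", "top2",
            "top1", "top0.5"]
    return pd.DataFrame(rows, columns=cols)
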