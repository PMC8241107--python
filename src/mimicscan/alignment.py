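"""Local pairwise alignment with Karlin-Altschul statistics.

A self-contained Smith-Waterman engine (Gotoh affine-gap recursion,
numba-accelerated with a pure-Python fallback) replaces external BLASTp /
LALIGN calls at desk scale.  Significance is assessed with the
Karlin-Altschul expectation E = K * m * n * exp(-lambda * S) using the
standard gapped-BLOSUM62 constants lambda = 0.267, K = 0.041, gap open 11,
gap extend 1, with no finite-size edge correction.  Absolute e-values will
differ from BLAST's composition-adjusted values; thresholds are interpreted
against this statistic.

Conventions: coordinates are 1-based inclusive; percent identity uses the
alignment column count (including gap columns) as denominator; query cover
uses the full query length.  Traceback tie-breaking prefers diagonal over
up (gap in subject) over left (gap in query); among equal-score local
optima the alignment with the smallest (subject_start, query_start) wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import (CANONICAL_AA, EpitopeRecord, OrganismAnnotation,
                         PipelineConfig, ProteinRecord)

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
_X_INDEX = len(CANONICAL_AA)       # ambiguous residue, scores 0
_MASK_INDEX = _X_INDEX + 1         # masked residue for suboptimal search

# Karlin-Altschul constants for gapped BLOSUM62 (open 11 / extend 1)
GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041


def _blosum62_matrix() -> np.ndarray:
    """22x22 integer matrix over CANONICAL_AA + X + mask.

    X scores 0 against everything; the mask residue scores strongly
    negative so suboptimal search never crosses a masked region.
    """
    bl = substitution_matrices.load("BLOSUM62")
    n = _MASK_INDEX + 1
    m = np.zeros((n, n), dtype=np.int32)
    for a, i in _AA_INDEX.items():
        for b, j in _AA_INDEX.items():
            m[i, j] = int(bl[a, b])
    m[_MASK_INDEX, :] = -10_000
    m[:, _MASK_INDEX] = -10_000
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and e-value constants."""

    substitution_matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open_penalty: int = 11
    gap_extend_penalty: int = 1
    karlin_lambda: float = GAPPED_BLOSUM62_LAMBDA
    karlin_k: float = GAPPED_BLOSUM62_K

    def __post_init__(self) -> None:
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.gap_open_penalty < 0 or self.gap_extend_penalty < 0:
            raise ValueError("gap penalties must be non-negative")
        m = self.substitution_matrix
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")


@dataclass
class LocalAlignment:
    """A local alignment with BLAST-style metrics (1-based coordinates)."""

    query_id: str
    subject_id: str
    score: int
    evalue: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str
    identity_pct: float
    query_cover_pct: float
    gap_count: int


@dataclass
class MimicryHit:
    """A filter-passing epitope-vs-protein alignment joined to its organism."""

    alignment: LocalAlignment
    epitope_id: str
    antigen_id: str
    subject_accession: str
    organism: OrganismAnnotation | None = None


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(c, _X_INDEX) for c in seq),
                       dtype=np.int8, count=len(seq))


# ---------------------------------------------------------------------------
# DP kernel
# ---------------------------------------------------------------------------

def _sw_fill(q, s, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    """Fill Gotoh matrices. M: alignments ending in a match column;
    Ix: ending with a gap in the query (subject consumed);
    Iy: ending with a gap in the subject (query consumed)."""
    m = q.shape[0]
    n = s.shape[0]
    M = np.zeros((m + 1, n + 1), dtype=np.int32)
    Ix = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)
    Iy = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            if prev < 0:
                prev = 0
            M[i, j] = prev + sub[qi, s[j - 1]]
            a = M[i, j - 1] - gap_first
            b = Ix[i, j - 1] - gap_ext
            Ix[i, j] = a if a > b else b
            a = M[i - 1, j] - gap_first
            b = Iy[i - 1, j] - gap_ext
            Iy[i, j] = a if a > b else b
            if M[i, j] > best:
                best = M[i, j]
    return M, Ix, Iy, best


try:  # numba acceleration; pure-Python fallback keeps results identical
    from numba import njit

    _sw_fill_fast = njit(cache=True, fastmath=False)(_sw_fill)
except Exception:  # pragma: no cover
    _sw_fill_fast = _sw_fill


def _traceback(q, s, M, Ix, Iy, i, j, gap_first, gap_ext):
    """Deterministic traceback from M[i, j]; returns (qs, qe, ss, se, aq, as_).

    Preference order at every step: match column (M) over gap-in-subject
    (Iy, 'up') over gap-in-query (Ix, 'left').
    """
    aq: list[str] = []
    asub: list[str] = []
    state = "M"
    while True:
        if state == "M":
            aq.append(q[i - 1])
            asub.append(s[j - 1])
            prev = max(0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i -= 1
            j -= 1
            if prev == 0:
                break
            if prev == M[i, j]:
                state = "M"
            elif prev == Iy[i, j]:
                state = "Iy"
            else:
                state = "Ix"
        elif state == "Iy":  # gap in subject, consume query residue
            aq.append(q[i - 1])
            asub.append("-")
            if Iy[i, j] == M[i - 1, j] - gap_first:
                state = "M"
            i -= 1
        else:  # Ix: gap in query, consume subject residue
            aq.append("-")
            asub.append(s[j - 1])
            if Ix[i, j] == M[i, j - 1] - gap_first:
                state = "M"
            j -= 1
    return i + 1, j + 1, "".join(reversed(aq)), "".join(reversed(asub))


def _alignment_from_cell(query, subject, M, Ix, Iy, i, j, scheme,
                         query_id, subject_id):
    qs, ss, aq, asub = _traceback(query, subject, M, Ix, Iy, i, j,
                                  scheme.gap_open_penalty + scheme.gap_extend_penalty,
                                  scheme.gap_extend_penalty)
    cols = len(aq)
    ident = sum(1 for a, b in zip(aq, asub) if a == b and a != "-")
    gaps = sum(1 for a, b in zip(aq, asub) if a == "-" or b == "-")
    return LocalAlignment(
        query_id=query_id, subject_id=subject_id,
        score=int(M[i, j]), evalue=float("nan"),
        query_start=qs, query_end=i, subject_start=ss, subject_end=j,
        aligned_query=aq, aligned_subject=asub,
        identity_pct=100.0 * ident / cols,
        query_cover_pct=100.0 * (i - qs + 1) / len(query),
        gap_count=gaps,
    )


def smith_waterman(query: str, subject: str, scheme: ScoringScheme | None = None,
                   suboptimal_count: int = 0, query_id: str = "query",
                   subject_id: str = "subject") -> list[LocalAlignment]:
    """Optimal (and optionally suboptimal) local alignments of two sequences.

    The first element is an optimal local alignment; when
    ``suboptimal_count > 0`` up to that many further alignments are found by
    iteratively masking the subject interval of each reported alignment and
    re-aligning, in non-increasing score order.  Returns an empty list when
    no alignment scores above zero.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    q = encode(query)
    s = encode(subject)
    results: list[LocalAlignment] = []
    for _ in range(1 + suboptimal_count):
        aln = _best_alignment(query, q, subject, s, scheme, query_id, subject_id)
        if aln is None:
            break
        results.append(aln)
        s = s.copy()
        s[aln.subject_start - 1:aln.subject_end] = _MASK_INDEX
    return results


def _best_alignment(query, q, subject, s, scheme, query_id, subject_id):
    gap_first = scheme.gap_open_penalty + scheme.gap_extend_penalty
    M, Ix, Iy, best = _sw_fill_fast(q, s, scheme.substitution_matrix,
                                    gap_first, scheme.gap_extend_penalty)
    if best <= 0:
        return None
    cells = np.argwhere(M == best)
    candidates = [
        _alignment_from_cell(query, subject, M, Ix, Iy, int(i), int(j),
                             scheme, query_id, subject_id)
        for i, j in cells
    ]
    candidates.sort(key=lambda a: (a.subject_start, a.query_start,
                                   a.subject_end, a.query_end))
    return candidates[0]


# ---------------------------------------------------------------------------
# statistics and filtering
# ---------------------------------------------------------------------------

def compute_evalue(score: int, query_len: int, db_len: int,
                   scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expectation K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    scheme = scheme or ScoringScheme()
    return scheme.karlin_k * query_len * db_len * math.exp(-scheme.karlin_lambda * score)


def passes_mimicry_filter(aln: LocalAlignment, cfg: PipelineConfig) -> bool:
    """The composite homology filter: identity >= 80%, query cover >= 80%,
    no gaps, e-value < 1 (identity/cover boundaries inclusive, e-value
    strict)."""
    return (aln.identity_pct >= cfg.identity_min_pct
            and aln.query_cover_pct >= cfg.cover_min_pct
            and aln.gap_count <= cfg.max_gaps
            and aln.evalue < cfg.evalue_max)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_epitopes(epitopes: list[EpitopeRecord], proteins: list[ProteinRecord],
                  cfg: PipelineConfig | None = None,
                  scheme: ScoringScheme | None = None,
                  annotations: list[OrganismAnnotation] | None = None,
                  ) -> list[MimicryHit]:
    """Align every epitope against every protein and keep filter-passing hits.

    E-values use n = total residue count of the protein collection (the
    searched database size).  Output is sorted by (epitope_id, e-value).
    When ``annotations`` is given, hits are joined to their organism
    annotation by the protein's organism name; unannotated organisms leave
    the field None.
    """
    if not proteins:
        raise ValueError("no proteins to scan")
    cfg = cfg or PipelineConfig()
    scheme = scheme or ScoringScheme()
    db_len = sum(len(p) for p in proteins)
    ann_by_name = {a.organism_name: a for a in (annotations or [])}
    encoded = [(p, encode(p.sequence)) for p in proteins]
    hits: list[MimicryHit] = []
    for epi in epitopes:
        q = encode(epi.sequence)
        for prot, s in encoded:
            aln = _best_alignment(epi.sequence, q, prot.sequence, s, scheme,
                                  epi.epitope_id, prot.accession)
            if aln is None:
                continue
            aln.evalue = compute_evalue(aln.score, len(epi.sequence), db_len, scheme)
            if passes_mimicry_filter(aln, cfg):
                hits.append(MimicryHit(
                    alignment=aln, epitope_id=epi.epitope_id,
                    antigen_id=epi.antigen_id or "",
                    subject_accession=prot.accession,
                    organism=ann_by_name.get(prot.organism_name),
                ))
    hits.sort(key=lambda h: (h.epitope_id, h.alignment.evalue, h.subject_accession))
    return hits


def best_protein_per_organism(hits: list[MimicryHit]) -> dict[str, str]:
    """For each organism, the accession whose best hit e-value is lowest.

    Ties on the minimum e-value are broken by lexicographic accession order
    (logged).  Hits lacking organism annotation are grouped under their
    protein's accession-less marker only if named; unannotated hits are
    skipped with a warning.
    """
    best: dict[str, tuple[float, str]] = {}
    ties: set[str] = set()
    for h in hits:
        if h.organism is None:
            logger.warning("hit on %s has no organism annotation; skipped",
                           h.subject_accession)
            continue
        org = h.organism.organism_name
        key = (h.alignment.evalue, h.subject_accession)
        if org not in best:
            best[org] = key
            continue
        cur = best[org]
        if key[0] < cur[0]:
            best[org] = key
        elif key[0] == cur[0] and key[1] != cur[1]:
            ties.add(org)
            if key[1] < cur[1]:
                best[org] = key
    for org in sorted(ties):
        logger.warning("organism %s: e-value tie broken by accession order", org)
    return {org: acc for org, (ev, acc) in best.items()}


def hits_to_frame(hits: list[MimicryHit]):
    """Hit table in BLAST outfmt-6 style plus organism annotation columns."""
    import pandas as pd

    rows = []
    for h in hits:
        a = h.alignment
        rows.append({
            "epitope_id": h.epitope_id,
            "antigen_id": h.antigen_id,
            "subject_accession": h.subject_accession,
            "organism": h.organism.organism_name if h.organism else "",
            "group": h.organism.group if h.organism else "",
            "identity_pct": round(a.identity_pct, 2),
            "query_cover_pct": round(a.query_cover_pct, 2),
            "gap_count": a.gap_count,
            "evalue": a.evalue,
            "q_start": a.query_start, "q_end": a.query_end,
            "s_start": a.subject_start, "s_end": a.subject_end,
        })
    cols = ["epitope_id", "antigen_id", "subject_accession", "organism",
            "group", "identity_pct", "query_cover_pct", "gap_count",
            "evalue", "q_start", "q_end", "s_start", "s_end"]
    return pd.DataFrame(rows, columns=cols)
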