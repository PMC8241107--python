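"""Identity-threshold epitope clustering with representative selection, and
information-content sequence-logo matrices.

Clustering follows a cluster-break strategy: peptides are joined into a
graph wherever their best ungapped-offset identity reaches the threshold,
connected components are taken, each component elects as representative the
member to which the largest number of members meet the threshold directly
(ties by highest mean identity, then lexicographic order), and members
failing the direct-to-representative threshold break out and are
re-clustered recursively.  The result is a partition in which every member
meets the identity threshold against its cluster's representative.  This is
a documented approximation of the IEDB cluster-break tool, whose internals
are unpublished.

Pairwise identity between two peptides is the maximum over ungapped
relative offsets of 100 * matches / overlap-columns, requiring a mutual
overlap of at least half the shorter peptide; epitopes are short and
near-fixed-length, so gapless comparison is appropriate.

Logo matrices use per-column information content against a uniform 1/20
background: IC_j = log2(20) + sum_a p_a log2 p_a (bits), with each
residue's stacked contribution p_a * IC_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import ScoringScheme, compute_evalue, smith_waterman
from .io_formats import CANONICAL_AA, ProteinRecord

LOG2_20 = math.log2(20.0)


def pairwise_identity(a: str, b: str, min_overlap_frac: float = 0.5) -> float:
    """Best ungapped-offset percent identity between two peptides.

    Maximum over relative offsets of 100 * matches / overlap, considering
    only offsets whose overlap is at least ``min_overlap_frac`` of the
    shorter peptide.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    min_overlap = max(1, math.ceil(min(len(a), len(b)) * min_overlap_frac))
    best = 0.0
    # offset = position of b[0] relative to a[0]
    for offset in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - offset])
        best = max(best, 100.0 * matches / overlap)
    return best


def _best_offset(rep: str, member: str) -> int:
    """Offset of ``member`` relative to ``rep`` maximizing identity
    (ties: smallest offset)."""
    min_overlap = max(1, math.ceil(min(len(rep), len(member)) * 0.5))
    best = (-1.0, 0)
    for offset in range(-(len(member) - min_overlap), len(rep) - min_overlap + 1):
        lo = max(0, offset)
        hi = min(len(rep), offset + len(member))
        if hi - lo < min_overlap:
            continue
        matches = sum(1 for i in range(lo, hi) if rep[i] == member[i - offset])
        ident = 100.0 * matches / (hi - lo)
        if ident > best[0]:
            best = (ident, offset)
    return best[1]


@dataclass
class LogoMatrix:
    """Per-position information-content contributions (bits, >= 0)."""

    n_positions: int
    values: np.ndarray        # (n_positions, 20), residue contributions p_a * IC
    column_ic: np.ndarray     # (n_positions,), total IC in [0, log2 20]


@dataclass
class EpitopeCluster:
    cluster_id: int
    members: list[str]
    representative: str
    member_alignment: dict[str, int] = field(default_factory=dict)  # gapless offsets
    consensus: str = ""
    logo: LogoMatrix | None = None


def cluster_break(peptides: list[str], identity_threshold_pct: float = 70.0,
                  ) -> list[EpitopeCluster]:
    """Partition peptides into identity clusters with clear representatives.

    Deterministic under input permutation: peptides are canonically sorted
    before clustering.  Input must be deduplicated.
    """
    if len(set(peptides)) != len(peptides):
        raise ValueError("peptides must be deduplicated before clustering")
    ordered = sorted(peptides)
    clusters: list[tuple[str, list[str]]] = []
    _cluster_recursive(ordered, identity_threshold_pct, clusters)
    clusters.sort(key=lambda rm: (-len(rm[1]), rm[1]))
    out = []
    for cid, (rep, members) in enumerate(clusters, start=1):
        offsets = {m: _best_offset(rep, m) for m in members}
        cluster = EpitopeCluster(cluster_id=cid, members=members,
                                 representative=rep, member_alignment=offsets)
        cluster.consensus = _consensus(cluster)
        cluster.logo = build_logo(cluster)
        out.append(cluster)
    return out


def _cluster_recursive(peptides: list[str], threshold: float,
                       acc: list[tuple[str, list[str]]]) -> None:
    if not peptides:
        return
    g = nx.Graph()
    g.add_nodes_from(peptides)
    for i, a in enumerate(peptides):
        for b in peptides[i + 1:]:
            if pairwise_identity(a, b) >= threshold:
                g.add_edge(a, b)
    for comp in sorted(nx.connected_components(g), key=min):
        members = sorted(comp)
        if len(members) == 1:
            acc.append((members[0], members))
            continue
        rep = _elect_representative(members, threshold)
        keep = [m for m in members
                if m == rep or pairwise_identity(rep, m) >= threshold]
        breakout = [m for m in members if m not in keep]
        acc.append((rep, keep))
        _cluster_recursive(breakout, threshold, acc)


def _elect_representative(members: list[str], threshold: float) -> str:
    """Member maximizing direct-threshold coverage; ties by highest mean
    identity, then lexicographic order."""
    if len(members) == 1:
        return members[0]
    best = None
    for cand in sorted(members):
        idents = [pairwise_identity(cand, m) for m in members if m != cand]
        coverage = sum(1 for x in idents if x >= threshold)
        key = (-coverage, -float(np.mean(idents)), cand)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


def filter_clusters(clusters: list[EpitopeCluster],
                    min_size: int) -> list[EpitopeCluster]:
    """Clusters with at least ``min_size`` members, order preserved."""
    return [c for c in clusters if len(c.members) >= min_size]


def _column_span(cluster: EpitopeCluster) -> tuple[int, int]:
    lo = min(cluster.member_alignment[m] for m in cluster.members)
    hi = max(cluster.member_alignment[m] + len(m) for m in cluster.members)
    return lo, hi


def _column_frequencies(cluster: EpitopeCluster) -> np.ndarray:
    """(n_positions, 20) residue frequencies from the gapless offsets."""
    lo, hi = _column_span(cluster)
    counts = np.zeros((hi - lo, len(CANONICAL_AA)))
    aa_index = {aa: k for k, aa in enumerate(CANONICAL_AA)}
    for m in cluster.members:
        off = cluster.member_alignment[m] - lo
        for i, ch in enumerate(m):
            if ch in aa_index:
                counts[off + i, aa_index[ch]] += 1
    cover = counts.sum(axis=1)
    if (cover == 0).any():
        raise ValueError("logo column covered by no member")
    return counts / cover[:, None]


def build_logo(cluster: EpitopeCluster) -> LogoMatrix:
    """Information-content logo matrix from the cluster's aligned members."""
    freqs = _column_frequencies(cluster)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = LOG2_20 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, LOG2_20)
    return LogoMatrix(n_positions=freqs.shape[0], values=freqs * ic[:, None],
                      column_ic=ic)


def _consensus(cluster: EpitopeCluster) -> str:
    """Majority residue per column (ties alphabetical)."""
    freqs = _column_frequencies(cluster)
    return "".join(CANONICAL_AA[int(k)] for k in freqs.argmax(axis=1))


def map_clusters_to_antigen(clusters: list[EpitopeCluster],
                            antigen: ProteinRecord,
                            scheme: ScoringScheme | None = None,
                            evalue_max: float = 1e-3,
                            ) -> list[tuple[int, int | None, int | None]]:
    """Locate each cluster representative on an antigen sequence.

    Returns (cluster_id, antigen_start, antigen_end) per cluster, with None
    coordinates for clusters whose representative alignment misses the
    significance bound (flagged unmapped).
    """
    scheme = scheme or ScoringScheme()
    out = []
    for c in clusters:
        alns = smith_waterman(c.representative, antigen.sequence, scheme,
                              query_id=f"cluster_{c.cluster_id}",
                              subject_id=antigen.accession)
        if not alns:
            out.append((c.cluster_id, None, None))
            continue
        aln = alns[0]
        ev = compute_evalue(aln.score, len(c.representative),
                            len(antigen.sequence), scheme)
        if ev >= evalue_max:
            out.append((c.cluster_id, None, None))
        else:
            out.append((c.cluster_id, aln.subject_start, aln.subject_end))
    return out


def clusters_to_frame(clusters: list[EpitopeCluster]):
    import pandas as pd

    rows = []
    for c in clusters:
        for m in c.members:
            rows.append({
                "cluster_id": c.cluster_id, "member": m,
                "offset": c.member_alignment[m],
                "is_representative": m == c.representative,
                "consensus": c.consensus,
            })
    return pd.DataFrame(rows)


def logo_to_frame(logo: LogoMatrix):
    import pandas as pd

    df = pd.DataFrame(logo.values, columns=list(CANONICAL_AA))
    df.insert(0, "position", np.arange(1, logo.n_positions + 1))
    df["column_ic"] = logo.column_ic
    return df


def render_logo(logo: LogoMatrix, path) -> None:
    """Minimal stacked-bar rendering of a logo matrix (PNG/PDF via matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, logo.n_positions * 0.4), 3))
    x = np.arange(1, logo.n_positions + 1)
    bottom = np.zeros(logo.n_positions)
    for k, aa in enumerate(CANONICAL_AA):
        h = logo.values[:, k]
        if h.max() <= 0:
            continue
        ax.bar(x, h, bottom=bottom, width=0.8, label=aa)
        bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("information (bits)")
    ax.set_ylim(0, LOG2_20)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
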