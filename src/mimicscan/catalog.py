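"""Curation of the experimental epitope catalog.

Covers the bookkeeping that precedes the homology scan: collapsing
post-translational-modification duplicates to unique sequences, excluding
epitopes that cannot be tied to a source autoantigen, applying antigen
re-assignments (e.g. folding collagen-precursor variants into a single
collagen antigen), and summarising filter-passing hits per antigen.
"""

from __future__ import annotations

import logging

import pandas as pd

from .alignment import MimicryHit
from .io_formats import EpitopeRecord

logger = logging.getLogger(__name__)


def deduplicate_epitopes(records: list[EpitopeRecord]) -> list[EpitopeRecord]:
    """One record per unique sequence; modification text is ignored for
    identity and the first occurrence is kept.  Order stable, idempotent."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.sequence in seen:
            continue
        seen.add(r.sequence)
        out.append(r)
    return out


def apply_exclusions(records: list[EpitopeRecord]) -> list[EpitopeRecord]:
    """Drop records lacking an antigen assignment, logging each removal."""
    out = []
    for r in records:
        if r.antigen_id is None:
            logger.info("excluding epitope %s: no antigen assignment", r.epitope_id)
            continue
        out.append(r)
    return out


def assign_antigens(records: list[EpitopeRecord],
                    reassignment: dict[str, str] | None = None,
                    ) -> dict[str, list[str]]:
    """Group epitope ids by antigen, applying re-assignment overrides.

    ``reassignment`` maps epitope_id -> new antigen_id and must reference
    only known epitope ids.  Every record ends up under exactly one antigen.
    """
    reassignment = reassignment or {}
    known = {r.epitope_id for r in records}
    unknown = set(reassignment) - known
    if unknown:
        raise KeyError(f"reassignment references unknown epitope ids: {sorted(unknown)}")
    groups: dict[str, list[str]] = {}
    for r in records:
        antigen = reassignment.get(r.epitope_id, r.antigen_id)
        if antigen is None:
            raise ValueError(f"epitope {r.epitope_id} has no antigen (run apply_exclusions first)")
        groups.setdefault(antigen, []).append(r.epitope_id)
    logger.info("catalog covers %d distinct antigens", len(groups))
    return groups


def read_reassignment_table(path) -> dict[str, str]:
    """Load an epitope -> antigen re-assignment mapping (TSV with columns
    epitope_id, new_antigen_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("epitope_id", "new_antigen_id"):
        if col not in df.columns:
            raise ValueError(f"reassignment table missing column {col!r}")
    return dict(zip(df["epitope_id"], df["new_antigen_id"]))


def hit_distribution(hits: list[MimicryHit],
                     catalog: dict[str, list[str]]) -> pd.DataFrame:
    """Hit counts per (antigen, organism group), with hits-per-epitope.

    Every hit must reference a cataloged epitope; totals are conserved
    (sum of hit_count over rows equals the number of input hits).
    """
    epitope_to_antigen: dict[str, str] = {}
    for antigen, epitope_ids in catalog.items():
        for eid in epitope_ids:
            epitope_to_antigen[eid] = antigen
    rows = []
    for h in hits:
        if h.epitope_id not in epitope_to_antigen:
            raise KeyError(f"hit references uncataloged epitope {h.epitope_id!r}")
        rows.append({
            "antigen_id": epitope_to_antigen[h.epitope_id],
            "group": h.organism.group if h.organism else "unannotated",
        })
    if not rows:
        return pd.DataFrame(columns=["antigen_id", "group", "hit_count",
                                     "n_epitopes", "hits_per_epitope"])
    df = (pd.DataFrame(rows).groupby(["antigen_id", "group"])
          .size().rename("hit_count").reset_index())
    df["n_epitopes"] = df["antigen_id"].map(lambda a: len(catalog[a]))
    df["hits_per_epitope"] = df["hit_count"] / df["n_epitopes"]
    return df
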