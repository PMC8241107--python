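"""Synthetic study generator: antigen panels, epitope pools, and microbial
proteomes with mimics planted at controlled divergence.

The generator emulates the screen's three inputs — an autoantigen panel, an
experimentally-derived epitope table excised from those antigens, and a
microbial proteome with organism annotations — plus a ground-truth planting
table so every pipeline stage can be scored without downloads.  Planted
mimics are copies of epitopes mutated at exactly ``d`` positions
(substitutions only, never back to the original residue, positions drawn
uniformly), written over non-overlapping windows of randomly chosen
proteins; a full-length ungapped match to a plant with d mutations on an
L-mer therefore has identity exactly 100*(L-d)/L.

Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (CANONICAL_AA, EpitopeRecord, OrganismAnnotation,
                         ProteinRecord, write_annotation_table,
                         write_epitope_table, write_fasta)

logger = logging.getLogger(__name__)

#: Uniform amino-acid background.
UNIFORM_AA = {aa: 1.0 / 20.0 for aa in CANONICAL_AA}

#: Robinson & Robinson-style average amino-acid composition of proteins
#: (normalized below so the frequencies sum to exactly 1).
ROBINSON_AA = {
    "A": 0.0780, "C": 0.0192, "D": 0.0536, "E": 0.0629, "F": 0.0405,
    "G": 0.0735, "H": 0.0227, "I": 0.0514, "K": 0.0577, "L": 0.0932,
    "M": 0.0233, "N": 0.0450, "P": 0.0518, "Q": 0.0428, "R": 0.0513,
    "S": 0.0712, "T": 0.0583, "V": 0.0645, "W": 0.0131, "Y": 0.0322,
}
ROBINSON_AA = {aa: f / sum(ROBINSON_AA.values()) for aa, f in ROBINSON_AA.items()}


@dataclass
class PlantingRecord:
    """Ground truth for one planted mimic."""

    epitope_id: str
    source_antigen_id: str
    target_accession: str
    insert_start: int          # 1-based
    n_mutations: int
    planted_sequence: str


@dataclass
class SyntheticStudy:
    antigens: list[ProteinRecord]
    epitopes: list[EpitopeRecord]
    proteome: list[ProteinRecord]
    annotations: list[OrganismAnnotation]
    truth: list[PlantingRecord]
    seed: int


@dataclass
class StudyParams:
    """Default study conditions.

    The defaults mirror the screened study's scale where it matters for the
    statistics (37 antigens of 200-700 residues, 15-mer class II epitopes)
    while keeping the proteome at ~10^5 residues so a full scan runs in
    minutes on one CPU.  Five mimics are planted at each divergence level
    d = 0..4 to probe both sides of the 3-mismatch filter boundary.
    """

    n_antigens: int = 37
    antigen_length_range: tuple[int, int] = (200, 700)
    epitopes_per_antigen: int = 2
    epitope_length: int = 15
    n_proteins: int = 300
    protein_length_range: tuple[int, int] = (280, 400)
    n_organisms: int = 30
    group_weights: dict = field(default_factory=lambda: {
        "Bacteria": 0.5, "Fungi": 0.3, "Viruses": 0.2})
    host_status_weights: dict = field(default_factory=lambda: {
        "pathogen": 0.3, "commensal": 0.3, "putative": 0.2,
        "non_human": 0.15, "unknown": 0.05})
    literature_weights: dict = field(default_factory=lambda: {
        "PubMed": 0.3, "NoPubMed": 0.6, "unassessed": 0.1})
    plants_per_divergence: dict = field(default_factory=lambda: {
        0: 5, 1: 5, 2: 5, 3: 5, 4: 5})
    aa_background: dict = field(default_factory=lambda: dict(UNIFORM_AA))


def _random_sequence(rng: np.random.Generator, length: int,
                     background: dict[str, float]) -> str:
    letters = list(background)
    probs = np.array([background[a] for a in letters], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("amino-acid background frequencies must sum to 1")
    return "".join(rng.choice(letters, size=length, p=probs))


def generate_antigen_panel(n_antigens: int, length_range: tuple[int, int],
                           aa_background: dict[str, float] | None = None,
                           seed: int = 0) -> list[ProteinRecord]:
    """Random autoantigen panel, deterministic given seed."""
    rng = np.random.default_rng(seed)
    background = aa_background or UNIFORM_AA
    lo, hi = length_range
    panel = []
    for k in range(1, n_antigens + 1):
        length = int(rng.integers(lo, hi + 1))
        panel.append(ProteinRecord(
            accession=f"Antigen_{k}", description=f"synthetic autoantigen {k}",
            organism_name="Homo sapiens",
            sequence=_random_sequence(rng, length, background)))
    return panel


def excise_epitopes(antigens: list[ProteinRecord], n_per_antigen: int,
                    length: int, seed: int = 0) -> list[EpitopeRecord]:
    """Cut exact-substring epitopes from each antigen at random positions."""
    rng = np.random.default_rng(seed)
    out = []
    eid = 0
    for ag in antigens:
        if len(ag) < length:
            raise ValueError(f"antigen {ag.accession} shorter than epitope length")
        for _ in range(n_per_antigen):
            eid += 1
            start = int(rng.integers(0, len(ag) - length + 1))
            out.append(EpitopeRecord(
                epitope_id=f"Epitope {eid}",
                sequence=ag.sequence[start:start + length],
                antigen_id=ag.accession, provenance="experimental"))
    return out


def _mutate(rng: np.random.Generator, seq: str, n_mutations: int) -> str:
    """Substitute exactly n_mutations positions, never to the original
    residue; positions drawn uniformly without replacement."""
    if n_mutations > len(seq):
        raise ValueError("more mutations than positions")
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in CANONICAL_AA if a != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def plant_mimics(proteome: list[ProteinRecord], epitopes: list[EpitopeRecord],
                 n_mutations_per_plant, plant_rate: float = 1.0,
                 seed: int = 0) -> tuple[list[ProteinRecord], list[PlantingRecord]]:
    """Plant mutated epitope copies over non-overlapping proteome windows.

    ``n_mutations_per_plant`` is either a categorical distribution
    {d: weight} — each epitope is then planted with probability
    ``plant_rate`` and its divergence drawn from the distribution — or an
    explicit sequence of divergence values, one plant each, paired with
    epitopes cycled in randomised order.

    Returns (modified proteome, truth records).  A plant with no available
    window is skipped with a warning, never an error.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_mutations_per_plant, dict):
        ds = sorted(n_mutations_per_plant)
        weights = np.array([n_mutations_per_plant[d] for d in ds], dtype=float)
        weights = weights / weights.sum()
        plan = [(e, int(rng.choice(ds, p=weights)))
                for e in epitopes if rng.random() < plant_rate]
    else:
        order = list(rng.permutation(len(epitopes)))
        plan = [(epitopes[order[i % len(epitopes)]], int(d))
                for i, d in enumerate(n_mutations_per_plant)]

    sequences = {p.accession: list(p.sequence) for p in proteome}
    occupied: dict[str, list[tuple[int, int]]] = {p.accession: [] for p in proteome}
    accessions = [p.accession for p in proteome]
    truth: list[PlantingRecord] = []
    for epi, d in plan:
        L = len(epi.sequence)
        placed = False
        for _ in range(200):  # rejection sampling over random windows
            acc = accessions[int(rng.integers(0, len(accessions)))]
            seq = sequences[acc]
            if len(seq) < L:
                continue
            start = int(rng.integers(0, len(seq) - L + 1))
            if any(start < e and s < start + L for s, e in occupied[acc]):
                continue
            planted = _mutate(rng, epi.sequence, d)
            seq[start:start + L] = list(planted)
            occupied[acc].append((start, start + L))
            truth.append(PlantingRecord(
                epitope_id=epi.epitope_id, source_antigen_id=epi.antigen_id or "",
                target_accession=acc, insert_start=start + 1,
                n_mutations=d, planted_sequence=planted))
            placed = True
            break
        if not placed:
            logger.warning("no free window for a plant of %s; skipped", epi.epitope_id)
    new_proteome = [ProteinRecord(p.accession, p.description, p.organism_name,
                                  "".join(sequences[p.accession]))
                    for p in proteome]
    return new_proteome, truth


def generate_proteome(n_proteins: int, length_range: tuple[int, int],
                      n_organisms: int, group_weights: dict[str, float],
                      host_status_weights: dict[str, float],
                      literature_weights: dict[str, float],
                      aa_background: dict[str, float] | None = None,
                      seed: int = 0,
                      ) -> tuple[list[ProteinRecord], list[OrganismAnnotation]]:
    """Random background proteome with organism annotations."""
    rng = np.random.default_rng(seed)
    background = aa_background or UNIFORM_AA

    def _draw(weights: dict[str, float]) -> str:
        keys = list(weights)
        p = np.array([weights[k] for k in keys], dtype=float)
        return str(rng.choice(keys, p=p / p.sum()))

    annotations = [
        OrganismAnnotation(organism_name=f"Org_{k:03d}", group=_draw(group_weights),
                           host_status=_draw(host_status_weights),
                           literature_flag=_draw(literature_weights))
        for k in range(1, n_organisms + 1)
    ]
    lo, hi = length_range
    proteome = []
    for k in range(1, n_proteins + 1):
        org = annotations[int(rng.integers(0, n_organisms))]
        length = int(rng.integers(lo, hi + 1))
        proteome.append(ProteinRecord(
            accession=f"PROT_{k:05d}",
            description=f"synthetic protein from {org.organism_name}",
            organism_name=org.organism_name,
            sequence=_random_sequence(rng, length, background)))
    return proteome, annotations


def generate_study(params: StudyParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Compose antigens, epitopes, annotated proteome and planted mimics."""
    params = params or StudyParams()
    root = np.random.SeedSequence(seed)
    s_ag, s_epi, s_prot, s_plant = (int(c.generate_state(1)[0] % 2**31)
                                    for c in root.spawn(4))
    antigens = generate_antigen_panel(params.n_antigens, params.antigen_length_range,
                                      params.aa_background, seed=s_ag)
    epitopes = excise_epitopes(antigens, params.epitopes_per_antigen,
                               params.epitope_length, seed=s_epi)
    proteome, annotations = generate_proteome(
        params.n_proteins, params.protein_length_range, params.n_organisms,
        params.group_weights, params.host_status_weights,
        params.literature_weights, params.aa_background, seed=s_prot)
    divergences = [d for d, n in sorted(params.plants_per_divergence.items())
                   for _ in range(n)]
    proteome, truth = plant_mimics(proteome, epitopes, divergences, seed=s_plant)
    return SyntheticStudy(antigens=antigens, epitopes=epitopes, proteome=proteome,
                          annotations=annotations, truth=truth, seed=seed)


def truth_to_frame(truth: list[PlantingRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth])


def write_study(study: SyntheticStudy, outdir, params: StudyParams | None = None) -> None:
    """Emit antigens.fasta, epitopes.tsv, proteome.fasta, annotations.tsv,
    truth.tsv and study.yaml into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.antigens, outdir / "antigens.fasta")
    write_epitope_table(study.epitopes, outdir / "epitopes.tsv")
    write_fasta(study.proteome, outdir / "proteome.fasta")
    write_annotation_table(study.annotations, outdir / "annotations.tsv")
    truth_to_frame(study.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = {"seed": study.seed}
    if params is not None:
        meta["params"] = asdict(params)
    with open(outdir / "study.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ground-truth scoring
# ---------------------------------------------------------------------------

def scan_recovery(truth: list[PlantingRecord], hits) -> pd.DataFrame:
    """Per-divergence recovery of planted mimics by the homology scan.

    A plant is recovered when some filter-passing hit for the same epitope
    on the same target protein overlaps the planted window.  Returns a table
    with columns n_mutations, n_planted, n_recovered, sensitivity.
    """
    hit_index: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        a = h.alignment
        hit_index.setdefault((h.epitope_id, h.subject_accession), []).append(
            (a.subject_start, a.subject_end))
    rows: dict[int, list[int]] = {}
    for t in truth:
        end = t.insert_start + len(t.planted_sequence) - 1
        spans = hit_index.get((t.epitope_id, t.target_accession), [])
        recovered = any(s <= end and t.insert_start <= e for s, e in spans)
        rows.setdefault(t.n_mutations, [0, 0])
        rows[t.n_mutations][0] += 1
        rows[t.n_mutations][1] += int(recovered)
    return pd.DataFrame([
        {"n_mutations": d, "n_planted": n, "n_recovered": r,
         "sensitivity": r / n}
        for d, (n, r) in sorted(rows.items())
    ])


# ---------------------------------------------------------------------------
# IEDB-style catalog emulation (synthetic stand-in for the S1/S2 exports)
# ---------------------------------------------------------------------------

#: Epitope ids re-assigned from collagen alpha-1(II) precursor entries to
#: the single collagen antigen (Antigen 10) during catalog curation.
COLLAGEN_REASSIGNED_IDS = [14, 22, 25, 43, 47, 53, 54, 55, 56, 57, 58, 59,
                           63, 64, 65, 66, 75, 194, 212, 233]

collagen_reassignment = {f"Epitope {i}": "Antigen_10" for i in COLLAGEN_REASSIGNED_IDS}

_N_RAW_ROWS = 234          # raw table rows (one per IEDB entry)
_N_UNIQUE = 206            # after collapsing PTM duplicates
_ANTIGENLESS_ID = 28       # the one unique epitope without an antigen
_N_ANTIGENS = 37
_ANTIGEN1_EPITOPES = 42


def synthetic_iedb_catalog(seed: int = 0,
                           ) -> tuple[list[EpitopeRecord], list[ProteinRecord],
                                      dict[str, str]]:
    """A synthetic stand-in for a curated rheumatoid-arthritis epitope export.

    The real supplementary tables are not redistributable, so this generator
    reproduces their bookkeeping structure exactly on synthetic sequences:
    234 raw rows of which 28 are PTM-duplicate rows of earlier entries, 206
    unique sequences, one unique epitope (id 28) without an antigen
    assignment, 42 epitopes on Antigen 1, 20 collagen-precursor epitopes
    re-assigned to Antigen 10, and 37 distinct antigens after
    re-assignment.

    Returns (raw 234-row record list, 37-antigen panel, reassignment map).
    """
    rng = np.random.default_rng(seed)
    antigens = generate_antigen_panel(_N_ANTIGENS, (200, 700),
                                      seed=int(rng.integers(0, 2**31)))
    by_acc = {a.accession: a for a in antigens}

    n_dups = _N_RAW_ROWS - _N_UNIQUE
    reassigned = set(COLLAGEN_REASSIGNED_IDS)
    # duplicate rows must be later-id copies of earlier unique rows and must
    # not collide with the re-assignment list or the antigen-less epitope
    candidates = [i for i in range(100, _N_RAW_ROWS + 1)
                  if i not in reassigned and i != _ANTIGENLESS_ID]
    dup_ids = set(int(i) for i in rng.choice(candidates, size=n_dups, replace=False))
    unique_ids = [i for i in range(1, _N_RAW_ROWS + 1) if i not in dup_ids]
    assert len(unique_ids) == _N_UNIQUE

    # antigen assignment over the 205 antigen-assigned unique epitopes:
    # 42 on Antigen 1, the 20 collagen ids on two precursor labels (sequences
    # cut from Antigen 10), the remaining 143 spread over Antigens 2-37
    # (except 10, whose catalog entries all arrive via the re-assignment)
    assignable = [i for i in unique_ids
                  if i != _ANTIGENLESS_ID and i not in reassigned]
    rng.shuffle(assignable)
    assignment: dict[int, str] = {}
    for i in assignable[:_ANTIGEN1_EPITOPES]:
        assignment[i] = "Antigen_1"
    others = [f"Antigen_{k}" for k in range(2, _N_ANTIGENS + 1) if k != 10]
    for j, i in enumerate(assignable[_ANTIGEN1_EPITOPES:]):
        assignment[i] = others[j % len(others)]
    for j, i in enumerate(sorted(reassigned)):
        assignment[i] = f"Antigen_10_precursor_{1 + j % 2}"

    def _excise(antigen_acc: str, length: int) -> str:
        src = by_acc.get(antigen_acc, by_acc["Antigen_10"])  # precursors share collagen
        start = int(rng.integers(0, len(src) - length + 1))
        return src.sequence[start:start + length]

    sequences: dict[int, str] = {}
    seen: set[str] = set()
    for i in unique_ids:
        length = int(rng.integers(12, 21))
        antigen = assignment.get(i, "Antigen_1" if i == _ANTIGENLESS_ID else None)
        for _ in range(50):
            seq = _excise(antigen, length)
            if seq not in seen:
                break
        seen.add(seq)
        sequences[i] = seq

    mods = ["citrullination", "carbamylation", "deamidation", "none"]
    records: list[EpitopeRecord] = []
    dup_sources = sorted(sequences)
    for i in range(1, _N_RAW_ROWS + 1):
        if i in dup_ids:
            src = int(rng.choice([j for j in dup_sources if j < i]))
            records.append(EpitopeRecord(
                epitope_id=f"Epitope {i}", sequence=sequences[src],
                modification=str(rng.choice(mods[:3])),
                antigen_id=assignment.get(src) or None))
        else:
            records.append(EpitopeRecord(
                epitope_id=f"Epitope {i}", sequence=sequences[i],
                modification=str(rng.choice(mods)),
                antigen_id=None if i == _ANTIGENLESS_ID else assignment[i]))
    return records, antigens, dict(collagen_reassignment)
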