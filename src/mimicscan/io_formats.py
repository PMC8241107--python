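"""Readers and writers for the pipeline's on-disk formats.

Sequences travel as FASTA (via Biopython), tabular data as TSV/CSV with a
header row (via pandas, tab-delimited by default with comma fallback by
sniffing), and the pipeline configuration as a flat YAML file whose keys
mirror :class:`PipelineConfig` field names exactly.

All amino-acid sequences are stored upper-case; the ambiguous letters
B, Z, X, U, O are replaced by ``X`` on input, which scores 0 against every
residue during alignment.  Comparisons are therefore case-insensitive by
construction.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X", "*": ""}


class FormatError(ValueError):
    """Raised on malformed input files (bad FASTA, missing table columns)."""


def sanitize_sequence(seq: str) -> str:
    """Upper-case, strip whitespace, and map ambiguous residues to X.

    Raises :class:`FormatError` if a character is neither a canonical
    residue nor a recognised ambiguity code.
    """
    out = []
    for ch in seq.upper():
        if ch.isspace():
            continue
        ch = _AMBIGUOUS.get(ch, ch)
        if ch == "":
            continue
        if ch != "X" and ch not in CANONICAL_AA:
            raise FormatError(f"non-amino-acid character {ch!r} in sequence")
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein sequence with its provenance annotations."""

    accession: str
    description: str = ""
    organism_name: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        self.sequence = sanitize_sequence(self.sequence)
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EpitopeRecord:
    """A short peptide epitope, experimental or predicted.

    ``modification`` carries free-text post-translational-modification
    annotation verbatim; it is ignored when comparing sequence identity.
    Experimental records lacking ``antigen_id`` are flagged for exclusion
    downstream.
    """

    epitope_id: str
    sequence: str
    modification: Optional[str] = None
    antigen_id: Optional[str] = None
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        self.sequence = sanitize_sequence(self.sequence)
        if not self.sequence:
            raise FormatError(f"empty sequence for epitope {self.epitope_id!r}")
        if self.provenance not in ("experimental", "predicted"):
            raise ValueError(f"bad provenance {self.provenance!r}")


ORGANISM_GROUPS = ("Bacteria", "Fungi", "Viruses")
HOST_STATUSES = ("pathogen", "commensal", "putative", "non_human", "unknown")
LITERATURE_FLAGS = ("PubMed", "NoPubMed", "unassessed")


@dataclass
class OrganismAnnotation:
    """Taxonomic group, host association and literature status of an organism."""

    organism_name: str
    group: str
    host_status: str = "unknown"
    literature_flag: str = "unassessed"

    def __post_init__(self) -> None:
        if self.group not in ORGANISM_GROUPS:
            raise ValueError(f"group must be one of {ORGANISM_GROUPS}, got {self.group!r}")
        if self.host_status not in HOST_STATUSES:
            raise ValueError(f"bad host_status {self.host_status!r}")
        if self.literature_flag not in LITERATURE_FLAGS:
            raise ValueError(f"bad literature_flag {self.literature_flag!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Standard IEDB 26-allele HLA class II reference panel (worldwide coverage
#: > 95%); the TepiTool default for class II prediction.
CLASS2_PANEL_26 = [
    "HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01", "HLA-DRB1*04:05",
    "HLA-DRB1*07:01", "HLA-DRB1*08:02", "HLA-DRB1*09:01", "HLA-DRB1*11:01",
    "HLA-DRB1*12:01", "HLA-DRB1*13:02", "HLA-DRB1*15:01", "HLA-DRB3*01:01",
    "HLA-DRB3*02:02", "HLA-DRB4*01:01", "HLA-DRB5*01:01",
    "HLA-DQA1*05:01/DQB1*02:01", "HLA-DQA1*05:01/DQB1*03:01",
    "HLA-DQA1*03:01/DQB1*03:02", "HLA-DQA1*04:01/DQB1*04:02",
    "HLA-DQA1*01:01/DQB1*05:01", "HLA-DQA1*01:02/DQB1*06:02",
    "HLA-DPA1*02:01/DPB1*01:01", "HLA-DPA1*01:03/DPB1*02:01",
    "HLA-DPA1*01:03/DPB1*04:01", "HLA-DPA1*03:01/DPB1*04:02",
    "HLA-DPA1*02:01/DPB1*05:01",
]

#: Standard IEDB 27-allele HLA class I A & B reference panel; the TepiTool
#: default for class I prediction.
CLASS1_PANEL_27 = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*02:03", "HLA-A*02:06", "HLA-A*03:01",
    "HLA-A*11:01", "HLA-A*23:01", "HLA-A*24:02", "HLA-A*26:01", "HLA-A*30:01",
    "HLA-A*30:02", "HLA-A*31:01", "HLA-A*32:01", "HLA-A*33:01", "HLA-A*68:01",
    "HLA-A*68:02", "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*35:01",
    "HLA-B*40:01", "HLA-B*44:02", "HLA-B*44:03", "HLA-B*51:01", "HLA-B*53:01",
    "HLA-B*57:01", "HLA-B*58:01",
]

#: Class II alleles with no established relation to rheumatoid arthritis,
#: excluded from autoreactivity-relevant tier selection.
EXCLUDED_ALLELES_RA = [
    "HLA-DRB5*01:01",
    "HLA-DQA1*01:01/DQB1*05:01",
    "HLA-DQA1*04:01/DQB1*04:02",
]


@dataclass
class PipelineConfig:
    """All thresholds and panels governing the screen.

    Defaults are the study conditions: composite homology filter of
    identity >= 80%, query cover >= 80%, no gaps, e-value < 1; class II
    15-mers with 10-residue overlap scored against 26 alleles and kept at
    the top 10% percentile-rank tier (top 1% highlighted, top 0.5% taken to
    the autoreactivity screen); class I 9-mers against 27 alleles at the top
    2% tier; autoreactivity confirmation at e-value < 0.001 for peptides of
    at least 10 residues; epitope clustering at 70% identity with a minimum
    cluster size of five.
    """

    identity_min_pct: float = 80.0
    cover_min_pct: float = 80.0
    max_gaps: int = 0
    evalue_max: float = 1.0
    autoreactivity_evalue_max: float = 1e-3
    min_align_len: int = 10
    cluster_identity_pct: float = 70.0
    cluster_min_size: int = 5
    overhang_max_aa: int = 3
    class2_pep_len: int = 15
    class2_overlap: int = 10
    class2_tier_pct: float = 10.0
    class2_highlight_pct: float = 1.0
    autoreact_tier_pct: float = 0.5
    class1_pep_len: int = 9
    class1_tier_pct: float = 2.0
    class2_allele_panel: list = field(default_factory=lambda: list(CLASS2_PANEL_26))
    class1_allele_panel: list = field(default_factory=lambda: list(CLASS1_PANEL_27))
    excluded_alleles: list = field(default_factory=lambda: list(EXCLUDED_ALLELES_RA))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class2_tier_pct", "class1_tier_pct",
                     "class2_highlight_pct", "autoreact_tier_pct"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.overhang_max_aa < 0:
            raise ValueError("overhang_max_aa must be >= 0")
        missing = set(self.excluded_alleles) - set(self.class2_allele_panel)
        if missing:
            raise ValueError(f"excluded alleles not in class II panel: {sorted(missing)}")


def load_config(path) -> PipelineConfig:
    """Load a YAML config whose keys mirror PipelineConfig field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, order preserved.

    The header is split into accession (first whitespace-delimited token)
    and description (remainder); a trailing bracketed token in the
    description is read as the organism name, following the NCBI defline
    convention ``>acc description [organism]``.  Sequences are sanitized
    (upper-cased, ambiguity codes mapped to X).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    # reject sequence data before the first header with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: sequence data before FASTA header")
            break
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip()
        organism = ""
        m = re.search(r"\[([^\[\]]+)\]\s*$", description)
        if m:
            organism = m.group(1)
            description = description[:m.start()].rstrip()
        records.append(ProteinRecord(
            accession=rec.id, description=description,
            organism_name=organism, sequence=str(rec.seq)))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA; the organism, if set, is appended to the
    description as a bracketed defline token so it round-trips."""
    seqrecords = []
    for r in records:
        desc = r.description
        if r.organism_name:
            desc = f"{desc} [{r.organism_name}]".strip()
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.accession,
                                    description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read a delimited table, tab by default with comma fallback by sniffing."""
    with open(path) as fh:
        sample = fh.read(8192)
    try:
        dialect = csv.Sniffer().sniff(sample.splitlines()[0], delimiters="\t,")
        sep = dialect.delimiter
    except (csv.Error, IndexError):
        sep = "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_epitope_table(path) -> list[EpitopeRecord]:
    """Read an epitope table with columns epitope_id, sequence
    [, modification, antigen_id, provenance]."""
    df = _read_table(path)
    for col in ("epitope_id", "sequence"):
        if col not in df.columns:
            raise FormatError(f"epitope table {path} missing mandatory column {col!r}")
    dup = df["epitope_id"][df.duplicated("epitope_id")].unique().tolist()
    # duplicate ids are only an error when they carry conflicting sequences;
    # IEDB exports repeat an id for each PTM variant row
    for did in dup:
        seqs = {sanitize_sequence(s) for s in df.loc[df["epitope_id"] == did, "sequence"]}
        if len(seqs) > 1:
            raise FormatError(f"duplicate epitope_id {did!r} with conflicting sequences")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(EpitopeRecord(
            epitope_id=str(d["epitope_id"]),
            sequence=d["sequence"],
            modification=d.get("modification") or None,
            antigen_id=d.get("antigen_id") or None,
            provenance=d.get("provenance") or "experimental",
        ))
    return records


def write_epitope_table(records: list[EpitopeRecord], path) -> None:
    df = pd.DataFrame([{
        "epitope_id": r.epitope_id,
        "sequence": r.sequence,
        "modification": r.modification or "",
        "antigen_id": r.antigen_id or "",
        "provenance": r.provenance,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> list[OrganismAnnotation]:
    df = _read_table(path)
    required = {"organism_name", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(OrganismAnnotation(
            organism_name=d["organism_name"],
            group=d["group"],
            host_status=d.get("host_status") or "unknown",
            literature_flag=d.get("literature_flag") or "unassessed",
        ))
    return out


def write_annotation_table(annotations: list[OrganismAnnotation], path) -> None:
    pd.DataFrame([asdict(a) for a in annotations]).to_csv(path, sep="\t", index=False)
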