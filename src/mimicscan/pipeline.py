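"""End-to-end orchestration of the screening stages.

Stage order: catalog -> scan -> predict -> reconcile -> autoreact ->
cluster.  Each stage writes its result table (TSV) plus a JSON run manifest
recording the config hash, seed, input checksums and output row counts, so
re-runs on unchanged inputs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import alignment, autoreactivity, catalog, cluster_logo, mhc
from .io_formats import (EpitopeRecord, OrganismAnnotation, PipelineConfig,
                         ProteinRecord, read_annotation_table,
                         read_epitope_table, read_fasta, save_config)
from .reconcile import recover_hits, recovery_to_frame

logger = logging.getLogger(__name__)

STAGES = ("catalog", "scan", "predict", "reconcile", "autoreact", "cluster")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig,
                    inputs: list[Path], row_counts: dict[str, int]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.rng_seed,
        "inputs": {str(p): _checksum(Path(p)) for p in inputs},
        "row_counts": row_counts,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(study_dir, outdir, cfg: PipelineConfig | None = None,
                 reassignment: dict[str, str] | None = None) -> Path:
    """Run all stages on a study directory (as written by the synthetic
    generator or assembled by hand with the same file names).

    Expects antigens.fasta, epitopes.tsv, proteome.fasta, annotations.tsv
    under ``study_dir``; writes all stage tables and manifests to ``outdir``.
    """
    study_dir = Path(study_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or PipelineConfig()
    save_config(cfg, outdir / "config.yaml")

    paths = {name: study_dir / name for name in
             ("antigens.fasta", "epitopes.tsv", "proteome.fasta", "annotations.tsv")}
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(p)

    state: dict = {}
    for stage in STAGES:
        try:
            _run_stage(stage, paths, outdir, cfg, state, reassignment)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise StageFailure(stage, exc) from exc
    return outdir


def _run_stage(stage, paths, outdir, cfg, state, reassignment):
    scheme = alignment.ScoringScheme()
    if stage == "catalog":
        raw = read_epitope_table(paths["epitopes.tsv"])
        unique = catalog.deduplicate_epitopes(raw)
        kept = catalog.apply_exclusions(unique)
        groups = catalog.assign_antigens(kept, reassignment)
        antigen_of = {eid: ag for ag, eids in groups.items() for eid in eids}
        for r in kept:
            r.antigen_id = antigen_of[r.epitope_id]
        state["epitopes"] = kept
        df = pd.DataFrame([{"epitope_id": r.epitope_id, "sequence": r.sequence,
                            "antigen_id": r.antigen_id} for r in kept])
        df.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, cfg, [paths["epitopes.tsv"]],
                        {"catalog.tsv": len(df), "raw_rows": len(raw)})
    elif stage == "scan":
        proteome = read_fasta(paths["proteome.fasta"])
        annotations = read_annotation_table(paths["annotations.tsv"])
        hits = alignment.scan_epitopes(state["epitopes"], proteome, cfg, scheme,
                                       annotations)
        state["proteome"] = proteome
        state["annotations"] = annotations
        state["hits"] = hits
        df = alignment.hits_to_frame(hits)
        df.to_csv(outdir / "hits.tsv", sep="\t", index=False)
        dist = catalog.hit_distribution(
            hits, {ag: [r.epitope_id for r in state["epitopes"] if r.antigen_id == ag]
                   for ag in {r.antigen_id for r in state["epitopes"]}})
        dist.to_csv(outdir / "hit_distribution.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, cfg,
                        [paths["proteome.fasta"], paths["annotations.tsv"]],
                        {"hits.tsv": len(df), "hit_distribution.tsv": len(dist)})
    elif stage == "predict":
        best = alignment.best_protein_per_organism(state["hits"])
        proteins = {p.accession: p for p in state["proteome"]}
        groups = {a.organism_name: a.group for a in state["annotations"]}
        scorer2 = mhc.PSSMScorer.random(cfg.class2_allele_panel, seed=cfg.rng_seed)
        scorer1 = mhc.PSSMScorer.random(cfg.class1_allele_panel, seed=cfg.rng_seed + 1)
        predictions: list[mhc.PredictedPeptide] = []
        for org, acc in sorted(best.items()):
            prot = proteins[acc]
            if groups.get(org) == "Viruses":
                peps = mhc.generate_peptides(prot, cfg.class1_pep_len,
                                             cfg.class1_pep_len - 1)
                scored = mhc.score_panel(peps, cfg.class1_allele_panel,
                                         scorer1, acc, "I")
            else:
                peps = mhc.generate_peptides(prot, cfg.class2_pep_len,
                                             cfg.class2_overlap)
                scored = mhc.score_panel(peps, cfg.class2_allele_panel,
                                         scorer2, acc, "II")
            predictions.extend(mhc.percentile_ranks(scored))
        class2 = [p for p in predictions if p.mhc_class == "II"]
        class1 = [p for p in predictions if p.mhc_class == "I"]
        class2 = mhc.apply_allele_exclusions(class2, cfg.excluded_alleles)
        predictions = class2 + class1
        state["predictions"] = predictions
        state["tiered"] = (mhc.select_tier(class2, cfg.class2_tier_pct)
                           + mhc.select_tier(class1, cfg.class1_tier_pct))
        df = mhc.predictions_to_frame(predictions, cfg)
        df.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, cfg, [], {"predictions.tsv": len(df)})
    elif stage == "reconcile":
        summary, details = recover_hits(state["tiered"], state["hits"], cfg)
        df = recovery_to_frame(details)
        df.to_csv(outdir / "reconciliation.tsv", sep="\t", index=False)
        sdf = pd.DataFrame([{"organism": o, **counts} for o, counts in
                            sorted(summary.items())])
        sdf.to_csv(outdir / "recovery_summary.tsv", sep="\t", index=False)
        state["recovery"] = summary
        _write_manifest(outdir, stage, cfg, [],
                        {"reconciliation.tsv": len(df),
                         "recovery_summary.tsv": len(sdf)})
    elif stage == "autoreact":
        antigens = read_fasta(paths["antigens.fasta"])
        class2 = [p for p in state["predictions"] if p.mhc_class == "II"]
        top = mhc.select_tier(class2, cfg.autoreact_tier_pct)
        results = autoreactivity.autoreactivity_screen(
            top, antigens, state["epitopes"], cfg)
        state["antigens"] = antigens
        state["autoreactivity"] = results
        df = autoreactivity.results_to_frame(results)
        df.to_csv(outdir / "autoreactivity.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, cfg, [paths["antigens.fasta"]],
                        {"autoreactivity.tsv": len(df)})
    elif stage == "cluster":
        results = state["autoreactivity"]
        counts = autoreactivity.confirmations_per_antigen(results)
        n_rows = 0
        if counts:
            top_antigen = max(counts, key=lambda a: (counts[a], a))
            peptides = sorted({r.peptide.peptide for r in results
                               if r.status == "confirmed"
                               and r.confirmed_antigen == top_antigen})
            clusters = cluster_logo.cluster_break(peptides, cfg.cluster_identity_pct)
            big = cluster_logo.filter_clusters(clusters, cfg.cluster_min_size)
            cdf = cluster_logo.clusters_to_frame(clusters)
            cdf.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            n_rows = len(cdf)
            antigen = {a.accession: a for a in state["antigens"]}[top_antigen]
            mapped = cluster_logo.map_clusters_to_antigen(
                big, antigen, evalue_max=cfg.autoreactivity_evalue_max)
            pd.DataFrame(mapped, columns=["cluster_id", "antigen_start",
                                          "antigen_end"]).to_csv(
                outdir / "cluster_mapping.tsv", sep="\t", index=False)
            for c in big:
                cluster_logo.logo_to_frame(c.logo).to_csv(
                    outdir / f"logo_cluster_{c.cluster_id}.tsv",
                    sep="\t", index=False)
        else:
            pd.DataFrame(columns=["cluster_id", "member", "offset",
                                  "is_representative", "consensus"]).to_csv(
                outdir / "clusters.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, cfg, [], {"clusters.tsv": n_rows})
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
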