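"""End-to-end orchestration: score → calibrate → call → scan → enrich →
cluster, with a plain-text run manifest for reproducibility auditing."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, clustering, enrichment, interactome, roc, scoring, sites
from .io import (
    KnownInteractionSet,
    SequenceRecord,
    read_plate_table,
    read_sequences,
    write_score_table,
)

log = logging.getLogger("mirseed")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    wells_path: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    positives_path: str | None = None  # scores of validated interactions
    empty_wells_path: str | None = None  # empty-3'UTR screen well table
    known_path: str | None = None
    cutoff: float | str = "calibrate"
    include_controls: bool = True
    center_pool: str = "all"
    strata: dict[str, str] = field(default_factory=dict)  # name → pandas query
    seed: int = 0
    out_dir: str = "mirseed-out"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    wells: pd.DataFrame | None = None,
    empty_wells: pd.DataFrame | None = None,
    mirnas: Sequence[SequenceRecord] | None = None,
    utrs: Sequence[SequenceRecord] | None = None,
    known: KnownInteractionSet | None = None,
) -> dict:
    """Execute the full analysis; in-memory inputs override file paths.

    Writes per-stage TSV/JSON artifacts under ``config.out_dir`` and returns
    the manifest (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }
    t0 = time.time()

    def stage(name: str, fn):
        start = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.time() - start, 3)}
        log.info("stage %s done in %.2fs", name, time.time() - start)
        return result

    # ------------------------------------------------------------------ load
    def load():
        w = wells if wells is not None else read_plate_table(config.wells_path)
        e = empty_wells
        if e is None and config.empty_wells_path:
            e = read_plate_table(config.empty_wells_path)
        return w, e

    wells_df, empty_df = stage("load", load)
    for key, path in (("wells", config.wells_path),
                      ("mirna_fasta", config.mirna_fasta),
                      ("utr_fasta", config.utr_fasta)):
        if path:
            manifest["inputs"][key] = _digest(Path(path))

    # ----------------------------------------------------------------- score
    def score():
        matrices = scoring.score_screen(
            wells_df,
            include_controls=config.include_controls,
            center_pool=config.center_pool,
        )
        avg = scoring.average_replicates(matrices["interaction"])
        write_score_table(matrices["interaction"].data, "interaction",
                          out / "interaction_scores.tsv")
        avg.to_csv(out / "avg_interaction_scores.tsv", sep="\t", index=False)
        return matrices, avg

    matrices, avg = stage("score", score)
    manifest["stages"]["score"]["rows"] = int(len(avg))

    # ------------------------------------------------------------- calibrate
    def calibrate():
        if config.cutoff != "calibrate":
            return float(config.cutoff), None
        if empty_df is None:
            raise PipelineError(
                "cutoff='calibrate' needs an empty-3'UTR screen for negatives"
            )
        if config.positives_path:
            positives = np.loadtxt(config.positives_path)
        elif known is not None and len(known):
            key = avg.set_index(["mirna", "gene"])["avg_score"]
            positives = np.array(
                [key[pair] for pair in known.entries if pair in key.index]
            )
        else:
            raise PipelineError("cutoff='calibrate' needs positive-control scores")
        neg_avg = scoring.average_replicates(
            scoring.score_screen(empty_df, include_controls=config.include_controls)[
                "interaction"
            ]
        )
        controls = roc.ControlScores(positives, neg_avg["avg_score"].to_numpy())
        result = roc.roc_analysis(controls)
        (out / "roc.json").write_text(json.dumps({
            "auc": result.auc, "best_cutoff": result.best_cutoff,
            "accuracy": result.accuracy, "precision": result.precision,
            "sensitivity": result.sensitivity, "specificity": result.specificity,
        }, indent=2))
        pd.DataFrame({"threshold": result.thresholds, "tpr": result.tpr,
                      "fpr": result.fpr}).to_csv(out / "roc_points.tsv",
                                                 sep="\t", index=False)
        return result.best_cutoff, result

    cutoff, roc_result = stage("calibrate", calibrate)
    manifest["cutoff"] = cutoff

    # ------------------------------------------------------------------ call
    def call():
        calls = interactome.call_and_annotate(avg, cutoff, known)
        calls.to_csv(out / "interactome_calls.tsv", sep="\t", index=False)
        summary = interactome.summarize_calls(calls)
        (out / "interactome_summary.json").write_text(json.dumps(summary, indent=2))
        return calls

    calls = stage("call", call)
    manifest["stages"]["call"]["rows"] = int(calls["called"].sum())

    # ------------------------------------------------------------------ scan
    def scan():
        mir = mirnas if mirnas is not None else (
            read_sequences(config.mirna_fasta, "miRNA") if config.mirna_fasta else None
        )
        utr = utrs if utrs is not None else (
            read_sequences(config.utr_fasta, "UTR") if config.utr_fasta else None
        )
        if mir is None or utr is None:
            return None, None
        site_table, annotations = sites.annotate_pairs(mir, utr)
        site_table.to_csv(out / "sites.tsv", sep="\t", index=False)
        annotations.to_csv(out / "combination_annotations.tsv", sep="\t", index=False)
        return site_table, annotations

    site_table, annotations = stage("scan", scan)
    if site_table is not None:
        manifest["stages"]["scan"]["rows"] = int(len(site_table))

    # ---------------------------------------------------------------- enrich
    def enrich():
        if annotations is None:
            return None
        merged = calls.merge(
            annotations, left_on=["mirna", "gene"], right_on=["mirna", "utr"],
            how="inner",
        )
        default_strata = {
            "any_canonical": "any_canonical",
            "multiple_canonical": "multiple_canonical",
            "8mer": "n_8mer > 0",
            "7mer-m8": "n_7mer_m8 > 0",
            "7mer-A1": "n_7mer_a1 > 0",
            "6mer": "n_6mer > 0",
            "offset6": "n_offset6 > 0",
            "mismatch_or_wobble": "n_seed_mismatch + n_gu_wobble > 0",
            "gbulge": "n_gbulge > 0",
        }
        queries = config.strata or default_strata
        values = merged.rename(columns={"avg_score": "value"})
        strata = {
            name: merged.eval(expr).to_numpy(dtype=bool)
            for name, expr in queries.items()
        }
        comparisons = enrichment.stratified_compare(values, strata, seed=config.seed)
        frame = enrichment.comparisons_to_frame(comparisons)
        frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return frame

    enrich_frame = stage("enrich", enrich)

    # --------------------------------------------------------------- cluster
    def cluster():
        corr, dropped = clustering.mirna_correlation_matrix(avg)
        if corr.shape[0] < 2 or corr.isna().any().any():
            return None
        dendro = clustering.cluster_mirnas(corr)
        (out / "mirna_dendrogram.nwk").write_text(clustering.to_newick(dendro))
        corr.to_csv(out / "mirna_correlations.tsv", sep="\t")
        return dendro

    stage("cluster", cluster)

    manifest["outputs"] = {
        p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    manifest["seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
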