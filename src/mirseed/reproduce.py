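"""Recompute the published screen's summary figures from its supplementary
data files.

This module is driven entirely by user-supplied files (they are not bundled
with the package): the mature miRNA FASTA, the 3' UTR insert FASTA, the
screening-results table (per-combination replicate interaction scores and
the called interactomes) and the prediction/known-interaction tables.  Given
those, it rebuilds the combination census, the interactome and its novelty
split, the seedless fraction of called interactions, the per-class
binding-site censuses, the replicate correlation and the two precision
figures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, interactome, sites
from .io import read_annotation_table, read_sequences


def supplementary_census(
    mirna_fasta: str | Path,
    utr_fasta: str | Path,
    results_table: str | Path,
    predictions_table: str | Path | None = None,
    cutoff: float = -1.94,
) -> dict[str, float]:
    """Summary quantities of a full screen from supplementary-style files.

    ``results_table`` is a TSV with columns mirna, gene, and one
    ``score_r<k>`` column per replicate interaction score.  Returns a dict of
    censuses, counts, the replicate Pearson correlation and precision
    percentages.
    """
    mirnas = read_sequences(mirna_fasta, "miRNA")
    utrs = read_sequences(utr_fasta, "UTR")
    results = pd.read_csv(results_table, sep="\t")
    rep_cols = [c for c in results.columns if c.startswith("score_r")]
    if not rep_cols:
        raise ValueError("results table lacks per-replicate score columns")

    avg = results.loc[:, ["mirna", "gene"]].copy()
    avg["avg_score"] = results[rep_cols].mean(axis=1)
    avg["n_replicates"] = results[rep_cols].notna().sum(axis=1)
    calls = interactome.call_and_annotate(avg, cutoff)

    r1 = results[rep_cols[0]]
    r2 = results[rep_cols[1]]
    ok = r1.notna() & r2.notna()
    replicate_corr = float(np.corrcoef(r1[ok], r2[ok])[0, 1])

    site_table, annotations = sites.annotate_pairs(mirnas, utrs)
    merged = calls.merge(
        annotations, left_on=["mirna", "gene"], right_on=["mirna", "utr"], how="left"
    )

    out = {
        "combinations_probed": int(len(calls)),
        "interactions_called": int(calls["called"].sum()),
        "seedless_called": int(
            (merged["called"] & ~merged["any_canonical"].fillna(False)).sum()
        ),
        "canonical_combinations": int(annotations["any_canonical"].sum()),
        "canonical_sites": int(annotations["n_canonical"].sum()),
        "combinations_8mer": int((annotations["n_8mer"] > 0).sum()),
        "combinations_offset6": int((annotations["n_offset6"] > 0).sum()),
        "combinations_gbulge": int((annotations["n_gbulge"] > 0).sum()),
        "combinations_centered": int((annotations["n_centered"] > 0).sum()),
        "replicate_correlation": replicate_corr,
    }

    multi_8mer = set(
        map(tuple, annotations.loc[annotations["n_8mer"] >= 2, ["mirna", "utr"]].values)
    )
    if multi_8mer:
        out["precision_multi_8mer_pct"] = enrichment.percent(
            enrichment.predictor_precision(calls, multi_8mer)
        )
    if predictions_table is not None:
        preds = read_annotation_table(predictions_table, "predictions")
        at_least_5 = preds.predicted_by_at_least(5)
        if at_least_5:
            out["precision_5plus_models_pct"] = enrichment.percent(
                enrichment.predictor_precision(calls, set(at_least_5))
            )
    return out
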