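"""Interactome calling: apply the calibrated cutoff to averaged interaction
scores and label each called interaction's novelty against a set of
literature-validated interactions."""

from __future__ import annotations

import pandas as pd

from .io import KnownInteractionSet


def call_and_annotate(
    avg: pd.DataFrame,
    cutoff: float,
    known: KnownInteractionSet | None = None,
) -> pd.DataFrame:
    """Call interactions (avg_score <= cutoff, inclusive) and flag novelty.

    ``avg`` carries columns mirna, gene, avg_score and optionally
    n_replicates.  Returns one row per probed (miRNA, gene) pair with boolean
    ``called`` and ``novel`` columns; ``novel`` implies ``called``.
    """
    calls = avg.copy()
    calls["called"] = calls["avg_score"] <= cutoff
    if known is None:
        known = KnownInteractionSet(frozenset())
    in_known = [
        (m, g) in known for m, g in zip(calls["mirna"], calls["gene"])
    ]
    calls["known"] = in_known
    calls["novel"] = calls["called"] & ~calls["known"]
    return calls


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Counts reported alongside a screen's interactome: total called, novel,
    known interactions recovered, and the per-gene breakdown."""
    called = calls[calls["called"]]
    per_gene = called.groupby("gene").size().to_dict()
    return {
        "probed": int(len(calls)),
        "called": int(len(called)),
        "novel": int(called["novel"].sum()),
        "known_recovered": int((called["known"]).sum()),
        "known_probed": int(calls["known"].sum()),
        "per_gene": per_gene,
    }


def gene_interactome(calls: pd.DataFrame, gene: str) -> pd.DataFrame:
    """The miRNAs called as regulators of one gene's 3' UTR."""
    sub = calls[(calls["gene"] == gene) & calls["called"]]
    return sub.sort_values("avg_score").reset_index(drop=True)
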