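"""Luminescence → interaction-score transforms.

The chain is: per-well normalized reporter activity
``NRA = log2(luc2P / Rluc)``; per-plate robust z-score
``z = (NRA − median(NRA)_p) / MAD(NRA)_p`` (MAD without a consistency
factor); per-miRNA median centering ``i = z − median(z)_m`` which removes
treatment-specific systematic bias; replicate averaging.  Two comparison
metrics are provided as well: the B-score (Tukey median-polish residuals of
the per-plate z grid, removing positional bias) and the knockdown percentage
relative to the plate's non-targeting controls.

Interaction scores are more negative for miRNAs that repress the 3' UTR
reporter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NTC, PLATE_ROWS, VEHICLE


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreMatrix:
    """Long-format (miRNA, gene, replicate) → value table under a named metric."""

    metric: str
    data: pd.DataFrame  # columns: mirna, gene, replicate, plate, value

    def values_for_mirna(self, mirna: str) -> np.ndarray:
        return self.data.loc[self.data["mirna"] == mirna, "value"].to_numpy()


def compute_nra(luc2p, rluc):
    """log2 firefly/renilla ratio; symmetric around 0, in log2 units."""
    luc2p = np.asarray(luc2p, dtype=float)
    rluc = np.asarray(rluc, dtype=float)
    if np.any(luc2p <= 0) or np.any(rluc <= 0):
        raise ScoringError("luminescence must be positive to form an NRA")
    return np.log2(luc2p / rluc)


def plate_robust_z(values) -> np.ndarray:
    """Robust z-scores of one plate's NRAs: (v − median) / MAD.

    MAD is the raw median absolute deviation, with no normal-consistency
    factor.  Requires at least 3 finite values and a nonzero MAD.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3 or not np.all(np.isfinite(v)):
        raise ScoringError("need >= 3 finite values per plate")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        raise ScoringError("MAD is zero; plate has no usable scale")
    return (v - med) / mad


def add_nra(wells: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``nra`` column (NaN for unusable wells)."""
    wells = wells.copy()
    if "usable" not in wells.columns:
        wells["usable"] = (wells["luc2P"] > 0) & (wells["Rluc"] > 0)
    nra = np.full(len(wells), np.nan)
    ok = wells["usable"].to_numpy()
    nra[ok] = compute_nra(wells.loc[ok, "luc2P"], wells.loc[ok, "Rluc"])
    wells["nra"] = nra
    return wells


def add_plate_z(wells: pd.DataFrame, include_controls: bool = True) -> pd.DataFrame:
    """Attach a per-plate robust z column.

    ``include_controls`` chooses the wells that define each plate's
    median/MAD: all usable wells (default) or miRNA-treated wells only.
    z-scores are then assigned to every usable well from those estimates.
    """
    wells = add_nra(wells) if "nra" not in wells.columns else wells.copy()
    z = np.full(len(wells), np.nan)
    for plate, idx in wells.groupby("plate").groups.items():
        sub = wells.loc[idx]
        pool = sub["usable"]
        if not include_controls:
            pool = pool & ~sub["treatment"].isin([NTC, VEHICLE])
        ref = sub.loc[pool, "nra"].to_numpy()
        if ref.size < 3:
            raise ScoringError(f"plate {plate!r}: fewer than 3 usable wells")
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        if mad == 0:
            raise ScoringError(f"plate {plate!r}: MAD is zero")
        usable = sub["usable"].to_numpy()
        zvals = np.full(len(sub), np.nan)
        zvals[usable] = (sub.loc[sub["usable"], "nra"].to_numpy() - med) / mad
        z[wells.index.get_indexer(idx)] = zvals
    wells["z"] = z
    return wells


def z_matrix(wells: pd.DataFrame, include_controls: bool = True) -> ScoreMatrix:
    """Per-plate robust z-scores of the miRNA-treated wells, long format."""
    wells = add_plate_z(wells, include_controls=include_controls)
    mirna_wells = wells[~wells["treatment"].isin([NTC, VEHICLE]) & wells["usable"]]
    data = (
        mirna_wells.rename(columns={"treatment": "mirna", "z": "value"})
        .loc[:, ["mirna", "gene", "replicate", "plate", "value"]]
        .reset_index(drop=True)
    )
    return ScoreMatrix("z", data)


def interaction_scores(z: ScoreMatrix, center_pool: str = "all") -> ScoreMatrix:
    """Median-center z-scores per miRNA, yielding interaction scores.

    ``center_pool='all'`` pools every z value of a miRNA across genes and
    replicates (the default, matching the i = z − median(z)_m definition);
    ``'per-replicate'`` stratifies the centering by replicate index.
    """
    if z.metric != "z":
        raise ScoringError(f"expected a z-score matrix, got {z.metric!r}")
    if center_pool not in ("all", "per-replicate"):
        raise ScoringError(f"unknown center_pool {center_pool!r}")
    data = z.data.copy()
    keys = ["mirna"] if center_pool == "all" else ["mirna", "replicate"]
    data["value"] = data["value"] - data.groupby(keys)["value"].transform("median")
    return ScoreMatrix("interaction", data)


def average_replicates(scores: ScoreMatrix) -> pd.DataFrame:
    """Arithmetic mean over available replicates per (miRNA, gene).

    Returns columns mirna, gene, avg_score, n_replicates.  Pairs with no
    usable replicate simply do not appear (they are reported by the caller's
    bookkeeping, never imputed).
    """
    grouped = scores.data.groupby(["mirna", "gene"])["value"]
    out = grouped.agg(avg_score="mean", n_replicates="size").reset_index()
    return out


def median_polish(grid, tol: float = 1e-9, max_iter: int = 100):
    """Two-way Tukey median polish; returns the residual grid.

    Iterates row- and column-median sweeps until the largest absolute change
    is below ``tol`` or ``max_iter`` sweeps have run.  NaN cells are carried
    through untouched; an all-missing row or column is an error.
    """
    r = np.array(grid, dtype=float)
    if r.ndim != 2:
        raise ScoringError("median polish expects a 2-D grid")
    if np.all(np.isnan(r), axis=1).any() or np.all(np.isnan(r), axis=0).any():
        raise ScoringError("grid has an all-missing row or column")
    for _ in range(max_iter):
        row_med = np.nanmedian(r, axis=1, keepdims=True)
        r = r - row_med
        col_med = np.nanmedian(r, axis=0, keepdims=True)
        r = r - col_med
        if max(np.max(np.abs(row_med)), np.max(np.abs(col_med))) < tol:
            break
    return r


def b_scores(z_grid) -> np.ndarray:
    """B-scores: median-polish residuals of one plate's 8×12 z grid."""
    return median_polish(z_grid)


def b_score_matrix(wells: pd.DataFrame, include_controls: bool = True) -> ScoreMatrix:
    """Per-plate B-scores of the miRNA-treated wells, long format."""
    wells = add_plate_z(wells, include_controls=include_controls)
    rows = []
    row_index = {r: i for i, r in enumerate(PLATE_ROWS)}
    for plate, sub in wells.groupby("plate"):
        grid = np.full((8, 12), np.nan)
        for w in sub.itertuples(index=False):
            if w.usable:
                grid[row_index[w.row], w.column - 1] = w.z
        resid = median_polish(grid)
        for w in sub.itertuples(index=False):
            if w.usable and w.treatment not in (NTC, VEHICLE):
                rows.append(
                    (w.treatment, w.gene, w.replicate, plate,
                     resid[row_index[w.row], w.column - 1])
                )
    data = pd.DataFrame(rows, columns=["mirna", "gene", "replicate", "plate", "value"])
    return ScoreMatrix("B", data)


def knockdown_percent(nra, ntc_nras) -> np.ndarray:
    """Percent knockdown relative to the mean NTC NRA of the same plate.

    100 × (1 − 2^(nra − mean(NTC))); negative values mean up-regulation.
    """
    ntc = np.asarray(ntc_nras, dtype=float)
    if ntc.size == 0:
        raise ScoringError("no non-targeting control NRAs supplied")
    return 100.0 * (1.0 - np.exp2(np.asarray(nra, dtype=float) - ntc.mean()))


def knockdown_matrix(wells: pd.DataFrame) -> ScoreMatrix:
    """Per-plate knockdown percentages of the miRNA-treated wells."""
    wells = add_nra(wells)
    rows = []
    for plate, sub in wells.groupby("plate"):
        ntc = sub.loc[(sub["treatment"] == NTC) & sub["usable"], "nra"].to_numpy()
        mir = sub[~sub["treatment"].isin([NTC, VEHICLE]) & sub["usable"]]
        kd = knockdown_percent(mir["nra"].to_numpy(), ntc)
        for w, v in zip(mir.itertuples(index=False), kd):
            rows.append((w.treatment, w.gene, w.replicate, plate, v))
    data = pd.DataFrame(rows, columns=["mirna", "gene", "replicate", "plate", "value"])
    return ScoreMatrix("knockdown", data)


def score_screen(
    wells: pd.DataFrame,
    include_controls: bool = True,
    center_pool: str = "all",
) -> dict[str, ScoreMatrix]:
    """Run the full scoring chain; returns {'z': ..., 'interaction': ...}."""
    z = z_matrix(wells, include_controls=include_controls)
    i = interaction_scores(z, center_pool=center_pool)
    return {"z": z, "interaction": i}
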