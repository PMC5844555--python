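"""Stratified cumulative-distribution comparisons and predictor precision.

Every comparison in this screen asks whether a feature-bearing stratum of
(miRNA, 3' UTR) combinations has *more negative* scores than its complement,
so the test is the one-sided two-sample Kolmogorov–Smirnov statistic
``D+ = sup_x [F_a(x) − F_b(x)]`` with the asymptotic p-value
``exp(−2 D+² n_a n_b / (n_a + n_b))``; batches of comparisons are
Benjamini–Hochberg corrected together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class KsComparison:
    name: str
    group_a_n: int
    group_b_n: int
    D: float
    p: float
    q: float = float("nan")
    direction: str = "a_smaller"


def _dplus(a: np.ndarray, b: np.ndarray) -> float:
    """sup over x of F_a(x) − F_b(x), evaluated at the pooled sample points."""
    a = np.sort(a)
    b = np.sort(b)
    xs = np.concatenate([a, b])
    fa = np.searchsorted(a, xs, side="right") / a.size
    fb = np.searchsorted(b, xs, side="right") / b.size
    return float(np.max(fa - fb))


def ks_one_sided(
    a,
    b,
    name: str = "",
    method: str = "auto",
    n_perm: int = 10000,
    seed: int = 0,
) -> KsComparison:
    """One-sided KS test that ``a`` is stochastically smaller than ``b``.

    ``method='auto'`` uses the asymptotic p-value when both groups have at
    least 5 values and a seeded permutation test below that;
    ``'asymptotic'``/``'permutation'`` force either.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EnrichmentError("both groups must be non-empty")
    d = _dplus(a, b)
    if method == "auto":
        method = "asymptotic" if min(a.size, b.size) >= 5 else "permutation"
    if method == "asymptotic":
        n_eff = a.size * b.size / (a.size + b.size)
        p = float(min(1.0, np.exp(-2.0 * d * d * n_eff)))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _dplus(perm[: a.size], perm[a.size :]) >= d:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise EnrichmentError(f"unknown method {method!r}")
    return KsComparison(name, int(a.size), int(b.size), d, p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stratified_compare(
    values: pd.DataFrame,
    strata: dict[str, np.ndarray],
    reference: str | None = None,
    method: str = "auto",
    seed: int = 0,
) -> list[KsComparison]:
    """One KS comparison per named stratum, BH-corrected across the batch.

    ``values`` carries a ``value`` column aligned row-wise with each boolean
    mask in ``strata``.  Each stratum is compared against its complement, or
    against the named ``reference`` stratum.  Strata with an empty side are
    skipped and reported with NaN statistics.
    """
    v = values["value"].to_numpy(dtype=float)
    results: list[KsComparison] = []
    skipped: list[KsComparison] = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.size != v.size:
            raise EnrichmentError(f"stratum {name!r}: mask length mismatch")
        if reference is None:
            other = ~mask
        else:
            other = np.asarray(strata[reference], dtype=bool)
        a, b = v[mask], v[other]
        if a.size == 0 or b.size == 0:
            skipped.append(
                KsComparison(name, int(a.size), int(b.size), float("nan"), float("nan"))
            )
            continue
        results.append(ks_one_sided(a, b, name=name, method=method, seed=seed))
    if results:
        qs = bh_adjust([r.p for r in results])
        results = [
            KsComparison(r.name, r.group_a_n, r.group_b_n, r.D, r.p, float(q))
            for r, q in zip(results, qs)
        ]
    return results + skipped


def comparisons_to_frame(comparisons: list[KsComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.name, c.group_a_n, c.group_b_n, c.D, c.p, c.q) for c in comparisons],
        columns=["stratum", "n_stratum", "n_other", "D", "p", "q"],
    )


def predictor_precision(calls: pd.DataFrame, predicted: set[tuple[str, str]]) -> float:
    """Positive predictive value of a prediction set against the called
    interactome: |predicted ∩ called| / |predicted|.

    Predictions must be a subset of the probed combinations.
    """
    if not predicted:
        raise EnrichmentError("empty prediction set")
    probed = set(zip(calls["mirna"], calls["gene"]))
    stray = predicted - probed
    if stray:
        raise EnrichmentError(
            f"{len(stray)} predicted pairs were never probed (e.g. {sorted(stray)[0]})"
        )
    called = set(
        zip(calls.loc[calls["called"], "mirna"], calls.loc[calls["called"], "gene"])
    )
    return len(predicted & called) / len(predicted)


def percent(x: float) -> int:
    """Integer percentage, rounding half away from zero (77 for 0.769…)."""
    import math

    v = 100.0 * x
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))
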