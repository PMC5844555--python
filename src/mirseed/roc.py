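"""ROC calibration of the interaction-score cutoff.

Scores are oriented so that *more negative means more evidence of
interaction*; a score s is therefore called positive iff ``s <= threshold``.
Thresholds sweep the distinct observed scores plus ±infinity.  The cutoff put
forward is the threshold of highest accuracy, ties broken toward the more
stringent (lower) cutoff, favoring false negatives over false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RocError(ValueError):
    pass


@dataclass(frozen=True)
class ControlScores:
    """Scores of validated interactions (positives) and of an empty-3'UTR
    screen (negatives)."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positives, dtype=float)
        neg = np.asarray(self.negatives, dtype=float)
        if pos.size == 0 or neg.size == 0:
            raise RocError("both control classes must be non-empty")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
            raise RocError("control scores must be finite")
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    best_cutoff: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    n_positives: int = 0
    n_negatives: int = 0
    extras: dict = field(default_factory=dict)


def _call_counts(controls: ControlScores, thresholds: np.ndarray):
    """TP and FP counts (calls: score <= threshold) at each threshold."""
    pos = np.sort(controls.positives)
    neg = np.sort(controls.negatives)
    tp = np.searchsorted(pos, thresholds, side="right")
    fp = np.searchsorted(neg, thresholds, side="right")
    return tp, fp


def metrics_at_cutoff(controls: ControlScores, cutoff: float) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity of the s <= cutoff rule."""
    p = controls.positives.size
    n = controls.negatives.size
    tp = int(np.sum(controls.positives <= cutoff))
    fp = int(np.sum(controls.negatives <= cutoff))
    tn = n - fp
    return {
        "accuracy": (tp + tn) / (p + n),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "sensitivity": tp / p,
        "specificity": tn / n,
    }


def roc_analysis(controls: ControlScores) -> RocResult:
    """Full ROC sweep over the observed scores, trapezoidal AUC and the
    best-accuracy cutoff with its operating metrics."""
    scores = np.concatenate([controls.positives, controls.negatives])
    thresholds = np.concatenate(
        [[-np.inf], np.unique(scores), [np.inf]]
    )
    p = controls.positives.size
    n = controls.negatives.size
    tp, fp = _call_counts(controls, thresholds)
    tpr = tp / p
    fpr = fp / n
    auc = float(np.trapezoid(tpr, fpr))

    accuracy = (tp + (n - fp)) / (p + n)
    # ties toward stringency: first (lowest) threshold achieving max accuracy
    best_idx = int(np.argmax(accuracy))
    best_cutoff = float(thresholds[best_idx])
    at = metrics_at_cutoff(controls, best_cutoff)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        best_cutoff=best_cutoff,
        accuracy=at["accuracy"],
        precision=at["precision"],
        sensitivity=at["sensitivity"],
        specificity=at["specificity"],
        n_positives=p,
        n_negatives=n,
    )


def auc_mann_whitney(controls: ControlScores) -> float:
    """Tie-adjusted probability that a positive scores below a negative.

    Equals the trapezoidal AUC of the s <= t sweep; pairs tied in score
    count 1/2.
    """
    pos = controls.positives[:, None]
    neg = controls.negatives[None, :]
    wins = np.sum(pos < neg) + 0.5 * np.sum(pos == neg)
    return float(wins / (pos.size * neg.size))


def _delong_variance(controls_a: ControlScores, controls_b: ControlScores):
    """DeLong covariance of two AUCs computed on the same control items."""

    def placements(c: ControlScores):
        pos, neg = c.positives, c.negatives
        # orientation: positive "wins" when it scores lower
        v_pos = (np.sum(pos[:, None] < neg[None, :], axis=1)
                 + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=1)) / neg.size
        v_neg = (np.sum(pos[:, None] < neg[None, :], axis=0)
                 + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=0)) / pos.size
        return v_pos, v_neg

    va_pos, va_neg = placements(controls_a)
    vb_pos, vb_neg = placements(controls_b)
    m, n = va_pos.size, va_neg.size
    s_pos = np.cov(np.vstack([va_pos, vb_pos]))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    cov = s_pos / m + s_neg / n
    return cov  # 2x2 covariance of (AUC_a, AUC_b)


def compare_aucs(
    scores_a: ControlScores,
    scores_b: ControlScores,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "bootstrap",
) -> dict[str, float]:
    """Two-sided p-value for a difference in AUC between two metrics scored
    on the identical control items.

    ``bootstrap`` resamples positives and negatives (paired across metrics)
    ``n_boot`` times; ``delong`` uses the DeLong asymptotic variance.
    """
    if scores_a.positives.size != scores_b.positives.size or \
            scores_a.negatives.size != scores_b.negatives.size:
        raise RocError("score lists must be paired over identical control items")
    auc_a = auc_mann_whitney(scores_a)
    auc_b = auc_mann_whitney(scores_b)
    delta = auc_a - auc_b

    if method == "delong":
        cov = _delong_variance(scores_a, scores_b)
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var <= 0:
            p = 1.0
        else:
            from scipy.stats import norm

            p = float(2 * norm.sf(abs(delta) / np.sqrt(var)))
        return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "p": p}

    if method != "bootstrap":
        raise RocError(f"unknown method {method!r}")
    if n_boot < 1:
        raise RocError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    m = scores_a.positives.size
    n = scores_a.negatives.size
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.integers(0, m, m)
        ineg = rng.integers(0, n, n)
        ca = ControlScores(scores_a.positives[ip], scores_a.negatives[ineg])
        cb = ControlScores(scores_b.positives[ip], scores_b.negatives[ineg])
        deltas[b] = auc_mann_whitney(ca) - auc_mann_whitney(cb)
    # two-sided bootstrap p: how often the resampled difference crosses zero
    frac_le = np.mean(deltas <= 0)
    frac_ge = np.mean(deltas >= 0)
    p = float(min(1.0, 2 * min(frac_le, frac_ge)))
    if delta == 0:
        p = 1.0
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "p": p}
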