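"""Weighted and unweighted discrimination metrics with bootstrap confidence intervals.

All metrics accept an optional per-patient weight vector so that estimates
computed on a non-representative subsample (e.g. survey respondents, or the
phase-2 subsample of a two-phase design) can be reweighted to represent the
full population.  With ``weights=None`` (or any constant weight) every
function reduces exactly to its unweighted textbook definition.

Conventions
-----------
* AUC is the weighted Mann-Whitney concordance: tied scores receive half
  credit.
* AUPRC integrates the precision-recall step curve, evaluating precision at
  each distinct score cut (no interpolation between cuts).  With constant
  scores the value equals the (weighted) outcome prevalence.
* The flag rule at a risk threshold is ``score >= threshold`` (closed on the
  left), so results are bit-reproducible.
* Bootstrap intervals are percentile (2.5/97.5) over seeded patient-level
  resamples; a patient's weight travels with the patient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "weighted_auc",
    "weighted_auprc",
    "tpr_fpr_at_threshold",
    "bootstrap_ci",
    "evaluate_scores",
    "PerformanceReport",
]


def _validate_inputs(scores, labels, weights):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.shape != y.shape:
        raise ValueError(f"scores and labels differ in length: {s.size} vs {y.size}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"labels must be binary 0/1; saw values {uniq[:10]}")
    y = y.astype(int)
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != s.shape:
            raise ValueError("weights must match scores in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    w_case = float(w[y == 1].sum())
    w_ctrl = float(w[y == 0].sum())
    if w_case <= 0:
        raise ValueError("no cases (label 1) with positive weight")
    if w_ctrl <= 0:
        raise ValueError("no controls (label 0) with positive weight")
    return s, y, w


def weighted_auc(scores, labels, weights=None) -> float:
    """Weighted area under the ROC curve (Mann-Whitney concordance).

    Equals ``sum_{i case, j control} w_i w_j [1(s_i > s_j) + 0.5 * 1(s_i = s_j)]
    / (W_case * W_ctrl)`` computed in O(n log n) by sorting.
    """
    s, y, w = _validate_inputs(scores, labels, weights)
    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    w1 = np.where(y == 1, w, 0.0)
    w0 = np.where(y == 0, w, 0.0)
    # group tied scores
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    g1 = np.add.reduceat(w1, starts)
    g0 = np.add.reduceat(w0, starts)
    ctrl_below = np.cumsum(g0) - g0
    num = float(np.sum(g1 * (ctrl_below + 0.5 * g0)))
    return num / (w1.sum() * w0.sum())


def weighted_auprc(scores, labels, weights=None) -> float:
    """Weighted area under the precision-recall step curve.

    Thresholds are the distinct observed scores, descending; precision is
    evaluated at each cut and multiplied by the recall increment.
    """
    s, y, w = _validate_inputs(scores, labels, weights)
    order = np.argsort(-s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    w1 = np.where(y == 1, w, 0.0)
    w0 = np.where(y == 0, w, 0.0)
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    tp = np.cumsum(np.add.reduceat(w1, starts))
    fp = np.cumsum(np.add.reduceat(w0, starts))
    recall = tp / tp[-1]
    precision = tp / (tp + fp)
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(drecall * precision))


def tpr_fpr_at_threshold(scores, labels, weights=None, threshold: float = 0.10):
    """Weighted true/false-positive rates flagging ``score >= threshold``.

    The 10% default mirrors the risk cut commonly used to trigger
    serious-illness conversations in oncology practices.
    """
    s, y, w = _validate_inputs(scores, labels, weights)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1); got {threshold}")
    flag = s >= threshold
    w1 = np.where(y == 1, w, 0.0)
    w0 = np.where(y == 0, w, 0.0)
    # clip away float-summation noise so rates are exactly within [0, 1]
    tpr = float(min(1.0, max(0.0, w1[flag].sum() / w1.sum())))
    fpr = float(min(1.0, max(0.0, w0[flag].sum() / w0.sum())))
    return tpr, fpr


def _resample_indices(rng: np.random.Generator, y: np.ndarray, w: np.ndarray,
                      max_redraws: int = 1000):
    """Draw a with-replacement resample that retains both outcome classes."""
    n = y.size
    redraws = 0
    while True:
        idx = rng.integers(0, n, size=n)
        yi, wi = y[idx], w[idx]
        if wi[yi == 1].sum() > 0 and wi[yi == 0].sum() > 0:
            return idx, redraws
        redraws += 1
        if redraws >= max_redraws:
            raise RuntimeError(
                "could not draw a bootstrap resample containing both classes; "
                "the evaluation set is too small or too imbalanced")


def bootstrap_ci(metric: Callable, scores, labels, weights=None,
                 n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05):
    """Percentile bootstrap interval for ``metric(scores, labels, weights)``.

    Patients are resampled with replacement (weights travel with their
    patient); resamples lacking either class are redrawn and counted via a
    warning.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a stable interval")
    s, y, w = _validate_inputs(scores, labels, weights)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    total_redraws = 0
    for b in range(n_boot):
        idx, redraws = _resample_indices(rng, y, w)
        total_redraws += redraws
        vals[b] = metric(s[idx], y[idx], w[idx])
    if total_redraws:
        warnings.warn(f"{total_redraws} bootstrap resamples were redrawn for "
                      "lacking both outcome classes", stacklevel=2)
    low, high = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


@dataclass
class PerformanceReport:
    """Point estimates and bootstrap CIs for one model on one evaluation set."""

    model_label: str
    auc: float
    auprc: float
    tpr: float
    fpr: float
    auc_ci: tuple = (float("nan"), float("nan"))
    auprc_ci: tuple = (float("nan"), float("nan"))
    tpr_ci: tuple = (float("nan"), float("nan"))
    fpr_ci: tuple = (float("nan"), float("nan"))
    threshold: float = 0.10
    n_evaluated: int = 0
    n_bootstrap: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model_label": self.model_label,
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "auprc": self.auprc, "auprc_ci": list(self.auprc_ci),
            "tpr": self.tpr, "tpr_ci": list(self.tpr_ci),
            "fpr": self.fpr, "fpr_ci": list(self.fpr_ci),
            "threshold": self.threshold,
            "n_evaluated": self.n_evaluated,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }
        d.update(self.extra)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _point_metrics(s, y, w, threshold):
    auc = weighted_auc(s, y, w)
    auprc = weighted_auprc(s, y, w)
    tpr, fpr = tpr_fpr_at_threshold(s, y, w, threshold)
    return auc, auprc, tpr, fpr


def evaluate_scores(scores, labels, weights=None, threshold: float = 0.10,
                    n_boot: int = 1000, seed: int = 0,
                    label: str = "model") -> PerformanceReport:
    """Full performance report: AUC/AUPRC/TPR/FPR with a shared patient bootstrap.

    All four intervals come from the same resamples so they are mutually
    consistent.  ``n_boot=0`` skips the bootstrap (point estimates only).
    Percentile bounds are expanded, if necessary, to contain the point
    estimate so that reported intervals always bracket the reported value.
    """
    s, y, w = _validate_inputs(scores, labels, weights)
    auc, auprc, tpr, fpr = _point_metrics(s, y, w, threshold)
    report = PerformanceReport(
        model_label=label, auc=auc, auprc=auprc, tpr=tpr, fpr=fpr,
        threshold=threshold, n_evaluated=int(s.size), n_bootstrap=n_boot,
        seed=seed)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = np.empty((n_boot, 4))
        for b in range(n_boot):
            idx, _ = _resample_indices(rng, y, w)
            vals[b] = _point_metrics(s[idx], y[idx], w[idx], threshold)
        lo = np.percentile(vals, 2.5, axis=0)
        hi = np.percentile(vals, 97.5, axis=0)
        pts = np.array([auc, auprc, tpr, fpr])
        lo = np.minimum(lo, pts)
        hi = np.maximum(hi, pts)
        report.auc_ci = (float(lo[0]), float(hi[0]))
        report.auprc_ci = (float(lo[1]), float(hi[1]))
        report.tpr_ci = (float(lo[2]), float(hi[2]))
        report.fpr_ci = (float(lo[3]), float(hi[3]))
    return report
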