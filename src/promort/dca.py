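"""Decision-curve analysis on the standardized net benefit scale.

The standardized net benefit (sNB) of flagging patients whose predicted risk
meets or exceeds a threshold t, in a population with outcome prevalence pi, is

    sNB(t) = TPR(t) - [t / (1 - t)] * [(1 - pi) / pi] * FPR(t)

i.e. the true-positive rate minus the false-positive rate weighted by the
odds of the threshold times the inverse odds of the prevalence.  sNB has a
maximum of 1, attained only when TPR = 1 and FPR = 0, and can be read as the
fraction of the maximum achievable clinical utility delivered by the model at
that risk preference.  At t = pi the weight is 1 and sNB reduces to
Youden's TPR - FPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import _resample_indices, _validate_inputs, tpr_fpr_at_threshold

__all__ = [
    "standardized_net_benefit",
    "decision_curve",
    "dominance_summary",
    "DecisionCurveResult",
    "DominanceSummary",
    "default_threshold_grid",
]


def default_threshold_grid() -> np.ndarray:
    """Risk thresholds 0.01..0.50 in steps of 0.01."""
    return np.round(np.arange(1, 51) / 100.0, 2)


def standardized_net_benefit(tpr: float, fpr: float, threshold: float,
                             prevalence: float) -> float:
    """sNB = TPR - [t/(1-t)] * [(1-pi)/pi] * FPR, exact arithmetic."""
    if not 0.0 <= tpr <= 1.0 or not 0.0 <= fpr <= 1.0:
        raise ValueError("tpr and fpr must lie in [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1); got {threshold}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(
            f"prevalence must lie strictly in (0, 1) for the inverse odds to "
            f"exist; got {prevalence}")
    weight = (threshold / (1.0 - threshold)) * ((1.0 - prevalence) / prevalence)
    return tpr - weight * fpr


@dataclass
class DecisionCurveResult:
    """Standardized net benefit across a grid of risk thresholds."""

    model_label: str
    thresholds: np.ndarray
    snb: np.ndarray
    prevalence: float
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        data = {"threshold": self.thresholds, "snb": self.snb}
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _curve_values(s, y, w, grid, prevalence):
    out = np.empty(grid.size)
    for k, t in enumerate(grid):
        tpr, fpr = tpr_fpr_at_threshold(s, y, w, t)
        out[k] = standardized_net_benefit(tpr, fpr, t, prevalence)
    return out


def decision_curve(scores, labels, weights=None,
                   threshold_grid: Optional[Sequence[float]] = None,
                   prevalence: Optional[float] = None,
                   n_boot: int = 0, seed: int = 0,
                   label: str = "model") -> DecisionCurveResult:
    """Decision curve of a score vector over a threshold grid.

    ``prevalence=None`` uses the weighted outcome prevalence of the
    evaluation population; pass a value to override (e.g. a known cohort
    prevalence).  ``n_boot>0`` adds percentile bootstrap bands from
    patient-level resamples; the prevalence is re-estimated in each resample
    unless it was supplied explicitly.
    """
    s, y, w = _validate_inputs(scores, labels, weights)
    grid = default_threshold_grid() if threshold_grid is None else np.asarray(
        threshold_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold_grid must be strictly increasing")
    if grid[0] <= 0.0 or grid[-1] >= 1.0:
        raise ValueError("threshold_grid values must lie in (0, 1)")
    fixed_pi = prevalence is not None
    pi = float(prevalence) if fixed_pi else float(np.average(y, weights=w))
    snb = _curve_values(s, y, w, grid, pi)
    result = DecisionCurveResult(model_label=label, thresholds=grid, snb=snb,
                                 prevalence=pi)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            idx, _ = _resample_indices(rng, y, w)
            pi_b = pi if fixed_pi else float(np.average(y[idx], weights=w[idx]))
            vals[b] = _curve_values(s[idx], y[idx], w[idx], grid, pi_b)
        result.ci_low = np.percentile(vals, 2.5, axis=0)
        result.ci_high = np.percentile(vals, 97.5, axis=0)
    return result


@dataclass
class DominanceSummary:
    """Which model attains the highest sNB at each threshold."""

    table: pd.DataFrame            # threshold, best_model (ties joined by '|')
    fraction_maximal: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def dominance_summary(curves: Sequence[DecisionCurveResult],
                      tie_tol: float = 1e-12) -> DominanceSummary:
    """Per-threshold argmax over models; ties are reported, not broken.

    ``fraction_maximal[label]`` is the fraction of grid points at which that
    model attains the maximum (ties count for every tied model).
    """
    if len(curves) == 0:
        raise ValueError("need at least one decision curve")
    grid = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != grid.shape or not np.allclose(
                c.thresholds, grid, atol=0, rtol=0):
            raise ValueError(
                f"threshold grids differ between '{curves[0].model_label}' "
                f"and '{c.model_label}'")
    labels = [c.model_label for c in curves]
    snb = np.vstack([c.snb for c in curves])          # models x thresholds
    best = snb.max(axis=0)
    maximal = snb >= best - tie_tol
    winners = ["|".join(l for l, m in zip(labels, col) if m)
               for col in maximal.T]
    table = pd.DataFrame({"threshold": grid, "best_model": winners})
    frac = {l: float(maximal[i].mean()) for i, l in enumerate(labels)}
    return DominanceSummary(table=table, fraction_maximal=frac)
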