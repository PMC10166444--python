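"""Two-phase EHR+PRO model: selection modeling, IPW fitting and evaluation.

PROs exist only for the completer subsample (phase 2) while EHR features
exist for everyone (phase 1), and completion is informative -- completers
differ systematically from non-completers.  A complete-case analysis is
therefore biased for the full cohort.  The standard two-phase design
estimator used here

1. models the probability of PRO completion given phase-1 data (the EHR
   logit risk plus configurable EHR covariates),
2. weights each completer by the inverse of that probability
   (Horvitz-Thompson), with percentile truncation to bound variance, and
3. uses those weights both when fitting the combined EHR+PRO logistic model
   and when estimating its performance metrics, so completer-based results
   represent the full cohort.

When completion is completely at random the weights are constant and every
estimate reduces to its unweighted complete-case counterpart.  The IPW
estimator is one member of the family of two-phase estimators; it is kept
behind small composable functions so an augmented or likelihood-based
variant could be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .cohort import pro_columns
from .metrics import PerformanceReport, _point_metrics
from .risk import RiskModel

__all__ = ["SelectionModel", "SelectionWeights", "CombinedModel",
           "fit_selection_model", "compute_weights", "fit_combined_model",
           "evaluate_two_phase"]

EHR_LOGIT = "ehr_logit"


@dataclass
class SelectionModel:
    """Logistic model of PRO completion given phase-1 (EHR) data."""

    covariate_names: list
    intercept: float
    coefficients: np.ndarray
    fitted: pd.DataFrame           # patient_id, p_hat
    completion_rate: float
    degenerate: bool = False       # completion rate 0 or 1: all weights 1
    ehr_model: Optional[RiskModel] = None

    def design(self, cohort: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.covariate_names:
            if name == EHR_LOGIT:
                cols.append(self.ehr_model.linear_predictor(cohort))
            else:
                cols.append(cohort[name].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        if self.degenerate:
            return np.ones(len(cohort))
        return expit(self.intercept + self.design(cohort) @ self.coefficients)


def fit_selection_model(cohort: pd.DataFrame, ehr_model: RiskModel,
                        extra_covariates: Sequence[str] = ("ehr_0001",),
                        ) -> SelectionModel:
    """Fit completion ~ EHR logit risk + named EHR covariates (logistic).

    If every patient (or none) completed, selection carries no information
    and a degenerate model with unit weights is returned with a warning.
    """
    y = cohort["pro_complete"].to_numpy().astype(int)
    rate = float(y.mean())
    names = [EHR_LOGIT] + [c for c in extra_covariates]
    for c in extra_covariates:
        if c not in cohort.columns:
            raise ValueError(f"selection covariate '{c}' not in cohort")
    if rate in (0.0, 1.0):
        warnings.warn("completion rate is %.0f%%; selection model is "
                      "degenerate and all weights are 1" % (100 * rate),
                      stacklevel=2)
        return SelectionModel(
            covariate_names=names, intercept=np.inf if rate else -np.inf,
            coefficients=np.zeros(len(names)),
            fitted=pd.DataFrame({"patient_id": cohort["patient_id"],
                                 "p_hat": np.ones(len(cohort))}),
            completion_rate=rate, degenerate=True, ehr_model=ehr_model)
    model = SelectionModel(covariate_names=names, intercept=0.0,
                           coefficients=np.zeros(len(names)),
                           fitted=pd.DataFrame(), completion_rate=rate,
                           ehr_model=ehr_model)
    X = model.design(cohort)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10,
                             max_iter=5000)
    clf.fit(X, y)
    model.intercept = float(clf.intercept_[0])
    model.coefficients = clf.coef_.ravel().copy()
    p_hat = expit(model.intercept + X @ model.coefficients)
    model.fitted = pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy(),
                                 "p_hat": p_hat})
    return model


@dataclass
class SelectionWeights:
    """Inverse-probability weights for completers, percentile-truncated."""

    table: pd.DataFrame            # patient_id, p_hat, weight (completers)
    truncation_percentiles: tuple
    truncation_bounds: tuple

    def for_cohort(self, cohort: pd.DataFrame) -> np.ndarray:
        """Weights aligned to the completer rows of ``cohort`` (in order)."""
        comp = cohort[cohort["pro_complete"] == 1]
        merged = comp[["patient_id"]].merge(self.table, on="patient_id",
                                            how="left")
        if merged["weight"].isna().any():
            missing = merged.loc[merged["weight"].isna(), "patient_id"]
            raise ValueError(
                f"no weight for completer(s) {list(missing[:5])}; weights "
                f"must be computed on the same population they are applied to")
        return merged["weight"].to_numpy()


def compute_weights(selection: SelectionModel, cohort: pd.DataFrame,
                    truncation: tuple = (1.0, 99.0)) -> SelectionWeights:
    """w_i = 1 / p_hat_i for completers, truncated at weight percentiles.

    The sum of weights over completers estimates the full-cohort size
    (Horvitz-Thompson); truncation (default 1st/99th percentile of the
    completer weights) trades a little bias for bounded variance.  A
    numerically zero p_hat is caught by the truncation ceiling.
    """
    comp = cohort[cohort["pro_complete"] == 1]
    p_hat = np.clip(selection.predict(comp), 1e-12, 1.0)
    w = 1.0 / p_hat
    lo, hi = np.percentile(w, truncation)
    w_trunc = np.clip(w, lo, hi)
    table = pd.DataFrame({"patient_id": comp["patient_id"].to_numpy(),
                          "p_hat": p_hat, "weight": w_trunc})
    return SelectionWeights(table=table,
                            truncation_percentiles=tuple(truncation),
                            truncation_bounds=(float(lo), float(hi)))


@dataclass
class CombinedModel:
    """Second-phase logistic model: death ~ EHR logit + selected PROs.

    The EHR logit enters as an estimated covariate (its coefficient is not
    fixed at 1), so the combined model can recalibrate the phase-1 risk.
    """

    ehr_model: RiskModel
    pro_terms: list
    intercept: float
    coefficients: np.ndarray       # aligned with [EHR_LOGIT] + pro_terms
    metadata: dict = field(default_factory=dict)

    @property
    def term_names(self) -> list:
        return [EHR_LOGIT] + list(self.pro_terms)

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        cols = [self.ehr_model.linear_predictor(cohort)]
        for t in self.pro_terms:
            v = cohort[t].to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(
                    f"PRO term '{t}' has missing values; the combined model "
                    f"scores completers only")
            cols.append(v)
        return self.intercept + np.column_stack(cols) @ self.coefficients

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return np.clip(expit(self.linear_predictor(cohort)), 1e-300,
                       1.0 - 1e-16)

    def to_dict(self) -> dict:
        return {"pro_terms": list(self.pro_terms),
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "term_names": self.term_names,
                "metadata": self.metadata}


def _weighted_glm(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  names: Sequence[str]):
    """Weighted logistic fit with robust (sandwich) standard errors."""
    design = sm.add_constant(pd.DataFrame(X, columns=list(names)),
                             has_constant="add")
    glm = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # freq_weights emit df warnings
        return glm.fit(cov_type="HC1")


def fit_combined_model(cohort: pd.DataFrame, ehr_model: RiskModel,
                       weights: SelectionWeights,
                       selection_strategy: str = "backward",
                       alpha: float = 0.05,
                       candidate_pros: Optional[Sequence[str]] = None,
                       ) -> CombinedModel:
    """Weighted logistic fit of death on EHR logit + a selected PRO subset.

    Fit on completers of the supplied (training) cohort with their
    inverse-probability weights.  The default PRO-subset strategy is
    weighted backward elimination on robust Wald tests at ``alpha``; the
    EHR logit term is never dropped.  ``selection_strategy="none"`` keeps
    all candidate PROs.
    """
    if selection_strategy not in ("backward", "none"):
        raise ValueError("selection_strategy must be 'backward' or 'none'")
    comp = cohort[cohort["pro_complete"] == 1]
    y = comp["death180"].to_numpy().astype(int)
    w = weights.for_cohort(cohort)
    # weighted case mass: the number of cohort cases the completer cases
    # represent; equals the raw completer case count under unit weights
    case_mass = float((w * y).sum())
    if case_mass < 20:
        raise ValueError(
            f"weighted completer case mass {case_mass:.1f} "
            f"({int(y.sum())} raw cases); at least 20 are needed for a "
            f"stable weighted fit")
    pros = list(candidate_pros) if candidate_pros else pro_columns(cohort)
    ehr_lp = ehr_model.linear_predictor(comp)

    terms = list(pros)
    eliminated = []
    while True:
        X = np.column_stack([ehr_lp] + [comp[t].to_numpy(dtype=float)
                                        for t in terms])
        res = _weighted_glm(X, y, w, [EHR_LOGIT] + terms)
        if selection_strategy == "none" or not terms:
            break
        pvals = {t: float(res.pvalues[t]) for t in terms}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        terms.remove(worst)
        eliminated.append((worst, pvals[worst]))

    params = res.params
    coefs = np.array([float(params[EHR_LOGIT])]
                     + [float(params[t]) for t in terms])
    return CombinedModel(
        ehr_model=ehr_model, pro_terms=terms,
        intercept=float(params["const"]), coefficients=coefs,
        metadata={"n_completers": int(len(comp)),
                  "n_completer_cases": int(y.sum()),
                  "sum_weights": float(w.sum()),
                  "alpha": alpha, "strategy": selection_strategy,
                  "eliminated": [[t, p] for t, p in eliminated]})


def evaluate_two_phase(model: CombinedModel, test_cohort: pd.DataFrame,
                       extra_covariates: Sequence[str] = ("ehr_0001",),
                       truncation: tuple = (1.0, 99.0),
                       threshold: float = 0.10, n_boot: int = 1000,
                       seed: int = 0,
                       label: str = "ehr_pro") -> PerformanceReport:
    """IPW performance of the combined model, representative of the full test set.

    The selection model is fitted on the evaluation cohort itself, weights
    are computed for its completers, and weighted AUC/AUPRC/TPR/FPR are
    estimated over completers.  Bootstrap resamples draw PATIENTS of the
    full test cohort (completers and non-completers) and re-estimate the
    selection model and weights inside each resample, so weight-estimation
    uncertainty is part of the interval.
    """
    sel = fit_selection_model(test_cohort, model.ehr_model, extra_covariates)
    wts = compute_weights(sel, test_cohort, truncation)
    comp = test_cohort[test_cohort["pro_complete"] == 1]
    if int(comp["death180"].sum()) == 0:
        raise ValueError("no completer cases in the evaluation cohort")
    scores = model.predict(comp)
    y = comp["death180"].to_numpy().astype(int)
    w = wts.for_cohort(test_cohort)
    auc, auprc, tpr, fpr = _point_metrics(scores, y, w, threshold)
    report = PerformanceReport(model_label=label, auc=auc, auprc=auprc,
                               tpr=tpr, fpr=fpr, threshold=threshold,
                               n_evaluated=int(len(comp)), n_bootstrap=n_boot,
                               seed=seed,
                               extra={"sum_weights": float(w.sum()),
                                      "n_test_cohort": int(len(test_cohort))})
    if n_boot <= 0:
        return report
    rng = np.random.default_rng(seed)
    n = len(test_cohort)
    vals = np.empty((n_boot, 4))
    b = 0
    guard = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        boot = test_cohort.iloc[idx]
        bcomp = boot[boot["pro_complete"] == 1]
        guard += 1
        if guard > n_boot * 20:
            raise RuntimeError("too many degenerate bootstrap resamples")
        if bcomp["death180"].nunique() < 2 or boot["pro_complete"].nunique() < 2:
            continue
        # duplicate ids within a resample are intentional: refit on the
        # resample, score and weight its completer rows positionally
        bsel = fit_selection_model(boot.reset_index(drop=True),
                                   model.ehr_model, extra_covariates)
        p_hat = np.clip(bsel.predict(bcomp), 1e-12, 1.0)
        bw = 1.0 / p_hat
        lo, hi = np.percentile(bw, truncation)
        bw = np.clip(bw, lo, hi)
        vals[b] = _point_metrics(model.predict(bcomp),
                                 bcomp["death180"].to_numpy().astype(int),
                                 bw, threshold)
        b += 1
    lo = np.percentile(vals, 2.5, axis=0)
    hi = np.percentile(vals, 97.5, axis=0)
    pts = np.array([auc, auprc, tpr, fpr])
    lo, hi = np.minimum(lo, pts), np.maximum(hi, pts)
    report.auc_ci = (float(lo[0]), float(hi[0]))
    report.auprc_ci = (float(lo[1]), float(hi[1]))
    report.tpr_ci = (float(lo[2]), float(hi[2]))
    report.fpr_ci = (float(lo[3]), float(hi[3]))
    return report
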