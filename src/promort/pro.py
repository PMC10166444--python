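"""PRO-only risk model, inter-PRO correlations, and PRO-mortality odds ratios.

All analyses run on assessment completers only.  Likert items enter the
logistic models as single linear covariates (odds ratios are per Likert
step; rash is 0/1), correlations are Spearman rank correlations because the
items are ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import pro_columns
from .risk import RiskModel

__all__ = ["AssociationResult", "CorrelationMatrix", "pro_correlations",
           "univariable_or", "adjusted_or", "fit_pro_model",
           "association_table"]


@dataclass
class AssociationResult:
    """One PRO's mortality odds ratio (per Likert step) with 95% Wald CI."""

    pro_name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted: bool
    n_used: int

    def __post_init__(self):
        if not (0.0 < self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"inconsistent OR/CI for {self.pro_name}: "
                f"{self.ci_low} / {self.odds_ratio} / {self.ci_high}")


@dataclass
class CorrelationMatrix:
    """Pairwise rank correlations between PRO items over completers."""

    pro_names: list
    values: pd.DataFrame
    method: str = "spearman"

    def __getitem__(self, pair):
        a, b = pair
        return float(self.values.loc[a, b])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def _completers(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["pro_complete"] == 1]


def pro_correlations(cohort: pd.DataFrame,
                     names: Optional[Sequence[str]] = None) -> CorrelationMatrix:
    """Spearman correlation matrix of PRO items among completers.

    A constant item yields NaN against every other item (undefined, not
    zero), matching pandas' convention.
    """
    comp = _completers(cohort)
    if len(comp) < 3:
        raise ValueError("need at least 3 completers for correlations")
    cols = [f"pro_{n}" for n in names] if names else pro_columns(cohort)
    values = comp[cols].corr(method="spearman")
    short = [c[4:] for c in cols]
    values.index = short
    values.columns = short
    return CorrelationMatrix(pro_names=short, values=values)


def _wald_or(result, term: str, pro_name: str, adjusted: bool,
             n_used: int) -> AssociationResult:
    b = float(result.params[term])
    se = float(result.bse[term])
    return AssociationResult(
        pro_name=pro_name, odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * se)),
        ci_high=float(np.exp(b + 1.959963984540054 * se)),
        adjusted=adjusted, n_used=n_used)


def _logit_fit(Xdf: pd.DataFrame, y: np.ndarray):
    try:
        model = sm.Logit(y, sm.add_constant(Xdf, has_constant="add"))
        return model.fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "logistic fit failed (perfect separation or singular design); "
            "consider a small ridge penalty") from exc


def univariable_or(cohort: pd.DataFrame, pro_name: str,
                   outcome_col: str = "death180") -> AssociationResult:
    """OR of 180-day mortality per step of one PRO, completers only."""
    comp = _completers(cohort)
    col = f"pro_{pro_name}"
    if col not in comp.columns:
        raise ValueError(f"no PRO column '{col}' in cohort")
    y = comp[outcome_col].to_numpy().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant among completers")
    res = _logit_fit(comp[[col]], y)
    return _wald_or(res, col, pro_name, adjusted=False, n_used=len(comp))


def adjusted_or(cohort: pd.DataFrame, pro_name: str,
                ehr_model: RiskModel,
                outcome_col: str = "death180") -> AssociationResult:
    """OR of one PRO adjusted for the continuous EHR-predicted mortality risk.

    The EHR risk enters on the log-odds scale (the natural scale of the
    logistic model, on which a correctly specified EHR model is exactly
    linear); a PRO carrying no information beyond the EHR risk then has a
    null adjusted effect.
    """
    comp = _completers(cohort)
    col = f"pro_{pro_name}"
    if col not in comp.columns:
        raise ValueError(f"no PRO column '{col}' in cohort")
    y = comp[outcome_col].to_numpy().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant among completers")
    X = comp[[col]].copy()
    X["ehr_risk_logit"] = ehr_model.linear_predictor(comp)
    res = _logit_fit(X, y)
    return _wald_or(res, col, pro_name, adjusted=True, n_used=len(comp))


def association_table(cohort: pd.DataFrame,
                      ehr_model: Optional[RiskModel] = None,
                      names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Univariable (and, given an EHR model, adjusted) ORs for every PRO."""
    cols = [f"pro_{n}" for n in names] if names else pro_columns(cohort)
    rows = []
    for col in cols:
        name = col[4:]
        r = univariable_or(cohort, name)
        rows.append({"pro_name": name, "odds_ratio": r.odds_ratio,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "adjusted": False, "n_used": r.n_used})
        if ehr_model is not None:
            r = adjusted_or(cohort, name, ehr_model)
            rows.append({"pro_name": name, "odds_ratio": r.odds_ratio,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "adjusted": True, "n_used": r.n_used})
    return pd.DataFrame(rows)


def fit_pro_model(cohort: pd.DataFrame, ridge: float = 0.0,
                  outcome_col: str = "death180") -> RiskModel:
    """Unpenalized logistic model of mortality on all PRO items (completers).

    With a dozen covariates and thousands of completers no penalty is
    needed; if the fit separates, retry with a small ``ridge`` (e.g. 1e-6,
    per-sample L2) as a documented fallback.
    """
    comp = _completers(cohort)
    cols = pro_columns(cohort)
    y = comp[outcome_col].to_numpy().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant among completers")
    Xdf = comp[cols]
    if ridge > 0.0:
        from sklearn.linear_model import LogisticRegression
        n = len(comp)
        clf = LogisticRegression(l1_ratio=0.0, C=1.0 / (n * ridge),
                                 solver="lbfgs", tol=1e-10, max_iter=5000)
        clf.fit(Xdf.to_numpy(dtype=float), y)
        intercept = float(clf.intercept_[0])
        beta = clf.coef_.ravel().copy()
    else:
        res = _logit_fit(Xdf, y)
        intercept = float(res.params["const"])
        beta = np.array([float(res.params[c]) for c in cols])
    return RiskModel(feature_names=cols, intercept=intercept,
                     coefficients=beta, penalty=ridge if ridge > 0 else None,
                     metadata={"n": int(len(comp)), "model": "pro_logistic"})
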