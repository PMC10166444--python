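"""Seeded synthetic oncology cohorts with EHR features, PROs and mortality.

The generator emulates the data structure of a two-site oncology cohort in
which every patient has ~200 structured EHR features (binary
demographic/comorbidity indicators plus standard-normal "lab" values) and a
180-day mortality outcome, while only a covariate-dependent subset completes
a 12-item patient-reported-outcome (PRO) assessment (11 symptom/function
items on a 1-5 Likert scale plus a 0/1 rash item).

Generative model
----------------
* EHR features X: Bernoulli indicators and independent standard normals.
* Latent PRO vector: each item j is ``l_j * z + sqrt(1-l_j^2) * u_j`` where
  ``z`` is the standardized EHR mortality score (so sicker patients report
  worse symptoms) and ``u`` is multivariate normal whose correlation is
  adjusted so the LATENT inter-item correlation matches the configured
  target exactly.  Likert items are the latent values cut at per-item
  thresholds; discretization attenuates the observed (Spearman) correlation
  relative to the latent target.
* Mortality: Bernoulli with logit = baseline + X @ ehr_effects +
  codes @ pro_effects, where codes are the coded PRO items (1-5, rash 0/1).
* PRO completion: Bernoulli with logit = selection intercept + effects of
  named EHR columns and/or the standardized EHR risk score, giving
  informative (non-representative) completion.

Defaults are calibrated so a tertiary-style cohort has ~5.7% mortality and
~54.7% PRO completion and a community-style cohort ~3.2% and ~31.4%, with
completers enriched for a "White/managed-care-like" indicator and for lower
EHR risk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "PRO_NAMES",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "calibrate_baseline",
    "calibrate_selection_intercept",
    "make_config",
    "tertiary_config",
    "community_config",
    "default_latent_correlation",
    "default_likert_cutpoints",
    "ehr_columns",
    "pro_columns",
    "write_cohort",
    "read_cohort",
]

#: The 12 PRO items: 11 Likert-coded symptom/function items and binary rash.
PRO_NAMES = (
    "performance_status",
    "quality_of_life",
    "fatigue",
    "appetite_loss",
    "nausea",
    "constipation",
    "shortness_of_breath",
    "anxiety",
    "sadness",
    "numbness_tingling",
    "pain",
    "rash",
)

#: Default Likert cell masses, skewed toward mild symptoms.
_LIKERT_MASS = (0.40, 0.25, 0.18, 0.10, 0.07)

#: Default latent pairwise correlations for named item pairs; all other
#: symptom-symptom pairs default to 0.30 and rash pairs to 0.10.
_NAMED_LATENT_CORR = {
    ("performance_status", "fatigue"): 0.69,
    ("performance_status", "quality_of_life"): 0.58,
    ("performance_status", "appetite_loss"): 0.50,
    ("fatigue", "quality_of_life"): 0.60,
    ("fatigue", "appetite_loss"): 0.51,
    ("anxiety", "sadness"): 0.72,
}

#: Default conditional (EHR-adjusted) odds ratios per Likert step.  Items not
#: listed have no independent effect; their marginal association with death
#: arises through the shared EHR-risk loading and inter-item correlation.
_DEFAULT_PRO_OR = {
    "performance_status": 1.53,
    "quality_of_life": 1.45,
    "numbness_tingling": 1.30,
    "nausea": 1.25,
}

_DEFAULT_RISK_LOADING = 0.12
_DEFAULT_RASH_LOADING = 0.05
_DEFAULT_RASH_THRESHOLD = float(norm.ppf(0.85))   # ~15% rash prevalence


def default_likert_cutpoints(n_items: int = 11) -> np.ndarray:
    """Per-item latent thresholds implying the default Likert cell masses."""
    cum = np.cumsum(_LIKERT_MASS)[:-1]
    row = norm.ppf(cum)
    return np.tile(row, (n_items, 1))


def default_latent_correlation(pro_names: Sequence[str] = PRO_NAMES) -> np.ndarray:
    names = list(pro_names)
    k = len(names)
    corr = np.full((k, k), 0.30)
    if "rash" in names:
        r = names.index("rash")
        corr[r, :] = corr[:, r] = 0.10
    for (a, b), v in _NAMED_LATENT_CORR.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = v
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic site cohort."""

    n_patients: int
    n_ehr_features: int = 200
    n_binary_features: int = 40
    binary_prevalences: Optional[np.ndarray] = None
    ehr_effect_vector: Optional[np.ndarray] = None
    baseline_log_odds: float = 0.0
    pro_names: Sequence[str] = PRO_NAMES
    pro_latent_correlation: Optional[np.ndarray] = None
    pro_effect_vector: Optional[np.ndarray] = None
    pro_risk_loadings: Optional[np.ndarray] = None
    likert_cutpoints: Optional[np.ndarray] = None
    rash_threshold: float = _DEFAULT_RASH_THRESHOLD
    selection_coefficients: dict = field(default_factory=dict)
    site: str = "tertiary"
    seed: int = 0

    def __post_init__(self):
        k = len(self.pro_names)
        n_likert = k - 1 if "rash" in self.pro_names else k
        if self.binary_prevalences is None:
            p = np.full(self.n_binary_features, 0.20)
            if self.n_binary_features >= 1:
                p[0] = 0.67          # White/managed-care-like indicator
            if self.n_binary_features >= 2:
                p[1] = 0.31
            self.binary_prevalences = p
        if self.ehr_effect_vector is None:
            self.ehr_effect_vector = np.zeros(self.n_ehr_features)
        if self.pro_latent_correlation is None:
            self.pro_latent_correlation = default_latent_correlation(self.pro_names)
        if self.pro_effect_vector is None:
            self.pro_effect_vector = np.array(
                [np.log(_DEFAULT_PRO_OR.get(nm, 1.0)) for nm in self.pro_names])
        if self.pro_risk_loadings is None:
            self.pro_risk_loadings = np.array(
                [_DEFAULT_RASH_LOADING if nm == "rash" else _DEFAULT_RISK_LOADING
                 for nm in self.pro_names])
        if self.likert_cutpoints is None:
            self.likert_cutpoints = default_likert_cutpoints(n_likert)
        if not self.selection_coefficients:
            self.selection_coefficients = {"intercept": 0.0}
        for attr in ("binary_prevalences", "ehr_effect_vector",
                     "pro_latent_correlation", "pro_effect_vector",
                     "pro_risk_loadings", "likert_cutpoints"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        self.pro_names = tuple(self.pro_names)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.n_binary_features <= self.n_ehr_features:
            raise ValueError("n_binary_features must lie in [0, n_ehr_features]")
        k = len(self.pro_names)
        n_likert = k - 1 if "rash" in self.pro_names else k
        if self.ehr_effect_vector.shape != (self.n_ehr_features,):
            raise ValueError(
                f"ehr_effect_vector has length {self.ehr_effect_vector.size}, "
                f"expected {self.n_ehr_features}")
        if self.pro_effect_vector.shape != (k,):
            raise ValueError(
                f"pro_effect_vector has length {self.pro_effect_vector.size}, "
                f"expected {k}")
        if self.pro_risk_loadings.shape != (k,):
            raise ValueError("pro_risk_loadings must have one entry per PRO")
        if np.any(np.abs(self.pro_risk_loadings) >= 1.0):
            raise ValueError("pro_risk_loadings must lie in (-1, 1)")
        if self.binary_prevalences.shape != (self.n_binary_features,):
            raise ValueError("binary_prevalences must have one entry per "
                             "binary feature")
        C = self.pro_latent_correlation
        if C.shape != (k, k):
            raise ValueError(f"pro_latent_correlation must be {k}x{k}")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("pro_latent_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("pro_latent_correlation must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"pro_latent_correlation is not positive semi-definite: "
                f"smallest eigenvalue {eigmin:.3e}")
        if self.likert_cutpoints.shape != (n_likert, 4):
            raise ValueError(
                f"likert_cutpoints must be {n_likert}x4 (4 thresholds per "
                f"Likert item)")
        if np.any(np.diff(self.likert_cutpoints, axis=1) <= 0):
            raise ValueError("likert_cutpoints must be strictly increasing "
                             "within each item")
        for name in self.selection_coefficients:
            if name in ("intercept", "risk_linpred"):
                continue
            if not _is_ehr_column(name, self.n_ehr_features):
                raise ValueError(
                    f"selection coefficient refers to unknown covariate "
                    f"'{name}' (use 'intercept', 'risk_linpred' or an "
                    f"ehr_#### column)")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_patients": int(self.n_patients),
            "n_ehr_features": int(self.n_ehr_features),
            "n_binary_features": int(self.n_binary_features),
            "binary_prevalences": self.binary_prevalences.tolist(),
            "ehr_effect_vector": self.ehr_effect_vector.tolist(),
            "baseline_log_odds": float(self.baseline_log_odds),
            "pro_names": list(self.pro_names),
            "pro_latent_correlation": self.pro_latent_correlation.tolist(),
            "pro_effect_vector": self.pro_effect_vector.tolist(),
            "pro_risk_loadings": self.pro_risk_loadings.tolist(),
            "likert_cutpoints": self.likert_cutpoints.tolist(),
            "rash_threshold": float(self.rash_threshold),
            "selection_coefficients": {k: float(v) for k, v in
                                       self.selection_coefficients.items()},
            "site": self.site,
            "seed": int(self.seed),
        }
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _is_ehr_column(name: str, n_features: int) -> bool:
    if not name.startswith("ehr_"):
        return False
    try:
        idx = int(name[4:])
    except ValueError:
        return False
    return 1 <= idx <= n_features


def _ehr_names(n_features: int) -> list:
    return [f"ehr_{i + 1:04d}" for i in range(n_features)]


def ehr_columns(df: pd.DataFrame) -> list:
    """EHR feature columns of a cohort table, in order."""
    return sorted([c for c in df.columns if c.startswith("ehr_")])


def pro_columns(df: pd.DataFrame) -> list:
    """PRO item columns of a cohort table, in generator order when possible."""
    cols = [f"pro_{n}" for n in PRO_NAMES if f"pro_{n}" in df.columns]
    extra = [c for c in df.columns if c.startswith("pro_")
             and c != "pro_complete" and c not in cols]
    return cols + extra


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

def _copula_root(config: GeneratorConfig) -> np.ndarray:
    """Matrix square root of the loading-adjusted latent correlation.

    With loadings l on the shared EHR-risk factor z, the residual u must have
    correlation C_u = (C - l l') / sqrt((1-l^2)(1-l^2)') off-diagonal for the
    total latent correlation to equal the configured target C.
    """
    C = config.pro_latent_correlation
    l = config.pro_risk_loadings
    denom = np.sqrt(np.outer(1.0 - l ** 2, 1.0 - l ** 2))
    Cu = (C - np.outer(l, l)) / denom
    np.fill_diagonal(Cu, 1.0)
    vals, vecs = np.linalg.eigh(Cu)
    if vals.min() < -1e-8:
        raise ValueError(
            f"pro_risk_loadings are incompatible with pro_latent_correlation: "
            f"residual correlation has eigenvalue {vals.min():.3e}")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _draw_structure(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Draw EHR features, latent PROs and coded PRO items for n patients."""
    nb, nf = config.n_binary_features, config.n_ehr_features
    X = np.empty((n, nf))
    X[:, :nb] = (rng.random((n, nb)) < config.binary_prevalences).astype(float)
    X[:, nb:] = rng.standard_normal((n, nf - nb))

    s_ehr = X @ config.ehr_effect_vector
    sd = float(s_ehr.std())
    if sd > 1e-12:
        z = (s_ehr - s_ehr.mean()) / sd
    else:
        # no EHR signal to load on; use an independent standard normal so the
        # PRO correlation structure is preserved
        z = rng.standard_normal(n)

    root = _copula_root(config)
    u = rng.standard_normal((n, len(config.pro_names))) @ root.T
    l = config.pro_risk_loadings
    latent = l * z[:, None] + np.sqrt(1.0 - l ** 2) * u

    codes = np.empty_like(latent)
    j_likert = 0
    for j, name in enumerate(config.pro_names):
        if name == "rash":
            codes[:, j] = (latent[:, j] > config.rash_threshold).astype(float)
        else:
            cuts = config.likert_cutpoints[j_likert]
            codes[:, j] = 1.0 + (latent[:, j][:, None] > cuts).sum(axis=1)
            j_likert += 1

    death_lin = s_ehr + codes @ config.pro_effect_vector
    sel_lin = np.zeros(n)
    names = _ehr_names(nf)
    for cname, coef in config.selection_coefficients.items():
        if cname == "intercept":
            continue
        elif cname == "risk_linpred":
            sel_lin += coef * z
        else:
            sel_lin += coef * X[:, names.index(cname)]
    return X, z, codes, death_lin, sel_lin


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A generated cohort.

    ``data`` is the public cohort table (PRO items blank for
    non-completers); ``complete_data`` additionally carries every patient's
    PRO items and true linear predictors, and exists only because the
    simulation knows them -- it plays the role of the unobservable
    full-information oracle in validation studies.
    """

    data: pd.DataFrame
    complete_data: pd.DataFrame
    config: GeneratorConfig

    @property
    def completers(self) -> pd.DataFrame:
        return self.data[self.data["pro_complete"] == 1]


def generate_cohort(config: GeneratorConfig,
                    seed: Optional[int] = None) -> SyntheticCohort:
    """Generate one cohort; deterministic given (config, seed).

    ``seed=None`` uses ``config.seed``; passing a seed overrides it, which
    lets replicate studies reuse one config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    X, z, codes, death_lin, sel_lin = _draw_structure(config, n, rng)

    p_death = expit(config.baseline_log_odds + death_lin)
    death = (rng.random(n) < p_death).astype(int)

    sel_int = float(config.selection_coefficients.get("intercept", 0.0))
    p_complete = expit(sel_int + sel_lin)
    complete = (rng.random(n) < p_complete).astype(int)

    prefix = (config.site[:1].upper() or "S")
    ids = [f"{prefix}{i + 1:06d}" for i in range(n)]
    cols = {"patient_id": ids, "site": config.site,
            "death180": death, "pro_complete": complete}
    for j, name in enumerate(_ehr_names(config.n_ehr_features)):
        cols[name] = X[:, j]
    for j, name in enumerate(config.pro_names):
        cols[f"pro_{name}"] = codes[:, j]
    cols["true_death_logit"] = config.baseline_log_odds + death_lin
    cols["true_completion_logit"] = sel_int + sel_lin
    full = pd.DataFrame(cols)

    public = full.drop(columns=["true_death_logit", "true_completion_logit"]).copy()
    mask = public["pro_complete"] == 0
    for name in config.pro_names:
        public.loc[mask, f"pro_{name}"] = np.nan
    return SyntheticCohort(data=public, complete_data=full, config=config)


def _solve_intercept(lin: np.ndarray, target: float, what: str) -> float:
    """Intercept b with mean expit(b + lin) == target, by Brent's method."""
    lo, hi = -40.0, 40.0
    f = lambda b: float(np.mean(expit(b + lin))) - target
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"target {what} {target} is unattainable; achievable range is "
            f"[{flo + target:.4f}, {fhi + target:.4f}]")
    return float(brentq(f, lo, hi, xtol=1e-10))


def calibrate_baseline(config: GeneratorConfig, target_prevalence: float,
                       n_mc: int = 200_000, seed: Optional[int] = None) -> float:
    """Baseline log-odds giving the target expected outcome prevalence.

    Simulates ``n_mc`` patients' covariates once and solves for the intercept
    whose expected Bernoulli rate matches the target; deterministic given
    seed (defaults to ``config.seed``).
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, _, _, death_lin, _ = _draw_structure(config, n_mc, rng)
    return _solve_intercept(death_lin, target_prevalence, "prevalence")


def calibrate_selection_intercept(config: GeneratorConfig,
                                  target_completion: float,
                                  n_mc: int = 200_000,
                                  seed: Optional[int] = None) -> float:
    """Selection intercept giving the target expected PRO completion rate."""
    if not 0.0 < target_completion < 1.0:
        raise ValueError("target_completion must lie in (0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, _, _, _, sel_lin = _draw_structure(config, n_mc, rng)
    return _solve_intercept(sel_lin, target_completion, "completion rate")


def _default_ehr_effects(n_features: int, n_binary: int) -> np.ndarray:
    """Moderate sparse EHR signal: a few comorbidities plus ~12 labs."""
    beta = np.zeros(n_features)
    binary_effects = {2: 0.75, 3: 0.875, 4: 0.625, 5: 1.0}   # 0-based indices
    for idx, b in binary_effects.items():
        if idx < n_binary:
            beta[idx] = b
    lab_effects = [0.875, 0.75, 0.625, 0.5625, 0.5, 0.4375, 0.375, 0.3125,
                   0.3125, 0.25, 0.25, 0.1875]
    for k, b in enumerate(lab_effects):
        j = n_binary + k
        if j < n_features:
            beta[j] = b
    return beta


def make_config(n_patients: int, *, site: str = "tertiary",
                target_prevalence: float = 0.057,
                target_completion: float = 0.547,
                n_ehr_features: int = 200, n_binary_features: int = 40,
                ehr_effect_vector: Optional[np.ndarray] = None,
                pro_effect_vector: Optional[np.ndarray] = None,
                pro_risk_loadings: Optional[np.ndarray] = None,
                selection_coefficients: Optional[dict] = None,
                seed: int = 0, calibration_n: int = 200_000,
                **overrides) -> GeneratorConfig:
    """Build a calibrated site config.

    Effect structure defaults to the package's study conditions; the baseline
    log-odds and selection intercept are then calibrated by Monte Carlo so the
    expected mortality prevalence and PRO completion rate hit their targets.
    """
    if ehr_effect_vector is None:
        ehr_effect_vector = _default_ehr_effects(n_ehr_features,
                                                 n_binary_features)
    if selection_coefficients is None:
        selection_coefficients = {"intercept": 0.0, "ehr_0001": 0.5,
                                  "risk_linpred": -0.35}
    cfg = GeneratorConfig(
        n_patients=n_patients, site=site, seed=seed,
        n_ehr_features=n_ehr_features, n_binary_features=n_binary_features,
        ehr_effect_vector=ehr_effect_vector,
        pro_effect_vector=pro_effect_vector,
        pro_risk_loadings=pro_risk_loadings,
        selection_coefficients=dict(selection_coefficients),
        **overrides)
    cal_seed = (seed * 1_000_003 + 12345) % (2 ** 31)
    # one covariate draw serves both calibrations: the baseline intercept
    # does not influence the selection linear predictor and vice versa
    rng = np.random.default_rng(cal_seed)
    _, _, _, death_lin, sel_lin = _draw_structure(cfg, calibration_n, rng)
    cfg.baseline_log_odds = _solve_intercept(
        death_lin, target_prevalence, "prevalence")
    cfg.selection_coefficients["intercept"] = _solve_intercept(
        sel_lin, target_completion, "completion rate")
    return cfg


def tertiary_config(n_patients: int = 8555, seed: int = 0,
                    **kwargs) -> GeneratorConfig:
    """Tertiary-practice-style cohort: ~5.7% mortality, ~54.7% completion."""
    kwargs.setdefault("target_prevalence", 0.057)
    kwargs.setdefault("target_completion", 0.547)
    return make_config(n_patients, site="tertiary", seed=seed, **kwargs)


def community_config(n_patients: int = 3795, seed: int = 0,
                     **kwargs) -> GeneratorConfig:
    """Community-practice-style cohort: ~3.2% mortality, ~31.4% completion."""
    kwargs.setdefault("target_prevalence", 0.032)
    kwargs.setdefault("target_completion", 0.314)
    return make_config(n_patients, site="community", seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, csv_path, *,
                 write_config: bool = True) -> None:
    """Write the public cohort table as CSV plus a provenance sidecar.

    PRO cells are empty for non-completers.  A ``<csv>.provenance.json``
    records the seed and config hash; the full config goes to
    ``<csv>.config.yaml``.
    """
    cohort.data.to_csv(csv_path, index=False)
    prov = {"seed": int(cohort.config.seed),
            "site": cohort.config.site,
            "n_patients": int(cohort.config.n_patients),
            "config_hash": cohort.config.content_hash()}
    with open(f"{csv_path}.provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
        fh.write("\n")
    if write_config:
        cohort.config.to_yaml(f"{csv_path}.config.yaml")


def read_cohort(csv_path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(csv_path)
    for col in ("death180", "pro_complete"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df
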