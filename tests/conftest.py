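"""Shared fixtures: small calibrated generator configs and cohorts.

Configs are session-scoped because Monte-Carlo calibration of the intercepts
is the expensive step; tests that need fresh randomness pass their own seed
to ``generate_cohort``.
"""

import numpy as np
import pytest

from promort import GeneratorConfig, make_config, tertiary_config
from promort.cohort import PRO_NAMES


def small_effects(n_features: int = 15, n_binary: int = 3) -> np.ndarray:
    """A compact EHR signal for fast replicate studies (sd ~ 1.3)."""
    beta = np.zeros(n_features)
    beta[1] = 0.7                      # one binary comorbidity
    labs = [0.7, 0.6, 0.5, 0.45, 0.4, 0.35, 0.3, 0.25]
    for k, b in enumerate(labs):
        if n_binary + k < n_features:
            beta[n_binary + k] = b
    return beta


@pytest.fixture(scope="session")
def small_cfg():
    """15-feature tertiary-style config: informative completion, default PROs."""
    return make_config(
        20_000, n_ehr_features=15, n_binary_features=3,
        ehr_effect_vector=small_effects(),
        selection_coefficients={"intercept": 0.0, "ehr_0001": 0.5,
                                "risk_linpred": -0.35},
        seed=101, calibration_n=100_000)


@pytest.fixture(scope="session")
def null_cfg():
    """No EHR/PRO effects, no loadings, MCAR completion at 50%."""
    return GeneratorConfig(
        n_patients=20_000, n_ehr_features=4, n_binary_features=1,
        baseline_log_odds=-2.0,
        pro_risk_loadings=np.zeros(len(PRO_NAMES)),
        selection_coefficients={"intercept": 0.0},
        pro_effect_vector=np.zeros(len(PRO_NAMES)),
        seed=202)


@pytest.fixture(scope="session")
def default_tertiary_cfg():
    """The package's full default tertiary study config (200 EHR features)."""
    return tertiary_config(seed=0)
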