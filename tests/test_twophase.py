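"""Selection model, inverse-probability weights and the combined model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from promort import (GeneratorConfig, RiskModel, compute_weights,
                     evaluate_two_phase, fit_combined_model,
                     fit_selection_model, generate_cohort, weighted_auc)
from promort.cohort import PRO_NAMES
from promort.twophase import EHR_LOGIT, SelectionModel

N_PRO = len(PRO_NAMES)


def truth_model(cfg) -> RiskModel:
    """RiskModel holding the generator's true EHR coefficients."""
    names = [f"ehr_{i + 1:04d}" for i in range(cfg.n_ehr_features)]
    return RiskModel(names, cfg.baseline_log_odds, cfg.ehr_effect_vector)


def mcar_config(n=20_000, rate_logit=0.0, seed=303):
    eff = np.zeros(8)
    eff[2:] = 0.6
    return GeneratorConfig(n_patients=n, n_ehr_features=8,
                           n_binary_features=2, baseline_log_odds=-3.2,
                           ehr_effect_vector=eff,
                           selection_coefficients={"intercept": rate_logit},
                           seed=seed)


class TestSelectionModel:
    def test_mcar_probabilities_near_constant(self):
        cfg = mcar_config()
        cohort = generate_cohort(cfg, seed=1)
        sel = fit_selection_model(cohort.data, truth_model(cfg))
        p = sel.fitted["p_hat"]
        assert np.all(np.abs(p - 0.5) < 0.03)
        assert p.mean() == pytest.approx(
            cohort.data["pro_complete"].mean(), abs=0.02)

    def test_recovers_known_selection_coefficients(self):
        eff = np.zeros(8)
        eff[2:] = 0.6
        cfg = GeneratorConfig(
            n_patients=50_000, n_ehr_features=8, n_binary_features=2,
            baseline_log_odds=-3.2, ehr_effect_vector=eff,
            selection_coefficients={"intercept": 0.3, "ehr_0001": 0.5,
                                    "risk_linpred": -0.6},
            seed=404)
        cohort = generate_cohort(cfg, seed=2)
        sel = fit_selection_model(cohort.data, truth_model(cfg))
        # generator uses the STANDARDIZED risk score; the model uses the raw
        # EHR logit, so the slope is -0.6 / sd(linear predictor)
        full = cohort.complete_data
        lp = truth_model(cfg).linear_predictor(full)
        expected_slope = -0.6 / lp.std()
        got = dict(zip(sel.covariate_names, sel.coefficients))
        assert got[EHR_LOGIT] == pytest.approx(expected_slope, abs=0.1)
        assert got["ehr_0001"] == pytest.approx(0.5, abs=0.1)

    def test_all_completers_degenerate_unit_weights(self):
        cfg = mcar_config(n=500, rate_logit=50.0)
        cohort = generate_cohort(cfg, seed=3)
        assert cohort.data["pro_complete"].all()
        with pytest.warns(UserWarning, match="degenerate"):
            sel = fit_selection_model(cohort.data, truth_model(cfg))
        wts = compute_weights(sel, cohort.data)
        assert (wts.table["weight"] == 1.0).all()

    def test_unknown_covariate_rejected(self):
        cfg = mcar_config(n=200)
        cohort = generate_cohort(cfg, seed=4)
        with pytest.raises(ValueError, match="nope"):
            fit_selection_model(cohort.data, truth_model(cfg),
                                extra_covariates=("nope",))


class TestWeights:
    @staticmethod
    def _manual_selection(cfg, intercept):
        return SelectionModel(covariate_names=[], intercept=intercept,
                              coefficients=np.zeros(0),
                              fitted=pd.DataFrame(), completion_rate=0.5,
                              ehr_model=None)

    def test_constant_half_probability_gives_weight_two(self):
        cfg = mcar_config(n=1000)
        cohort = generate_cohort(cfg, seed=5)
        sel = self._manual_selection(cfg, 0.0)          # expit(0) = 0.5
        sel.design = lambda df: np.zeros((len(df), 0))
        wts = compute_weights(sel, cohort.data)
        assert np.allclose(wts.table["weight"], 2.0)

    def test_horvitz_thompson_sum_estimates_cohort_size(self, small_cfg):
        cohort = generate_cohort(small_cfg, seed=6)
        sel = fit_selection_model(cohort.data, truth_model(small_cfg))
        w = compute_weights(sel, cohort.data).table["weight"]
        assert w.sum() == pytest.approx(len(cohort.data), rel=0.05)
        assert (w >= 1.0 - 1e-9).all()

    def test_truncation_bounds_recorded_and_applied(self, small_cfg):
        cohort = generate_cohort(small_cfg, seed=7)
        sel = fit_selection_model(cohort.data, truth_model(small_cfg))
        wts = compute_weights(sel, cohort.data, truncation=(5.0, 95.0))
        lo, hi = wts.truncation_bounds
        assert lo < hi
        assert wts.table["weight"].min() == pytest.approx(lo)
        assert wts.table["weight"].max() == pytest.approx(hi)


class TestCombinedModel:
    def test_always_contains_ehr_logit_term(self, small_cfg):
        cohort = generate_cohort(small_cfg, seed=8)
        ehr = truth_model(small_cfg)
        sel = fit_selection_model(cohort.data, ehr)
        wts = compute_weights(sel, cohort.data)
        model = fit_combined_model(cohort.data, ehr, wts)
        assert model.term_names[0] == EHR_LOGIT
        assert set(model.pro_terms) <= {f"pro_{n}" for n in PRO_NAMES}

    def test_informative_pros_selected(self, small_cfg):
        # the generator gives independent effects to exactly four PROs;
        # the two strongest must survive backward elimination
        cohort = generate_cohort(small_cfg, seed=9)
        ehr = truth_model(small_cfg)
        wts = compute_weights(
            fit_selection_model(cohort.data, ehr), cohort.data)
        model = fit_combined_model(cohort.data, ehr, wts)
        assert {"pro_performance_status", "pro_quality_of_life"} <= set(
            model.pro_terms)

    def test_mcar_weighted_fit_matches_unweighted_glm(self):
        # completely-at-random completion with all-unit weights must agree
        # exactly with the standard unweighted statsmodels fit
        cfg = mcar_config()
        cohort = generate_cohort(cfg, seed=10)
        ehr = truth_model(cfg)
        sel = fit_selection_model(cohort.data, ehr)
        wts = compute_weights(sel, cohort.data)
        wts.table["weight"] = 1.0
        model = fit_combined_model(cohort.data, ehr, wts,
                                   selection_strategy="none")
        comp = cohort.data[cohort.data.pro_complete == 1]
        X = pd.DataFrame({EHR_LOGIT: ehr.linear_predictor(comp)})
        for t in model.pro_terms:
            X[t] = comp[t].to_numpy()
        ref = sm.GLM(comp["death180"].to_numpy(),
                     sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        assert model.intercept == pytest.approx(ref.params["const"],
                                                abs=1e-8)
        got = dict(zip(model.term_names, model.coefficients))
        for t, b in got.items():
            assert b == pytest.approx(ref.params[t], abs=1e-8)

    def test_too_few_cases_rejected(self):
        cfg = mcar_config(n=600)
        cohort = generate_cohort(cfg, seed=11)
        df = cohort.data.copy()
        df["death180"] = 0
        df.loc[df.index[:10], "death180"] = 1
        ehr = truth_model(cfg)
        wts = compute_weights(fit_selection_model(df, ehr), df)
        with pytest.raises(ValueError, match="case mass"):
            fit_combined_model(df, ehr, wts)


class TestEvaluateTwoPhase:
    def test_mcar_matches_unweighted_completer_estimates(self):
        cfg = mcar_config()
        train = generate_cohort(cfg, seed=12).data
        test = generate_cohort(cfg, seed=13).data
        ehr = truth_model(cfg)
        wts = compute_weights(fit_selection_model(train, ehr), train)
        model = fit_combined_model(train, ehr, wts,
                                   selection_strategy="none")
        rep = evaluate_two_phase(model, test, n_boot=0)
        comp = test[test.pro_complete == 1]
        unweighted = weighted_auc(model.predict(comp),
                                  comp["death180"].to_numpy())
        assert rep.auc == pytest.approx(unweighted, abs=0.01)

    def test_weighted_closer_to_full_cohort_truth_under_selection(
            self, small_cfg):
        # completers are lower-risk; the IPW estimate of AUC should sit
        # closer to the all-patients oracle than the complete-case estimate
        cohort = generate_cohort(small_cfg, seed=14)
        full = cohort.complete_data
        scores_all = full["true_death_logit"].to_numpy()
        y_all = full["death180"].to_numpy()
        oracle = weighted_auc(scores_all, y_all)
        comp_mask = full["pro_complete"].to_numpy() == 1
        cc = weighted_auc(scores_all[comp_mask], y_all[comp_mask])
        ehr = truth_model(small_cfg)
        sel = fit_selection_model(cohort.data, ehr)
        w = compute_weights(sel, cohort.data).for_cohort(cohort.data)
        ipw = weighted_auc(scores_all[comp_mask], y_all[comp_mask], w)
        assert abs(ipw - oracle) < abs(cc - oracle)

    def test_deterministic_given_seed(self):
        cfg = mcar_config(n=4000)
        train = generate_cohort(cfg, seed=15).data
        test = generate_cohort(cfg, seed=16).data
        ehr = truth_model(cfg)
        wts = compute_weights(fit_selection_model(train, ehr), train)
        model = fit_combined_model(train, ehr, wts)
        a = evaluate_two_phase(model, test, n_boot=120, seed=5)
        b = evaluate_two_phase(model, test, n_boot=120, seed=5)
        assert a.to_dict() == b.to_dict()
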