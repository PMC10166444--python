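"""Synthetic cohort generator: determinism, calibration, copula structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import chisquare, norm, spearmanr, ttest_ind

from promort import (GeneratorConfig, calibrate_baseline, generate_cohort,
                     read_cohort, write_cohort)
from promort.cohort import (PRO_NAMES, default_latent_correlation,
                            default_likert_cutpoints)

N_PRO = len(PRO_NAMES)


def zero_effect_config(n=50_000, baseline=logit(0.057), sel_intercept=0.0,
                       seed=0, **kw):
    kw.setdefault("pro_risk_loadings", np.zeros(N_PRO))
    kw.setdefault("pro_effect_vector", np.zeros(N_PRO))
    kw.setdefault("selection_coefficients", {"intercept": sel_intercept})
    return GeneratorConfig(n_patients=n, n_ehr_features=4,
                           n_binary_features=1, baseline_log_odds=baseline,
                           seed=seed, **kw)


class TestSchemaAndDeterminism:
    def test_bit_identical_given_config_and_seed(self):
        cfg = zero_effect_config(n=2000)
        a = generate_cohort(cfg, seed=5).data
        b = generate_cohort(cfg, seed=5).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_values_not_schema(self):
        cfg = zero_effect_config(n=2000)
        a = generate_cohort(cfg, seed=5).data
        b = generate_cohort(cfg, seed=6).data
        assert list(a.columns) == list(b.columns)
        assert not a.drop(columns=["patient_id", "site"]).equals(
            b.drop(columns=["patient_id", "site"]))

    def test_value_ranges_and_missingness_pattern(self):
        cfg = zero_effect_config(n=5000)
        df = generate_cohort(cfg).data
        assert set(df["death180"].unique()) <= {0, 1}
        comp = df[df["pro_complete"] == 1]
        noncomp = df[df["pro_complete"] == 0]
        for name in PRO_NAMES:
            col = f"pro_{name}"
            assert noncomp[col].isna().all()
            vals = comp[col]
            assert not vals.isna().any()
            if name == "rash":
                assert set(vals.unique()) <= {0.0, 1.0}
            else:
                assert vals.between(1, 5).all()
                assert (vals == vals.astype(int)).all()

    def test_complete_data_has_pros_for_everyone(self):
        cfg = zero_effect_config(n=1000)
        full = generate_cohort(cfg).complete_data
        assert not full[[f"pro_{n}" for n in PRO_NAMES]].isna().any().any()


class TestCalibration:
    def test_zero_effects_prevalence_matches_baseline(self):
        cfg = zero_effect_config(n=50_000, baseline=logit(0.057))
        df = generate_cohort(cfg).data
        assert df["death180"].mean() == pytest.approx(0.057, abs=0.005)

    def test_zero_slope_selection_matches_intercept(self):
        cfg = zero_effect_config(n=50_000, sel_intercept=logit(0.547))
        df = generate_cohort(cfg).data
        assert df["pro_complete"].mean() == pytest.approx(0.547, abs=0.01)

    def test_calibrate_baseline_closed_forms(self):
        cfg = zero_effect_config(n=100)
        assert abs(calibrate_baseline(cfg, 0.5, n_mc=50_000)) < 0.02
        assert calibrate_baseline(cfg, 0.057, n_mc=100_000) == pytest.approx(
            logit(0.057), abs=0.05)

    def test_calibrate_baseline_monotone_in_effects(self):
        eff = np.zeros(4)
        eff[1:] = 1.2                      # strong positive continuous effects
        cfg = zero_effect_config(n=100, ehr_effect_vector=eff)
        assert calibrate_baseline(cfg, 0.057, n_mc=100_000) < logit(0.057)

    def test_unattainable_target_rejected(self):
        cfg = zero_effect_config(n=100)
        with pytest.raises(ValueError):
            calibrate_baseline(cfg, 1.5, n_mc=1000)


class TestCopula:
    def test_discretized_spearman_matches_monte_carlo_oracle(self):
        # latent r=0.69 between performance status and fatigue; the observed
        # rank correlation of the cut items is attenuated.  Oracle: direct
        # numpy simulation of the bivariate copula at n=500k.
        cuts = default_likert_cutpoints(1)[0]
        rng = np.random.default_rng(99)
        z1 = rng.standard_normal(500_000)
        z2 = 0.69 * z1 + np.sqrt(1 - 0.69 ** 2) * rng.standard_normal(500_000)
        c1 = 1 + (z1[:, None] > cuts).sum(axis=1)
        c2 = 1 + (z2[:, None] > cuts).sum(axis=1)
        oracle = spearmanr(c1, c2).statistic
        assert oracle < 0.69               # attenuation is real

        cfg = zero_effect_config(n=50_000)
        df = generate_cohort(cfg, seed=7).complete_data
        got = spearmanr(df["pro_performance_status"],
                        df["pro_fatigue"]).statistic
        assert got == pytest.approx(oracle, abs=0.05)

    def test_latent_correlation_preserved_under_risk_loading(self):
        # loadings reshape the residual copula; total latent correlation --
        # and hence the discretized Spearman -- must be unchanged
        eff = np.zeros(4)
        eff[1:] = 0.8
        base = zero_effect_config(n=80_000)
        loaded = zero_effect_config(
            n=80_000, ehr_effect_vector=eff,
            pro_risk_loadings=np.full(N_PRO, 0.3))
        r0 = spearmanr(*(generate_cohort(base, seed=3).complete_data[c]
                         for c in ("pro_anxiety", "pro_sadness"))).statistic
        r1 = spearmanr(*(generate_cohort(loaded, seed=3).complete_data[c]
                         for c in ("pro_anxiety", "pro_sadness"))).statistic
        assert r1 == pytest.approx(r0, abs=0.02)

    def test_likert_marginals_match_cutpoint_cells(self):
        # chi-square GOF against the cutpoint-implied cell masses; at most a
        # few rejections at alpha=0.01 across 20 seeds
        cfg = zero_effect_config(n=50_000)
        cuts = cfg.likert_cutpoints[0]
        probs = np.diff(np.r_[0.0, norm.cdf(cuts), 1.0])
        probs /= probs.sum()
        rejections = 0
        for seed in range(20):
            df = generate_cohort(cfg, seed=seed).complete_data
            counts = (df["pro_pain"].value_counts()
                      .reindex([1, 2, 3, 4, 5], fill_value=0).to_numpy())
            p = chisquare(counts, probs * counts.sum()).pvalue
            rejections += p < 0.01
        assert rejections <= 3


class TestInformativeSelection:
    def test_completers_differ_on_selection_covariate(self, small_cfg):
        df = generate_cohort(small_cfg, seed=11).data
        comp = df[df["pro_complete"] == 1]
        noncomp = df[df["pro_complete"] == 0]
        # binary demographic-like covariate drives completion (coef +0.5)
        assert comp["ehr_0001"].mean() > noncomp["ehr_0001"].mean()
        p = ttest_ind(comp["ehr_0001"], noncomp["ehr_0001"]).pvalue
        assert p < 0.01

    def test_completers_lower_risk(self, small_cfg):
        full = generate_cohort(small_cfg, seed=11).complete_data
        assert (full.loc[full.pro_complete == 1, "true_death_logit"].mean()
                < full.loc[full.pro_complete == 0, "true_death_logit"].mean())


class TestValidation:
    def test_non_psd_correlation_names_eigenvalue(self):
        corr = np.full((N_PRO, N_PRO), 0.99)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = -0.99
        with pytest.raises(ValueError, match="eigenvalue"):
            zero_effect_config(n=10, pro_latent_correlation=corr)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ehr_effect_vector"):
            zero_effect_config(n=10, ehr_effect_vector=np.zeros(7))
        with pytest.raises(ValueError, match="pro_effect_vector"):
            zero_effect_config(n=10, pro_effect_vector=np.zeros(5))

    def test_cutpoints_must_increase(self):
        cuts = default_likert_cutpoints(11)
        cuts[3, 2] = cuts[3, 1] - 0.1
        with pytest.raises(ValueError, match="increasing"):
            zero_effect_config(n=10, likert_cutpoints=cuts)

    def test_unknown_selection_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            zero_effect_config(
                n=10, selection_coefficients={"intercept": 0.0, "age": 0.1})


class TestIO:
    def test_csv_roundtrip_with_provenance(self, tmp_path):
        cfg = zero_effect_config(n=500)
        cohort = generate_cohort(cfg)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == 500
        assert back["death180"].equals(cohort.data["death180"])
        assert (tmp_path / "cohort.csv.provenance.json").exists()
        cfg2 = GeneratorConfig.from_yaml(tmp_path / "cohort.csv.config.yaml")
        assert cfg2.content_hash() == cfg.content_hash()
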