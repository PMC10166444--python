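# promort

Two-phase mortality-risk modeling with patient-reported outcomes (PROs).

## The problem

Oncology practices increasingly run EHR-based algorithms that flag patients
at high risk of short-term (180-day) mortality to prompt earlier
serious-illness conversations and supportive care.  Routinely collected
PROs — symptom, function and quality-of-life items on 1–5 Likert scales —
carry prognostic signal the EHR does not, but only a non-representative
subset of patients completes them: completers differ by demographics and by
risk itself.  Naively restricting to completers (complete-case analysis)
biases both model fitting and performance estimates; naively imputing a
majority-missing 12-item block is worse.

`promort` implements the two-phase answer for biostatisticians and clinical
data scientists: treat the EHR as phase 1 (everyone) and the PROs as phase 2
(a subsample), model the probability of completion from phase-1 data, and
inverse-probability-weight both the combined model fit and its evaluation so
completer-based results represent the full cohort.

## What's in the box

| Module | Contents |
|---|---|
| `promort.cohort` | seeded synthetic two-site cohort generator (Gaussian-copula ordinal PROs, informative completion), CSV/YAML IO |
| `promort.ehr` | outcome-stratified 70/30 split; adaptive-LASSO logistic EHR model (`w_j = 1/\|β̃_j\|^γ`, CV-chosen λ, 1-SE rule) |
| `promort.pro` | PRO-only logistic model; Spearman inter-PRO correlations; univariable and EHR-risk-adjusted odds ratios |
| `promort.twophase` | completion (selection) model, truncated inverse-probability weights, weighted combined model with backward PRO selection, weighted evaluation |
| `promort.metrics` | weighted AUC (Mann–Whitney, ties ½), step-curve AUPRC, TPR/FPR at a risk threshold, patient-level percentile bootstrap CIs |
| `promort.dca` | standardized net benefit `sNB(t) = TPR − [t/(1−t)]·[(1−π)/π]·FPR`, decision curves, dominance summary |
| `promort.pipeline` / `promort.cli` | end-to-end seeded experiment (EHR vs PRO vs EHR+PRO per site) and the `promort` command-line tool |

The real clinical data behind this design are not publicly deposited, so the
cohort generator is a first-class, tested component: it reproduces the
study-like conditions (≈5.7%/3.2% mortality prevalence, ≈54.7%/31.4% PRO
completion at a tertiary- and community-style site, inter-PRO correlations
up to 0.72, per-PRO mortality odds ratios ≈1.2–2) and knows every patient's
PROs, which gives the tests a full-information oracle to measure
complete-case bias against.  See `docs/methods.md` for the generative model
and all statistical conventions.

## Worked example

```python
from promort import (tertiary_config, generate_cohort, split_cohort,
                     fit_adaptive_lasso, fit_pro_model, fit_selection_model,
                     compute_weights, fit_combined_model, evaluate_two_phase)
from promort.cohort import ehr_columns

cfg = tertiary_config(seed=1)            # n=8,555, calibrated to 5.7% / 54.7%
cohort = generate_cohort(cfg).data
split = split_cohort(cohort, 0.7, seed=1)
train_mask, test_mask = split.masks(cohort)
train, test = cohort[train_mask], cohort[test_mask]

ehr = fit_adaptive_lasso(train[ehr_columns(train)],
                         train["death180"].to_numpy(), seed=1)
sel = fit_selection_model(train, ehr)            # completion ~ EHR logit + demographics
w = compute_weights(sel, train)                  # truncated 1/p̂ for completers
combined = fit_combined_model(train, ehr, w)     # weighted backward elimination
print(combined.term_names)
report = evaluate_two_phase(combined, test, n_boot=200, seed=1)
print(f"AUC {report.auc:.3f} ({report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f})")
```

prints

```
['ehr_logit', 'pro_performance_status', 'pro_quality_of_life', 'pro_nausea', 'pro_numbness_tingling']
AUC 0.929 (0.904-0.950)
```

— the combined model keeps the EHR logit plus exactly the four PRO items the
generator makes independently prognostic, and its weighted test AUC
represents the *full* test set, not just the completers.  The same flow from
a shell:

```bash
promort run-all --seed 3 --bootstrap 100 --out expdir/
# tertiary: AUC {'ehr': '0.838', 'pro': '0.804', 'ehr_pro': '0.910'} (in_sample=False)
# community: AUC {'ehr': '0.872', 'pro': '0.826', 'ehr_pro': '0.932'} (in_sample=True)
```

The combined model beats the EHR-only model, which beats the PRO-only model,
and (in `expdir/dominance_*.tsv`) its standardized-net-benefit curve is
maximal over most of the 0.01–0.50 risk-threshold grid — the qualitative
pattern that motivates integrating PROs into EHR risk models.  Other
subcommands: `simulate`, `fit-ehr`, `fit-pro`, `fit-combined`, `evaluate`,
`dca`, `sensitivity` (completer-only re-evaluation).

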