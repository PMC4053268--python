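"""Fit the model family prospectively and compare its members.

Trains on pre-2007 admissions, evaluates on 2007, and prints a summary
row per model: background (age+gender), exposure variants a/b/c,
disease (Charlson), and the combined full model.
"""

from hosprisk import CohortConfig, evaluate, fit_preset, odds_ratios, preset, simulate_cohort, split_by_year

records = simulate_cohort(CohortConfig(n_admissions=60_000, seed=11))
train, test = split_by_year(records, test_year=2007)
print(f"train {len(train)} / test {len(test)} admissions\n")

print(f"{'model':<9} {'vars':>4} {'AUC':>6} {'AIC':>10} {'BIC':>10} {'sens':>6} {'spec':>6}")
for name in ("model1", "model2a", "model2b", "model2c", "model3", "model5c"):
    m = fit_preset(train, name)
    r = evaluate(m, test)
    print(f"{name:<9} {preset(name).n_covariates:>4} {r.auc.auc:>6.3f} "
          f"{r.aic:>10.0f} {r.bic:>10.0f} "
          f"{r.cutoff.sensitivity:>6.1f} {r.cutoff.specificity:>6.1f}")

full = fit_preset(train, "model5c")
ors = odds_ratios(full)  # per-block odds ratios vs Monday daytime
sun = ors.loc["count_Sun_daytime", "odds_ratio"]
print(f"\nSunday-daytime vs Monday-daytime odds ratio: {sun:.2f}")
# The full model (5c) should clearly out-discriminate each component.
# The Sunday/Monday contrast targets the generator's configured 1.7 but
# is a noisy single-coefficient contrast at this cohort size; the
# recovery checks in the test suite use 200,000 admissions.
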