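"""Quintile hazard-ratio analysis on a generated cohort.

Generates 2000 subjects whose true hazard rises by log-HR 0.5 per
severity quintile, fits the unadjusted (model0) and covariate-adjusted
(model1) Cox regressions, applies Benjamini-Hochberg correction, and
averages predicted survival curves by quintile.
"""
import numpy as np

from whi import averaged_survival_curves, fit_cox_models, generate_cohort

cohort = generate_cohort(2000, hazard_spec={"baseline_hazard": 0.02,
                                            "log_hr_per_quintile": 0.5},
                         censor_rate=0.3, seed=42)
print(f"{len(cohort)} subjects, "
      f"{cohort.event_indicator.sum()} events "
      f"({100 * (1 - cohort.event_indicator.mean()):.0f}% censored)")

for model in ("model0", "model1"):
    fitted = fit_cox_models(cohort, "whi_auc90", model)
    print(f"\n{model} hazard ratios vs quintile 1 "
          f"(true per-step HR = e^0.5 = {np.exp(0.5):.2f}):")
    for _, r in fitted.hr_table.iterrows():
        print(f"  Q{r.quintile}: HR {r.hr:6.2f} "
              f"({r.ci_low:.2f}-{r.ci_high:.2f})  p={r.p:.2e}  "
              f"p_bh={r.p_bh:.2e}")

curves = averaged_survival_curves(fitted, times=np.array([5.0, 10.0]))
print("\nquintile-averaged predicted survival:")
for t in (5.0, 10.0):
    at_t = curves[curves.time == t].set_index("quintile")["mean_survival"]
    row = "  ".join(f"Q{q}={at_t[q]:.2f}" for q in range(1, 6))
    print(f"  t={t:>4.0f} y: {row}")
print("\nSurvival orders inversely with severity quintile, mirroring the")
print("monotone hazard gradient the generator embedded.")
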