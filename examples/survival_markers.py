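"""Marker-level survival analysis: Kaplan-Meier, log-rank, Cox.

Simulates survival with a hazard multiplied by 4 per methylated
prognostic marker, then tests one marker's methylation status against
overall survival.
"""

import numpy as np

from methmark import simulate, survival

cfg = simulate.TruthConfig(seed=3, hazard_multiplier=4.0)
clinical = simulate.gen_clinical_cohort(cfg)
truth = simulate.gen_truth_calls(cfg, clinical)
surv = simulate.gen_survival(
    clinical, truth, cfg.prognostic_markers, cfg.hazard_multiplier, seed=4
)

marker = "PRPH"
methylated = truth.loc[marker, surv.index] == "M"
groups = np.where(methylated, "methylated", "unmethylated")

lr = survival.logrank(surv["time"], surv["event"], groups)
fit = survival.cox_fit(surv["time"], surv["event"], methylated.astype(float))
km = survival.km_curve(
    surv.loc[methylated.to_numpy(), "time"],
    surv.loc[methylated.to_numpy(), "event"],
)

print(f"{marker}: {int(methylated.sum())}/{len(methylated)} samples methylated")
print(f"log-rank (Mantel-Cox): chi2={lr.statistic:.2f}, p={lr.p:.4g}")
print(
    f"Cox fit: HR={fit.hr:.2f} (95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), "
    f"Wald p={fit.p:.4g}"
)
print(f"KM survival at last event time (methylated arm): {km.survival[-1]:.2f}")
print(
    "\nA hazard ratio above 1 with a small log-rank p indicates that "
    "methylation of this marker is associated with worse overall survival, "
    "as planted in the simulation."
)
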