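"""Leave-one-out decision-tree marker selection among high-risk patients.

Plants a four-marker complementary prognostic signature, counts how
often each marker is used across the leave-one-out trees, restricts the
classifier to the selected signature, and tests the predicted classes
for survival separation.
"""

import pandas as pd

from methmark import classifier, simulate, survival

SIGNATURE = ["CNR1", "ACSS3", "HIST1H3C", "PRPH"]

cfg = simulate.TruthConfig(seed=1)
clinical = simulate.gen_clinical_cohort(cfg)
truth = pd.concat(
    [
        simulate.gen_signature_truth(clinical, SIGNATURE, seed=101),
        simulate.gen_truth_calls(cfg, clinical).drop(index=SIGNATURE),
    ]
)

hr = clinical[clinical["risk_group"].isin(["HR-DOD", "HR-SURV"])]
X = (truth.loc[:, hr["sample"]] == "M").astype(float).T
y = hr.set_index("sample")["risk_group"]

freq = classifier.loo_marker_frequency(X, y)
selected = classifier.select_markers(freq, min_fraction=0.5)
print("marker inclusion across leave-one-out trees:")
print(freq.sort_values(ascending=False).round(2).head(8))
print(f"\nselected signature (>=50% of trees): {selected}")

pred = classifier.loo_predict_restricted(X[selected], y)
surv = simulate.gen_survival(
    clinical, truth, tuple(SIGNATURE), cfg.hazard_multiplier, seed=9
)
svh = surv.loc[hr["sample"]]
lr = survival.logrank(svh["time"], svh["event"], pred.loc[svh.index])
print(f"\nlog-rank between predicted outcome classes: p={lr.p:.3g}")
print(
    "\nA small p means the combined methylation status of the selected "
    "markers separates high-risk survivors from deceased patients — the "
    "signature carries prognostic information beyond the risk grouping."
)
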