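"""Step 3 — recalibrate the transported model and compare before/after.

Produces the three-panel calibration figure (original, intercept-updated,
intercept+slope-updated) and the rule-based updating recommendation.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from extval import (
    calibrate_metrics,
    development_spec,
    generate_cohort,
    interpret_validation,
    recalibrate_intercept,
    recalibrate_slope,
    validation_spec,
)
from extval.performance import auc
from extval.plots import plot_calibration

dev_spec = development_spec(seed=1)
val_spec = validation_spec(seed=2, dev=dev_spec)
model = dev_spec.truth_model
cohort = generate_cohort(val_spec)
y = cohort.outcome.to_numpy()

variants = {
    "original": model.predicted_risk(cohort),
    "intercept update": recalibrate_intercept(model, cohort).predicted_risk(cohort),
    "intercept+slope update": recalibrate_slope(model, cohort).predicted_risk(cohort),
}

fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True, sharey=True)
for ax, (name, p) in zip(axes, variants.items()):
    cal = calibrate_metrics(p, y)
    print(f"{name:23s}: E:O {cal.eo:.3f}, CITL {cal.citl:6.3f}, slope {cal.slope:.3f}")
    plot_calibration(p, y, ax=ax, title=name, smoother=False)
fig.tight_layout()
fig.savefig("calibration_panels.png", dpi=120)
print("wrote calibration_panels.png")
# Intercept updating restores E:O = 1.000 and CITL = 0.000 but leaves the
# slope < 1 (the model is still overfit); the joint update also restores
# slope = 1.000. Discrimination is untouched by either update.

cal0 = calibrate_metrics(variants["original"], y)
disc0 = auc(variants["original"], y)
print("recommendation:", interpret_validation(cal0, disc0)["recommendation"])
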