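"""ROC evaluation and the injury risk curve for a fixed biomarker panel.

Fits the glycine/taurine/ornithine logit on a development cohort, finds the
Youden-optimal logit-score threshold, reports sensitivity / specificity /
overall prediction accuracy rate, and shows how the logit score maps to an
estimated injury probability.
"""

import numpy as np

from aapanel import (
    confusion_at,
    fit_logit,
    generate_cohort,
    optimal_threshold,
    planted_signal_config,
    risk_curve,
    roc_curve,
)

panel = generate_cohort(planted_signal_config(signal_set=("GLY", "TAU", "ORN"), seed=42))
model = fit_logit(panel, ("GLY", "TAU", "ORN"))

print("fitted logit coefficients (raw nmol/mL scale):")
print(f"  intercept {model.beta0:+.4f}")
for name, beta, se in zip(model.variable_names, model.betas, model.standard_errors[1:]):
    print(f"  {name}       {beta:+.4f}  (SE {se:.4f})")

scores = model.scores(panel)
roc = roc_curve(scores, panel.labels)
thr = optimal_threshold(roc)
cm = confusion_at(scores, panel.labels, thr)
print(f"\nAUC = {roc.auc:.4f}, optimal logit-score threshold = {thr:.3f}")
print(f"S = {cm.sensitivity_pct:.0f}%, SP = {cm.specificity_pct:.0f}%, PAR = {cm.accuracy_pct:.0f}%")

print("\nrisk curve (logit score -> injury probability):")
for score, prob in risk_curve(model, np.linspace(-4, 4, 5)):
    print(f"  score {score:+4.1f}  ->  P(injured) = {prob:.3f}")
print("A sample scoring at the threshold sits on the decision boundary.")
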