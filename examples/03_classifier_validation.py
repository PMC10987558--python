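"""Stepwise-AIC logistic classification with frozen external validation.

Trains on a flux-like feature matrix with three informative features among
seventeen noise features, validates the frozen model on an independent
batch-shifted cohort after per-cohort mean-centering, and reports both ROC
areas plus the specificity at the training-chosen Youden operating point.
"""

from commflux import batch_correct, stepwise_aic, validate_external
from commflux.studies import classifier_study, classifier_validation_study

X_train, y_train, informative = classifier_study(seed=0)
X_val, y_val = classifier_validation_study(seed=0)

Xc, Xvc = batch_correct(X_train, X_val)  # removes the cohort location shift
model = stepwise_aic(Xc, y_train)

print(f"Planted informative features: {informative}")
print(f"Selected features: {model.feature_ids}")
print("Stepwise trace (move, AIC):")
for move, aic in model.step_trace:
    print(f"  {move:>10s}  {aic:8.2f}")
print(f"\nTraining AUC: {model.train_auc:.3f}")
print("Wald p-values of selected coefficients (post-selection, descriptive):")
for f, p in model.wald_p.items():
    print(f"  {f}: p = {p:.3g}")

val = validate_external(model, Xvc, y_val)
print(f"\nFrozen-model validation AUC: {val.auc:.3f}")
print(f"Sensitivity / specificity at the training Youden threshold: "
      f"{val.sensitivity:.2f} / {val.specificity:.2f}")
print("\nThe drop from training to validation AUC reflects selection optimism")
print("at n=40; coefficients and standardization were never refit.")
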