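"""Classify the diffusion medium from fingerprints.

Fingerprints the heterogeneous synthetic study, runs the seven-classifier
panel with fivefold cross-validation, and prints the F1 ranking, the
best model's confusion matrix and the top-5 Shapley feature importances.
"""

import warnings

from diffprint import (confusion, fingerprint_table, mode_fractions,
                       shap_importance, train_panel)
from diffprint.simulate import build_synthetic_study, default_study_design

warnings.filterwarnings("ignore")

design = default_study_design("heterogeneous", n_per_cell=60)
trajs, labels = build_synthetic_study(design, seed=7)
table = fingerprint_table(trajs, labels)
print(f"{len(table)} fingerprints ({int(table.flagged.sum())} flagged)\n")

print("diffusion-mode percentages per medium:")
print(mode_fractions(table, by=("medium",)).round(1).to_string(index=False))

report = train_panel(table, protocol="cv_5fold", seed=7)
print("\nmean F1 across folds:")
print(report.summary[("f1", "mean")].sort_values(ascending=False).round(3))
print(f"\nconfusion matrix of {report.best_classifier} "
      "(rows = true medium, diagonal = per-class recall):")
print(confusion(report).round(2))

shap = shap_importance(table, seed=7, top_k=5)
print("\ntop-5 features by total mean |Shapley| attribution:")
print(shap.top.round(3))
print("\nTree ensembles lead on this overlapping-mixture design; the "
      "attribution table shows which fingerprint features each class "
      "decision relies on.")
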