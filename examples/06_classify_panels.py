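"""Marker-panel classification with an RBF-SVM and a permutation control.

Ten repetitions of stratified 10-fold cross-validation; inside every
training fold the top-k markers by t-test significance are selected, so the
held-out fold never influences the panel.  The permutation null repeats the
whole procedure on shuffled labels.
"""

from mirqval import (
    ClassifierConfig, SimulationConfig, cross_validate, curate_matrix,
    delta_ct, expressed_panel, generate_study, permutation_null,
)

config = SimulationConfig(seed=42)
wells, annotation, _ = generate_study(config)
curated = curate_matrix(wells)
groups = annotation.set_index("sample_id")["group"]
delta = delta_ct(curated, "RNU44")
panel = [a for a in expressed_panel(curated, config.control_names)
         if a in delta.values.index]
values = delta.values.loc[panel]

cfg = ClassifierConfig(panel_sizes=(5, 10, 50), seed=7)
res = cross_validate(values, groups, ("NSCLC", "control"), cfg)
print("NSCLC vs control (positive class = NSCLC):")
for k, p in res.panels.items():
    lo, hi = p.ci_accuracy
    print(f"  {k:3d} markers: accuracy {p.accuracy:5.1f}% "
          f"(95% CI {lo:.1f}-{hi:.1f}), sens {p.sensitivity:.1f}%, "
          f"spec {p.specificity:.1f}%, AUC {p.auc:.3f}")
print(f"  most selected markers (5-panel): {res.panels[5].consensus_panel()[:5]}")

null = permutation_null(values, groups, ("NSCLC", "control"), cfg, panel_size=5)
print(f"\npermutation null (5 markers, {len(null.accuracies)} shuffles): "
      f"mean accuracy {null.accuracies.mean():.1f}%")
print(f"empirical p for the observed accuracy: {null.empirical_p:.3f}")
print("\nThe null sits at the majority-class rate (~79% here), so the gap to")
print("the observed accuracy is signal, not overtraining.")
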