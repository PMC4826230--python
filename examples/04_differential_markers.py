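"""Per-marker statistics and the Venn partition of up/down sets.

Welch t and rank-sum p-values with BH adjustment and Mann-Whitney AUC per
contrast, a three-group ANOVA, and the overlap structure of the significant
marker sets of the two contrasts.
"""

from mirqval import (
    SimulationConfig, anova_three_group, curate_matrix, delta_ct,
    expressed_panel, generate_study, two_group_stats, venn_partition,
)

config = SimulationConfig(seed=42)
wells, annotation, truth = generate_study(config)
curated = curate_matrix(wells)
groups = annotation.set_index("sample_id")["group"]
delta = delta_ct(curated, "RNU44")
panel = [a for a in expressed_panel(curated, config.control_names)
         if a in delta.values.index]
values = delta.values.loc[panel]

ms_ctrl = two_group_stats(values, groups, ("NSCLC", "control"))
ms_copd = two_group_stats(values, groups, ("NSCLC", "COPD"))
print("top 5 markers, NSCLC vs control (AUC < 0.5 = up in NSCLC):")
print(ms_ctrl.table.nsmallest(5, "p_t")[["p_t", "q", "auc", "direction"]]
      .round(5).to_string())

planted = set(truth.planted_assays(("NSCLC", "control"))) & set(panel)
sig = set(ms_ctrl.significant(adjusted=True).index)
print(f"\nplanted markers recovered at q<0.05: {len(sig & planted)}/{len(planted)}"
      f" (false positives: {len(sig - planted)})")

anova = anova_three_group(values, groups)
print(f"ANOVA: {(anova['p'] < 0.05).sum()} significant before, "
      f"{(anova['q'] < 0.05).sum()} after adjustment")

venn = venn_partition(ms_ctrl, ms_copd, alpha=0.05, use_adjusted=True)
print("\nVenn counts (adjusted p < 0.05, split by direction):")
for label, count in venn.counts().items():
    if count:
        print(f"  {label}: {count}")
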