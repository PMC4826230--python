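# mirqval

Validation analysis for blood-borne miRNA biomarker panels measured by
high-throughput qRT-PCR (Fluidigm-style dynamic arrays), aimed at studies
that take a marker signature discovered on one platform (e.g. a microarray
screen) and re-measure it on an independent cohort by qRT-PCR. The running
use case is the separation of non-small cell lung cancer (NSCLC) patients
from COPD patients and unaffected controls using whole-blood miRNA profiles.

The library covers the full workflow:

1. **Curation** — triplicate wells are filtered (no amplification, Ct beyond
   the 25-cycle linear range, amplification-curve quality score < 0.65),
   merged to the median of surviving replicates, assays with more than 10 NA
   samples dropped, and remaining NAs imputed with the assay's global mean.
2. **Normalization** — candidate endogenous controls (RNU6B, RNU24, RNU44,
   RNU48, RPL21) are ranked by SD, coefficient of variation on the Ct and
   linearized 2⁻ᶜᵗ scales, a NormFinder-style variance-decomposition
   stability value, and concordance with the screening study; the chosen
   reference yields ΔCt(a, s) = Ct(a, s) − Ct(ref, s).
3. **Differential statistics** — per marker: two-sided Welch t and
   Wilcoxon/Mann–Whitney rank-sum p-values, Benjamini–Hochberg q across the
   panel, Mann–Whitney AUC = U/(n₁n₂) with ties counted ½, one-way ANOVA for
   the three-group comparison, and the Venn partition of up/down sets.
4. **Concordance** — markers significant in the screening study (unadjusted
   p < α) are checked for directional agreement, sign(AUC − ½) on both
   platforms, with an exact binomial test against chance, a 2×2 Fisher
   variant, and the Pearson correlation of the AUC vectors.
5. **Classification** — RBF-kernel SVM panels of k markers evaluated by 10
   repetitions of stratified 10-fold cross-validation with t-test
   stepwise-forward filter selection *inside each training fold*, and a
   permutation (random-label) null to expose overtraining.

Because real patient-level Ct tables from such studies are rarely deposited,
the package ships a first-class synthetic-data generator
(`mirqval.simulate`) that emulates the measurement design — triplicates,
per-well quality scores, abundance-tiered controls, well dropout, planted
group effects with known ground truth, and a correlated screening-statistics
table — so every stage is testable end to end.

## Worked example

```python
from mirqval import (SimulationConfig, generate_study, curate_matrix,
                     delta_ct, expressed_panel, two_group_stats,
                     ClassifierConfig, cross_validate, permutation_null)

config = SimulationConfig(seed=42)          # 74/26/20 cohort, 235 assays
wells, annotation, truth = generate_study(config)
curated = curate_matrix(wells)              # 25-cycle / 0.65-quality / 10-NA rules
groups = annotation.set_index("sample_id")["group"]
delta = delta_ct(curated, "RNU44")
panel = [a for a in expressed_panel(curated, config.control_names)
         if a in delta.values.index]

res = cross_validate(delta.values.loc[panel], groups, ("NSCLC", "control"),
                     ClassifierConfig(panel_sizes=(5, 10, 50), seed=7))
for k, p in res.panels.items():
    print(f"{k:3d} markers: accuracy {p.accuracy:.1f}%, AUC {p.auc:.3f}")
```

prints (exactly, for these seeds):

```
  5 markers: accuracy 89.4%, AUC 0.896
 10 markers: accuracy 97.1%, AUC 0.979
 50 markers: accuracy 98.9%, AUC 1.000
```

89.4% of pooled held-out predictions are correct with a 5-marker panel, and
accuracy grows slightly with panel size; the matching permutation null
(`permutation_null(...)`) sits at the majority-class rate of 78.7%, so the
gap is signal rather than overtraining. The `examples/` directory walks
through each capability (simulation, curation, control ranking, marker
statistics, screening concordance, classification, full pipeline) as short
scripts that print and explain their numbers; `mirqval all --config
run.yaml` runs everything from one config file with a reproducibility
manifest.

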