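# Methods

This note documents the models, rules and conventions implemented in
`mirqval`, the parameters that matter, and what the synthetic-data generator
does and does not emulate.

## Measurement model and synthetic data

Ct (threshold cycle) is a log2-scale abundance readout: one cycle is a
two-fold change, and lower Ct means more template. The generator draws, for
every sample s and assay a,

```
merged(a, s) = baseline(a) + shift(a, group(s)) + L(s) + ε(a, s)
replicate(a, s, r) = merged(a, s) + δ(a, s, r),   r = 1..3
```

* `baseline(a)` — uniform on `target_ct_range` (default 12–24 cycles) for
  target assays; the configured tier mean for endogenous controls. The
  default control tiers are RNU48 at 8.0/1.4 (mean/total SD, cycles), RNU44
  at 12.0/2.1 and RNU6B at 20.9/2.0; RNU24 (22.0/1.1) and RPL21 (21.0/2.3)
  are only qualitatively characterized in the motivating study ("low
  abundant", RNU24 the most constant), so their tiers are fixed here once:
  high-Ct, with RNU24 given the tightest spread of the five and RPL21 the
  loosest.
* `L(s) ~ N(0, loading_sd²)` — a per-sample offset shared by *every* assay
  on the array (RNA input, reverse-transcription and loading efficiency).
  This is the component ΔCt normalization exists to remove; without it a
  reference control would only add noise to ΔCt. Default 1.0 cycles. A
  control profile's SD is its *total* between-sample SD; the intrinsic part
  is `sqrt(max(sd² − loading_sd², 0))`.
* `ε ~ N(0, biological_sd²)` — assay-intrinsic biological variation
  (default 1.0 cycles); `δ ~ N(0, replicate_sd²)` — technical triplicate
  scatter (default 0.25 cycles).
* **Planted effects.** `n_planted` target assays per contrast carry a group
  shift of exactly `effect_size` cycles (default 2.0) with random sign.
  Assays planted for NSCLC-vs-control receive the same shift in NSCLC and
  COPD so the NSCLC-vs-COPD contrast stays exactly null for them; assays
  planted for NSCLC-vs-COPD shift COPD only. Controls never shift. This is
  the only construction in which every non-planted contrast shift is
  exactly zero with disjoint planted sets.
* **Failures.** A well fails with probability
  `dropout_base + (1 − dropout_base)·logistic((Ct − (ceiling − 2.5))/0.8)`,
  so dropout rises over the last ~5 cycles below `ct_ceiling` (default 28);
  wells past the ceiling never amplify. Half of the failed wells record no
  Ct at all, the rest keep their Ct but draw a quality score from the
  "failed" Beta(4, 6) (mode ≈ 0.4) instead of the "good" Beta(9, 1.5)
  (mode ≈ 0.94), so the 0.65 quality threshold is exercised from both
  sides. The quality-score distributions are free knobs — the motivating
  platform documents only the threshold, not the score distribution.
* **Screening table.** For each target assay the synthetic screening study
  reports `AUC = 0.5 + 0.3·tanh(shift/1.5) + N(0, noise_sd)` (clipped) and a
  p-value `2·Φ(−|snr·shift + N(0,1)|)`: null assays get uniform p, planted
  assays concentrate at small p, and at `noise_sd = 0` the AUC sign equals
  the true direction exactly.

What the generator does **not** emulate: microarray intensities,
pre-amplification chemistry, plate-position/spatial effects, inter-plate
calibration drift, non-Gaussian heavy-tailed Ct noise, and correlation
between markers (assays are independent given the loading offset). Passing
tests therefore demonstrate correctness of the *procedures* under a clean
hierarchical-Gaussian design, not robustness to every artifact of real
dynamic-array data.

## Curation rules

A replicate fails for exactly one reason, checked in order: no
amplification (absent Ct), out of the linear detection range, low quality.
"Out of the linear range of detection of 25 Ct cycles" is read as *Ct above
25 is unreliable* (late amplification = below detection limit); boundaries
are inclusive for passing (Ct ≤ 25 passes, quality ≥ 0.65 passes).
Surviving replicates merge to their median — the midpoint when two survive.
A cell with no survivors is NA; assays with more than `na_limit` (10) NA
cells across *all* samples (not per group) are dropped; remaining NAs are
imputed with the assay's arithmetic mean over all observed samples, groups
pooled, computed after dropping. Pooled imputation slightly shrinks group
differences — a known, accepted property of global-mean imputation; the NA
mask and per-cell replicate-survival counts are kept so downstream users
can exclude imputed cells.

## Control stability

Four criteria are computed per candidate control. CV = sample SD / mean on
the Ct scale and on the linearized 2⁻ᶜᵗ scale (the transform is convex, so
the two scales legitimately reorder candidates). The model-based stability
follows the NormFinder variance-decomposition idea: candidate-set data are
sample-centered (mean over the *candidate set* only — full-panel centering
would leak disease signal into the reference assessment), then per gene i
and group g the intragroup variance σ²ᵢg and intergroup bias dᵢg are
estimated; centering inflates the naive variances, undone by the standard
unbiasing step (needs ≥ 3 candidates; with exactly 2 the raw variances are
used). The stability is

```
ρᵢ = mean over groups of ( |dᵢg| · γ²/(γ² + vᵢg) + sqrt(vᵢg) ),   vᵢg = σ̂²ᵢg / n_g
```

with γ² the moment estimate of the between-gene bias variance: the bias is
shrunk toward zero by its uncertainty, and the candidate is charged for its
intragroup noise. Lower is more stable. The second term is deliberately the
intragroup variation `sqrt(v)` rather than the posterior SD of the shrunken
bias — the posterior-SD variant saturates at γ for very noisy genes and can
rank an arbitrarily noisy candidate above a quiet one. A caveat at small
samples: the centered values of a perfectly constant candidate inherit its
co-candidates' noise, and with ~4 samples per group the 3-df variance
estimates flip the top rank in roughly 15% of draws; the ranking
concentrates as samples grow (<1% flips at 50 per group). With no group
labels the stability degrades to the SD across samples after centering.
Both modes are exposed because grouped use is not always possible; the
grouped default uses the primary contrast's two groups. When screening
statistics are available, each candidate additionally gets the Pearson
correlation between validation AUCs computed under its ΔCt normalization
and the screening AUCs, with the raw-Ct correlation as the no-normalization
baseline. The downstream default reference is RNU44, overridable.

## Differential statistics and orientation

The AUC of a contrast (A, B) is the Mann–Whitney probability that a random
A-sample has the larger value, ties ½; A — the first-named group — is
always the positive class. On ΔCt, AUC < 0.5 therefore means *lower* ΔCt,
i.e. *higher* expression, in A ("up_in_A"); an AUC of exactly 0.5 has no
direction. The t-test is Welch's (robust default for the 74-vs-20
imbalance; the equal-variance variant is recoverable but not reported).
All tests are two-sided. BH adjustment runs across the assays tested within
one contrast (the curated panel), on the t-test p by default. ANOVA is
one-way fixed-effects with the group of highest mean ΔCt reported per
assay. The Venn partition splits each contrast's significant set by
direction and reports all pairwise intersections, including
discordant-direction cells.

## Concordance

Only markers significant in the screening study at *unadjusted* p < α
enter, which avoids biasing the comparison by the very different panel
sizes of the two platforms. A marker is concordant iff sign(AUC − ½) agrees
across platforms; exact-0.5 AUCs are excluded from numerator and
denominator and counted separately. The primary significance statement is
the two-sided exact binomial test of the concordant count against 0.5 — the
historically used "Fisher's exact test" phrasing leaves the 2×2 table
undefined, so a Fisher variant on (significant-in-validation ×
concordant) is emitted alongside, clearly labelled, and neither printed
historical p-value is treated as reproducible. Identifier reconciliation
across miRNA nomenclature revisions is data (a user-supplied old→new
mapping), never computation; unmatched identifiers are counted and listed,
and many-to-one mappings require an explicit flag.

## Classification protocol

RBF-SVM (cost 1, kernel width 1/(n_features·variance), no inner tuning
loop), stratified 10-fold CV repeated 10 times. Marker selection — rank by
two-group t-test p ascending, ties by |AUC − ½| descending then lexical id
— is recomputed inside every training fold; whole-dataset preselection is
available behind an explicit `preselect=True` flag because it leaks test
information and inflates accuracy. Metrics are confusion-matrix rates of
the pooled fold predictions per repetition, AUC from pooled decision
values; the 95% CI is mean ± 1.96·SD over the 10 repetition means — a
reporting convention, not a distributional claim. Sensitivity always refers
to the first-named (disease) group. Since single printed signatures cannot
be reconstructed from fold-wise selection, the reported panel is the
selection-frequency consensus over all folds — a convention of this
package. The permutation null reruns the entire procedure (selection
included) per label shuffle within the contrast samples; the empirical p
uses the add-one rule (1 + #null ≥ observed)/(n_perm + 1) with 10 shuffles
by default (raise `n_permutations` for calibration work).

## Pipeline and reproducibility

`run_all` executes simulate/load → curate → rank controls → ΔCt → marker
statistics (+ ANOVA, Venn) → concordance → classification. The master seed
spawns independent child seeds per stage, so adding a stage never perturbs
earlier randomness; reruns of one config are bit-identical, recorded in
`manifest.json` via a config hash (the output directory is excluded from
the hash — where artifacts land does not change them). All tables are TSV
with a header and the sentinel `NA` for missing values.

## Test and acceptance problem sizes

The acceptance suite runs the calibration studies at the motivating
cohort's design (74/26/20, 128 assays) over 100 seeds each, with a single
loading-only reference control so the ΔCt noise SD is exactly the
configured biological SD; oracle-equivalence checks use 200 random toys for
AUC (n ≤ 12) and BH (m ≤ 50) and 3-gene/2-group/8-sample toys for the
stability estimator. The permutation-null calibration uses 20 shuffles of a
74-vs-20 null design with 30 features. These sizes keep the full suite
under a minute of compute while leaving every statistical margin at ≥ 3–4
standard errors.

## Known limitations

* Inter-plate calibration (standard-sample based) is not implemented; the
  generator does not simulate plate effects either.
* Global-mean imputation shrinks group contrasts slightly (see above).
* No geNorm/BestKeeper control-ranking alternatives, no spike-in
  normalization, no limma-style moderated statistics, no alternative
  classifiers or nested hyperparameter search — all out of scope.
* Sequence-based re-annotation between miRNA nomenclature versions is not
  performed; a mapping table must be supplied.
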