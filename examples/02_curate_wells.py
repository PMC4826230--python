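"""Turn raw triplicate wells into the final Ct matrix.

Applies the three filtering rules (no amplification, Ct above the 25-cycle
linear range, quality score below 0.65), merges surviving replicates to
their median, drops assays with more than 10 NA samples and imputes the
rest with the assay's global mean.
"""

from mirqval import SimulationConfig, curate_matrix, expressed_panel, generate_study

config = SimulationConfig(seed=42)
wells, annotation, _ = generate_study(config)
curated = curate_matrix(wells, na_limit=10, ct_limit=25.0, quality_min=0.65)

print(f"assays kept: {len(curated.assays)} of {wells['assay_id'].nunique()}")
print(f"assays dropped (>10 NA samples): {len(curated.dropped_assays)}")
for assay, reason in list(curated.dropped_assays.items())[:3]:
    print(f"  {assay}: {reason}")
print(f"cells imputed with the assay mean: {int(curated.na_mask.to_numpy().sum())}")

panel = expressed_panel(curated, controls=config.control_names)
print(f"\nexpressed target panel: {len(panel)} miRNAs (controls excluded)")
print("These are the markers deemed reliably detectable; every later stage")
print("(normalization, testing, classification) works on this panel only.")
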