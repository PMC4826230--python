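"""Generate a synthetic Fluidigm-style validation study with known truth.

Builds the default cohort (74 NSCLC / 26 COPD / 20 controls, 235 target
miRNA assays plus five endogenous controls, all in triplicate) and prints
what the generator planted, so later stages can be judged against it.
"""

from mirqval import SimulationConfig, generate_study

config = SimulationConfig(seed=42)
wells, annotation, truth = generate_study(config)

print(f"wells table: {len(wells)} rows "
      f"({annotation.shape[0]} samples x {wells['assay_id'].nunique()} assays x 3 replicates)")
print(f"failed wells without a Ct: {wells['ct'].isna().sum()}")
print(annotation.groupby('group').size().to_string())

planted = truth.planted_assays(("NSCLC", "control"))
print(f"\n{len(planted)} assays planted for NSCLC-vs-control at "
      f"|shift| = {config.effect_size} cycles, e.g. {planted[:3]}")
print("Controls carry no group shift; their printed Ct tiers (mean/SD):")
for p in config.control_profiles:
    print(f"  {p.name:6s} {p.mean_ct:5.1f} / {p.sd_ct}")
print("\nA planted shift of 2 cycles is a 4-fold abundance change (Ct is log2);")
print("the downstream stages should recover these assays and only these.")
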