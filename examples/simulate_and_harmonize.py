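"""Generate a three-scanner feature table with strong batch effects and
remove them with ComBat, printing the ANOVA pattern before and after."""

from radcombat import SimulationConfig, simulate_features, harmonize
from radcombat.assessment import anova_by_batch, rejection_rate

cfg = SimulationConfig(
    n_per_batch=[53, 42, 40],        # Siemens / Philips / GE cohort sizes
    n_features=100,
    additive_effect_scale=1.5,       # per-batch location shifts
    multiplicative_effect_range=(0.5, 2.0),  # per-batch scale distortion
    seed=0,
)
table, truth = simulate_features(cfg)
harmonized, model = harmonize(table, covariates=("class",))

before = anova_by_batch(table)
after = anova_by_batch(harmonized)
print(f"samples: {table.n_samples}, features: {table.n_features}")
print(f"ANOVA rejection rate across scanners before: "
      f"{rejection_rate(before):.2f}")
print(f"ANOVA rejection rate across scanners after:  "
      f"{rejection_rate(after):.2f}")
print(f"smallest post-ComBat p-value: "
      f"{min(r.p_value for r in after):.3f}")
# Before harmonization nearly every feature differs by scanner
# (p < 0.05); afterwards no feature does — the location/scale batch
# effects are gone while the class covariate was preserved.
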