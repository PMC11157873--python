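# radcombat

Remove scanner-manufacturer batch effects from CT radiomic features with
empirical-Bayes ComBat harmonization, and measure what that does to
downstream statistics and machine-learning classification.

Radiomic features — intensity statistics and GLCM / GLRLM / GLSZM / GLDM
texture descriptors computed from labeled image regions — are sensitive
to the scanner that acquired the image. When cohorts from several
manufacturers are pooled, per-feature ANOVA across scanners rejects for
nearly every feature and the scanners separate cleanly in PCA space,
which corrupts any model trained on the pooled table. `radcombat`
implements the location/scale harmonization model

    y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

(`i` scanner batch, `j` sample, `g` feature, `X` the protected class
covariate) and removes the estimated additive (`gamma`) and
multiplicative (`delta`) batch effects after shrinking them across
features with empirical-Bayes priors:

    y*_ijg = (y_ijg - alpha_g - X beta_g - gamma*_ig) / delta*_ig
             + alpha_g + X beta_g

The package is aimed at imaging researchers who want a tested, fully
synthetic-reproducible replica of this workflow: a generative simulator
with known ground truth, a radiomic feature extractor for labeled NIfTI
volumes, the harmonizer itself, and the assessment/evaluation harness
(ANOVA, PCA, lasso screening, five classifiers with cross-validated
metrics).

## Worked example

```python
from radcombat import SimulationConfig, simulate_features, harmonize
from radcombat.assessment import anova_by_batch, rejection_rate

cfg = SimulationConfig(
    n_per_batch=[53, 42, 40],       # three manufacturers' cohort sizes
    n_features=100,
    additive_effect_scale=1.5,      # strong per-scanner shifts
    multiplicative_effect_range=(0.5, 2.0),
    seed=0,
)
table, truth = simulate_features(cfg)
harmonized, model = harmonize(table, covariates=("class",))

print(rejection_rate(anova_by_batch(table)))       # 0.95
print(rejection_rate(anova_by_batch(harmonized)))  # 0.0
print(min(r.p_value for r in anova_by_batch(harmonized)))  # 0.894
```

Before harmonization 95% of the 100 features differ significantly
across the three scanner batches; afterwards none do — the smallest
post-harmonization p-value is 0.894 — while the texture-class effect
(`X beta_g`) is preserved because the class label is a protected
covariate. On the classification side
(`examples/select_and_evaluate.py`), harmonization lifts the random
forest's 5-fold AUC from 0.910 to 0.923 in the weak-signal regime where
batch noise matters.

More narrative scripts live in `examples/`:

- `simulate_and_harmonize.py` — the table above, end to end
- `extract_features.py` — phantom volume → NIfTI → 86 radiomic features
- `select_and_evaluate.py` — lasso screening + five-classifier arms
- `full_pipeline.py` — the whole study replica from one config

A thin CLI mirrors the stages
(`radcombat simulate|phantom|extract|select|harmonize|assess|evaluate|run-all`);
try `radcombat run-all --seed 0 --out run/`.

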