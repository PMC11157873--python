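# Methods

## Problem and model

Radiomic features computed from CT images of the same physical object
differ systematically between scanner manufacturers. `radcombat` models a
feature `g` of sample `j` acquired on scanner batch `i` as

    y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg,
    eps_ijg ~ N(0, sigma_g^2),

where `alpha_g` is the feature's overall location, `X` the protected
covariate design (here the binary texture class), `beta_g` its effect,
`gamma_ig` an additive and `delta_ig` a multiplicative batch effect. The
harmonized value is

    y*_ijg = (y_ijg - alpha_g - X beta_g - gamma*_ig) / delta*_ig
             + alpha_g + X beta_g,

with `gamma*`, `delta*` empirical-Bayes posterior estimates.

## Estimation

`fit_standardize` estimates per-batch means and covariate effects by
ordinary least squares on the batch-indicator + covariate design;
`alpha_g` is the batch-size-weighted mean of the batch parameters, so
batch effects satisfy the weighted zero-sum constraint and harmonized
data land at the pooled location rather than at a reference batch. The
pooled error variance uses denominator `N`; per-batch variances of the
standardized residuals use `ddof=1`. These conventions make the fit
numerically interchangeable with the canonical parametric ComBat, which a
test verifies directly against Bioconductor's `sva::ComBat` and against a
loop-coded, equation-by-equation reference.

`eb_hyperpriors` fits, per batch across features, a normal prior on the
standardized additive effects (empirical mean/variance) and an
inverse-gamma prior on the squared multiplicative effects by the method
of moments: `lambda = (2 s^2 + m^2)/s^2`, `theta = (m s^2 + m^3)/s^2`
from the empirical mean `m` and variance `s^2`. When the spread across
features degenerates to zero the prior falls back to a near-diffuse
inverse-gamma centered on `m`. At least 3 features are required.

`eb_adjust` iterates the two conditional posterior updates (precision-
weighted mean for `gamma*`, conditional inverse-gamma mean for
`delta*^2`) to a fixed point. Defaults: relative tolerance `1e-4`,
maximum 100 iterations; non-convergence is reported as a warning status,
never silently. `delta*^2` is floored at `1e-8` (with a warning) if a
batch has a near-zero within-batch variance.

The class label is always carried as a protected covariate; dropping it
would remove the biological signal together with the batch effects. A
single-batch table is returned unchanged with a warning.

**Approximate idempotence.** EB shrinkage is not a projection: applying
harmonization twice still moves the data slightly (a few percent of the
data scale at 20–100 features), with the change contracting geometrically
on each further pass. The suite asserts this contraction rather than
exact idempotence.

## Synthetic data

`simulate_features` draws directly from the model above: `alpha ~
N(0,1)`, `beta ~ N(0, class_effect_scale^2)`, `gamma ~ N(0,
additive_effect_scale^2)`, `delta ~ U(multiplicative_effect_range)` —
the same families the EB step assumes, so harmonization can be tested as
parameter recovery. Classes are balanced within each batch, mirroring
the paired two-cartridge design. Defaults encode the study structure:
batches of 53/42/40 samples (the three manufacturers), 100 features,
unit class effect and noise, additive scale 1.0 and multiplicative range
(0.75, 1.33); the stress setting used throughout the acceptance checks
raises these to 1.5 and (0.5, 2.0). One integer seed drives a single
named generator; identical seeds give bitwise-identical tables.

`simulate_phantom` packs equal-size labeled cubes (one-voxel margins) of
two textures into one volume: class 0 is Gaussian white noise smoothed
with a 1-voxel kernel (rubber-like speckle); class 1 is a thresholded
sum of three phase-shifted sinusoids plus noise (honeycomb-like cells).
The two are strongly separable by texture features (|Cohen's d| > 1 by a
wide margin), which is all the downstream classifiers need. What the
generator does **not** emulate: CT physics (reconstruction kernels,
FOV, slice thickness, Hounsfield calibration), spatial correlation of
scanner noise with anatomy, or imbalanced designs — so green tests here
show the pipeline's statistical machinery is correct under its model
assumptions, not that any particular clinical dataset is harmonizable.

## Feature extraction

Per ROI: Min-Max normalization to [0, 1] (a constant ROI maps to zeros),
then equal-width discretization into 25 gray levels (bin `k` covers
`[(k-1)/25, k/25)`, the value 1.0 joins the top bin). The discretization
parameter is a bin *count*: on [0,1] data this is the only
self-consistent reading.

Families and conventions (86 features total: 18 first-order, 22 GLCM, 16
GLRLM, 16 GLSZM, 14 GLDM):

- **GLCM**: symmetric pairs at distance 1, counts pooled over the 13
  unique 3D directions, normalized to sum 1. Degenerate single-level
  matrices return Correlation = 1 and Imc1 = Imc2 = 0 by convention;
  Inverse Variance sums over off-diagonal cells only.
- **GLRLM**: maximal equal-level runs pooled over the 13 directions;
  Run Percentage divides the run count by `voxels x directions` so it
  stays in (0, 1] for the pooled matrix.
- **GLSZM**: zones are 26-connected equal-level components
  (`scipy.ndimage.label` with a full structuring element).
- **GLDM**: a voxel's dependence size is itself plus the 26-neighbors
  whose level differs by at most `alpha` (default 0); counting the
  center keeps the small-dependence emphases finite.
- **First order**: intensity statistics of the normalized values;
  Entropy and Uniformity use the discretized histogram; "Percentile" is
  realized as the 10th/90th pair; Kurtosis is the raw fourth
  standardized moment (no excess correction); zero-spread moments return
  0 rather than NaN.

All matrix builders are verified exactly against brute-force pair / run /
zone / dependence enumeration on small random arrays.

## Downstream analyses

- **Selection**: lasso of class on internally standardized features
  (penalty 0.1, 1000 iterations), ranked by |coefficient|, ties broken
  lexicographically; at most `n_keep`=20 names. Selection runs once on
  the unharmonized table so both arms share one feature set.
- **ANOVA**: classical one-way fixed-effects F from the sums-of-squares
  formulas; p from the F distribution, floored at the smallest positive
  double when within-group variance vanishes; a Benjamini–Hochberg
  column is emitted alongside the (deliberately unadjusted) per-feature
  p-values; alpha = 0.05 throughout.
- **PCA**: features standardized (constant columns dropped with a
  warning), full SVD, component sign fixed so the largest-magnitude
  loading is positive. Batch mixing is summarized by the silhouette of
  batch labels in 2-component score space.
- **Distribution summaries**: quartiles by linear interpolation, Tukey
  whiskers, Gaussian KDE with Silverman bandwidth on a 256-point grid
  padded by 4 bandwidths so densities integrate to ~1.
- **Evaluation**: five models at the study's settings (see
  `radcombat.evaluation`); hidden-layer width for the neural net is 32
  units per layer (only the depth, 5, was specified — width is a
  configurable default). Splits and folds are stratified by class;
  fold metrics get normal-approximation 95% CIs (`mean ± 1.96 sd/√k`,
  clipped to [0, 1]) — a documented convention, not an exact interval.
  Standardization always uses training-fold statistics only.
  Harmonization, however, is fit on the full table *before* splitting,
  matching the study's order of operations; the mild leakage this
  implies is inherent to that design (ComBat cannot be frozen and
  applied to unseen batches), and the lasso "classifier" is thresholded
  regression at 0.5.

## Pipeline and determinism

`run_pipeline` executes simulate → select → harmonize → assess →
evaluate on both arms, writing every intermediate artifact plus a
manifest with SHA-256 hashes. One master seed expands into per-stage
seeds as `(master * 1000 + stage_offset) mod 2^31`. Constant features
(e.g. the Min-Max-pinned Maximum/Minimum/Range on the volume path) are
dropped before modeling, logged and counted in the manifest.

Problem sizes used by the shipped checks — 135 samples x 100 features,
20 replicate seeds for the ANOVA pattern, 10 for the classifier
comparison, 1800 x 500 for parameter recovery — keep every run in the
tens of seconds while leaving the statistical conclusions stable across
seeds.

## Known limitations

- Parametric EB only; the nonparametric prior variant and
  reference-batch / frozen-model modes are out of scope.
- Feature definitions follow the standard conventions listed above but
  are not bit-exact replicas of any particular extraction tool.
- The 95% CIs over 5 folds use the normal approximation; with k=5 they
  are rough.
- Per-feature 3-SE recovery checks are applied at the binomially
  expected coverage (>=99% of features) rather than elementwise, since
  with 500 features at least one |z| > 3 is expected by chance.
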