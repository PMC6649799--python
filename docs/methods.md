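# Methods

This note documents the models and procedures implemented in `cirrus`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Segmentation and quality control

A digitized CC-view film mammogram is modeled as a bright breast region
attached to exactly one lateral border (the chest wall) on a dark noisy
background, possibly with detached bright objects (view labels, markers).

Segmentation is a global Otsu threshold on the intensity histogram, followed
by morphological closing (disk, radius 5 px), hole filling, and selection of
the largest 4-connected component. Detached bright objects form separate
components and are excluded. The mask is rejected
(`segmentation_failed`) when the chosen component touches no lateral border
or both, or when its area fraction lies outside (0.05, 0.95). A helper flips
image and mask so the chest wall is on the left; texture features are flip
invariant, so this only standardizes stored masks.

Quality control rejects, in order of precedence: non-CC views; negative
images, detected as the median background intensity exceeding the median
breast intensity (a deliberately minimal, testable proxy for an inverted
film scan); and low contrast, when `(max − min)/(2^bit_depth − 1)` inside
the mask falls below `min_range_fraction` (default **0.05**, configurable —
"abnormally low" has no canonical value).

Otsu's threshold is not exactly invariant under monotone intensity
transforms: on a noisy image a remapping can flip pixels whose value
straddles the threshold. On clearly bimodal images the effect is confined to
a 1–2-pixel boundary layer, which is how the invariance is asserted in the
tests (and why a hard sub-pixel guarantee is not claimed). Pectoral-muscle
removal is not implemented: the pipeline is restricted to CC views, and the
synthetic phantoms contain no pectoral region by construction. Real MLO
input is rejected at QC.

## Digitizer-resistant GLCM features

Film digitizers differ in gain, offset and transfer curve, so raw
intensities are not comparable across studies. Breast pixels are therefore
requantized into `G` gray levels by **equal-mass (quantile) binning** within
the mask, with bin edges taken as actual data values (`inverted_cdf`
quantiles). Equal intensities always receive the same level, and the level
image — hence every downstream feature — is invariant to any strictly
monotone intensity transform. This is the strongest reproducible reading of
"resistant to digitizer settings", and it is directly testable. The
invariance is exact up to ties: a transform that merges previously distinct
intensity values (e.g. gamma followed by integer rounding) can shift bin
edges; the tests therefore apply monotone transforms in floating point.

Co-occurrence counts are accumulated for the four offsets
`(0,d), (d,0), (d,d), (d,−d)`, each together with its reverse, pooled into
one matrix **before** normalization, counting only pairs with both pixels
inside the mask. Pooling symmetric directions makes the matrix — and every
feature — *exactly* invariant under 90°/180°/270° rotations, horizontal and
vertical flips, and translation of the masked content.

Defaults: `G = 64` gray levels, offset distance `d = 1`, four directions
pooled. The feature-variant conventions (the literature has several):

* `difference_variance` is the variance of the difference distribution;
* `sum_variance` is centered on `sum_average`;
* `homogeneity` is the inverse difference moment `Σ p/(1+(i−j)²)`;
* the two normalized inverse-difference features use the IDN/IDMN
  normalizations by `G`;
* all logarithms are natural; features enter the model only after
  standardization, so the base is immaterial but fixed.

Correlation-type features (`correlation`, both information correlations) are
undefined on a degenerate matrix (zero marginal variance or entropy) and are
emitted as NaN sentinels; such images are QC-rejected in practice, and the
model drops sentinel rows at training time (scoring imputes the training
mean, i.e. standardized 0, with a warning).

GLCM features at a fixed `d` are not resolution invariant: doubling the
pixel grid halves the physical offset. Comparisons across resolutions are
meaningful only when `d` scales with the grid, which is how the stability
regression test is constructed (<5% drift of the scale-free features).

## Aggregation

A woman's feature vector is the featurewise (marginal) median over all her
QC-passing mammograms — left and right breasts and all visits pooled; even
counts use the mean of the two central values and NaN sentinels are excluded
per feature. The marginal median is the conventional reading of "median of
her features" and is robust to a single unusual film. A single-mammogram
mode (earliest visit, ties broken by image id) supports sensitivity
analyses.

## Bayesian-lasso logistic risk model

The 20 features are heavily collinear (pairwise r > 0.9 within blocks), so
maximum likelihood gives unstable weights and stepwise selection picks
features essentially at random. The model is

    y_i ~ Bernoulli(logit⁻¹(α + x_i'β)),  x standardized (mean 0, SD 1)
    β_j | τ_j² ~ N(0, τ_j²),  τ_j² | λ² ~ Exp(λ²/2)   (Laplace prior)
    λ² ~ Gamma(1, 0.1),  α ~ flat

Standardization uses the training sample (cases and controls combined,
population SD), stored with the fit and always reused at scoring time. The
global penalty λ is sampled, not tuned.

Posterior exploration is Gibbs: Pólya-Gamma augmentation renders the
logistic likelihood conditionally Gaussian (the PG(1, z) sampler is the
exact Devroye alternating-series rejection method, numba-compiled, drawing
from the fit's single seeded `numpy` Generator — identical inputs and seed
give bit-identical results); `1/τ_j²` updates are inverse-Gaussian; λ² is
conjugate Gamma. Defaults: 10 000 draws with the first 1 000 discarded as
burn-in. Split-chain potential scale reduction above 1.1 on any coefficient
raises a warning, not an error. The prior keeps estimates finite under
separation. `|β_j|` is floored at 1e-10 in the inverse-Gaussian update to
avoid a division singularity at exact zero.

The point weights are **posterior means** on the standardized scale (means,
not medians, so the score is linear in the posterior). The Cirrus score of a
woman is `Σ_j w_j (x_j − m_j)/s_j`; the intercept is omitted — the score is
relative. The Gamma(1, 0.1) hyperprior on λ² is a diffuse conventional
choice; with the sample sizes used here the likelihood dominates it.

Validation: on simulated data the sampler recovers sparse truths (n = 2000,
p = 20, 3 nonzero coefficients: signs correct, RMSE < 0.15), shrinks the L1
norm below the MLE's, splits weight across perfectly collinear duplicates
while their sum stays near the joint effect, and lands near an independent
L1-penalized optimization when the penalty is fixed at the posterior mean of
λ.

## Risk-gradient statistics

**OPERA adjustment.** The measure is regressed on age and **log BMI** by OLS
*among controls only*; residuals from that control-fitted model are computed
for all women and divided by the control-residual SD, so controls have mean
0 and SD 1 exactly. Log BMI (not raw BMI) is the covariate convention used
throughout, including the logistic models.

**OR per adjusted SD.** Logistic regression of status on the adjusted
measure plus age and log BMI; the gradient is `exp(coef)` with a 95% Wald
interval (multiplier 1.959964) and Wald p-value. Joint models (several
measures at once) use one logistic fit and report each measure's OR row.
Perfect separation raises an error directing the user to the Bayesian
module. No collinearity pruning is performed when both conventional density
measures enter one model.

**Closed forms.** For a normally distributed risk factor and a relatively
rare disease, `IQRR = Φ(log OR − b)/Φ(a − log OR)` with
`a = Φ⁻¹(0.25) = −b` (evaluated with scipy's exact quantiles, not the
rounded ±0.6745). The form is exactly 1 at OR = 1 and satisfies
`IQRR(1/OR) = 1/IQRR(OR)`. Its agreement with a numerically integrated true
logistic quartile-risk oracle is within 2% for OR in [1.2, 2.5]. Under the
equal-variance normal model `AUC = Φ(log OR/√2)` (approximately linear in
log OR over AUC 0.5–0.7), and a standardized case–control mean difference δ
implies `OR = exp(δ)`. The empirical AUC is the Mann–Whitney statistic (ties
count ½) with the Hanley–McNeil asymptotic 95% CI.

**Density transforms.** Conventional density enters as `absolute^(1/4)` and
`percent^(1/3)` (variance-stabilizing power transforms), then OPERA-adjusted
like any other measure.

**Cross-study evaluation.** For named per-woman tables, every (train, test)
pair is evaluated by fitting the score on the training study, scoring the
test study with the *training* standardization, OPERA-adjusting within the
test study, and reporting the OR per adjusted SD — the train/test grid
semantics used to establish external replication.

## Synthetic data

The generator emulates the statistical structure the pipeline relies on,
not breast anatomy.

*Images.* White noise smoothed by a Gaussian kernel of width `t` (the
woman's latent texture parameter), masked to a half-ellipse attached to the
left border, plus sensor noise (SD 8 counts at 12 bits) and, with
probability 0.2, a detached bright label rectangle scaled to the frame.
Wider kernels give large homogeneous patches (the high-risk appearance);
narrow kernels a scattered rough pattern (low risk). Extracted homogeneity
rises, and contrast falls, monotonically in `t`. `t = 0` is defined as the
degenerate no-texture limit (constant breast when sensor noise is also
zero), giving a QC-rejectable image.

*Feature-level cohorts.* Per-mammogram feature vectors come from a
two-factor Gaussian model: an 11-feature block loads on the texture factor
(loading 0.96 → pairwise |r| ≈ 0.92) with signs matching each feature's risk
direction, the remaining 9 features load on a second factor (loading 0.9 →
pairwise |r| ≈ 0.81), and the factors correlate at 0.3 (cross-block |r| <
0.3). The case–control effect is planted on the *latent texture factor* —
never on individual features — so the pipeline, not the generator, decides
which features carry signal. Per-image latent noise (SD 0.4, renormalized to
unit variance) models within-woman variation across mammograms.

*Covariates and defaults.* Age ~ U(40, 75); BMI lognormal (median 26 kg/m²,
σ = 0.15); case fraction 0.25; 2–6 images per woman; a weak negative BMI →
texture-factor link (−0.1 per SD of log BMI) so the OPERA step has real
work; planted effect **0.6** SD on the texture factor, chosen so the
end-to-end fitted gradient reproduces a realistic OR of about 1.9 per
adjusted SD. The desk-scale preset is 300 women with 10% rendered as 256×256
pixel phantoms, keeping the full suite within minutes on one CPU. Optional
conventional-density surrogates are noisy copies of the texture factor
mapped to plausible cm²/% scales such that the fourth-root transform is
linear in the noisy factor.

*What the generator does not emulate*, and hence what passing tests do not
show about real data: breast anatomy (ducts, vessels, skin line, pectoral
muscle), lesions, scanner artifacts beyond a single label rectangle,
age-dependent density trends, and the true joint distribution of GLCM
features (the factor model matches the block-correlation structure, not the
full law). The rendered-phantom feature distribution differs in location
and scale from the factor-model features, so mixed-mode studies keep the
two populations separate: rendered women validate the imaging stage, while
the risk model is fitted on the feature-level women. Mixing both in one
standardized model would manufacture an artificial outlier block.

*Evaluation semantics.* In-sample evaluation of a freshly trained
20-feature score is optimistically biased — under a null configuration the
fitted score still correlates with status in-sample, and the in-sample CI
does not cover 1. Null behavior is therefore checked under replication
semantics (train on one null study, score an independent one), matching the
cross-study design; planted-gradient runs report in-sample gradients, as
combined-data analyses conventionally do, and their optimism at n = 300 is
visible as an OR slightly above the planted 1.9.

## Problem sizes used by the test suite

Simulation-backed checks run at desk scale, chosen as the smallest sizes at
which the asserted properties are stable: sparse recovery at n = 2000;
OR-coverage at 100 replicate cohorts of n = 3000 (1:3 case:control) scored
by a model trained once at reduced draws (2000/200); the end-to-end run on
the 300-woman preset; attenuation over 20 replicates of 500 women;
co-occurrence oracle equivalence on 200 random images up to 16×16.

## Known limitations

* The segmentation contract targets the synthetic phantom geometry; real
  mammograms (skin-line gradients, pectoral muscle on mislabeled views,
  scanner edge artifacts) will need tuning of the closing radius and area
  bounds.
* Digitizer resistance by quantile quantization discards absolute-brightness
  information entirely; measures defined by brightness thresholds cannot be
  derived downstream of it.
* The λ² hyperprior and the G = 64 / d = 1 GLCM settings are conventional
  defaults, not fitted quantities; conclusions about individual feature
  weights (as opposed to the combined score) remain unstable under the
  collinearity the model is designed to absorb.
* Film-era assumptions: full-field digital mammography calibration, DICOM
  input, and MLO pectoral segmentation are out of scope.
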