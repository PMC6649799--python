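"""Synthetic mammograms and cohorts with a planted texture-risk gradient.

Every stage of the pipeline is testable without real data against this
generator, which emulates the *statistical* structure the method relies
on, with no claim of anatomical realism:

* images: a Gaussian-random-field texture (white noise smoothed with a
  Gaussian kernel) inside a half-ellipse "breast" attached to the left
  border, on a dark noisy background, optionally with a detached bright
  label rectangle.  The kernel width is the woman's latent texture
  parameter: wider kernels give larger, more homogeneous patches (the
  high-risk pattern), narrow kernels a scattered rough pattern (low
  risk), so extracted homogeneity rises and contrast falls monotonically
  with the parameter.
* feature-level cohorts: 20-dimensional per-mammogram feature vectors
  from a two-factor Gaussian model — an 11-feature block loading on the
  texture factor with pairwise correlations above 0.9, a 9-feature block
  on a second factor, weakly cross-correlated — with the case-control
  effect planted on the texture factor, never on individual features.
* covariates: age uniform over the screening range, BMI lognormal, and a
  weak negative BMI-texture link so the OPERA adjustment has work to do.

Both modes emit the same table schemas (per-mammogram features + cohort
covariates) and are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .preprocess import RawImage
from .texture import FEATURE_NAMES

# ---------------------------------------------------------------------------
# feature factor model

#: the 11 features whose risk associations are consistent across studies;
#: they load on the texture factor with the sign of their risk direction
#: (+1: higher value in the smooth/high-risk pattern).
TEXTURE_BLOCK: dict[str, int] = {
    "contrast": -1,
    "correlation": +1,
    "difference_entropy": -1,
    "difference_variance": -1,
    "dissimilarity": -1,
    "entropy": -1,
    "homogeneity": +1,
    "info_correlation_1": -1,
    "info_correlation_2": +1,
    "moment_normalized_inverse_difference": +1,
    "normalized_inverse_difference": +1,
}

#: the remaining 9 features load on a second, weakly risk-related factor.
SECOND_BLOCK: dict[str, int] = {
    "autocorrelation": +1,
    "cluster_prominence": -1,
    "cluster_shade": -1,
    "energy": +1,
    "maximum_probability": +1,
    "sum_average": +1,
    "sum_variance": +1,
    "sum_entropy": -1,
    "variance": +1,
}

_LOAD_A = 0.96   # texture-block loading -> pairwise |r| = 0.92
_LOAD_B = 0.90   # second-block loading  -> pairwise |r| = 0.81
_FACTOR_CORR = 0.30  # corr(texture factor, second factor) -> cross |r| < 0.26

#: plausible raw scales for each feature (G = 64, d = 1 extraction);
#: immaterial to the model (features are standardized) but keeps tables
#: looking like real extractions.
_FEATURE_SCALE: dict[str, tuple[float, float]] = {
    "autocorrelation": (1080.0, 60.0),
    "cluster_prominence": (3.1e6, 4e5),
    "cluster_shade": (-9000.0, 2500.0),
    "contrast": (42.0, 12.0),
    "correlation": (0.935, 0.02),
    "difference_entropy": (2.1, 0.2),
    "difference_variance": (28.0, 8.0),
    "dissimilarity": (4.4, 0.9),
    "energy": (0.0021, 0.0005),
    "entropy": (7.1, 0.3),
    "homogeneity": (0.36, 0.04),
    "info_correlation_1": (-0.30, 0.04),
    "info_correlation_2": (0.975, 0.008),
    "maximum_probability": (0.012, 0.004),
    "moment_normalized_inverse_difference": (0.994, 0.002),
    "normalized_inverse_difference": (0.955, 0.01),
    "sum_average": (65.0, 2.0),
    "sum_variance": (1340.0, 220.0),
    "sum_entropy": (5.2, 0.25),
    "variance": (345.0, 60.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (desk-scale defaults)."""

    n_women: int = 300
    case_fraction: float = 0.25
    images_per_woman_range: tuple[int, int] = (2, 6)
    image_size: int = 256
    bit_depth: int = 12
    correlation_length_case: float = 6.0    # px, Gaussian kernel sigma
    correlation_length_control: float = 3.0
    texture_effect_sd: float = 0.5          # per-woman random effect (log scale)
    planted_effect: float = 0.6             # case-control shift of the texture
                                            # factor, in its SD units; the
                                            # default reproduces a risk
                                            # gradient of OR ~ 1.9 per
                                            # adjusted SD end to end
    within_woman_sd: float = 0.4            # image-to-image latent noise
    bmi_feature_effect: float = -0.1        # texture factor per SD of log BMI
    age_range: tuple[float, float] = (40.0, 75.0)
    bmi_lognormal_params: tuple[float, float] = (np.log(26.0), 0.15)
    label_artifact_prob: float = 0.2
    sensor_noise_sd: float = 8.0            # background counts, 12-bit scale
    image_fraction: float = 0.1             # share of women rendered as pixels
    include_density: bool = False           # emit conventional-density columns
    density_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if min(self.correlation_length_case, self.correlation_length_control) <= 0:
            raise ValueError("correlation lengths must be positive")


def desk_preset(**overrides) -> SyntheticConfig:
    """The default desk-scale study conditions."""
    return replace(SyntheticConfig(), **overrides)


# ---------------------------------------------------------------------------
# image generation

def generate_image(woman_texture_param: float, config: SyntheticConfig,
                   rng: np.random.Generator,
                   image_id: str = "", woman_id: str = "",
                   visit_index: int = 0) -> tuple[RawImage, np.ndarray]:
    """Render one textured breast phantom; returns (image, truth mask).

    The texture is unit-variance white noise smoothed with a Gaussian
    kernel of width ``woman_texture_param`` (zero width is taken as the
    degenerate no-texture limit, giving a constant breast when the sensor
    noise is also zero).
    """
    size = config.image_size
    hi = 2**config.bit_depth - 1
    rows, cols = np.mgrid[0:size, 0:size]
    # half-ellipse attached to the left border (chest wall)
    a, b = 0.42 * size, 0.72 * size
    mask = ((rows - size / 2) / a) ** 2 + (cols / b) ** 2 <= 1.0

    t = float(woman_texture_param)
    if t > 0:
        field_ = rng.standard_normal((size, size))
        field_ = ndimage.gaussian_filter(field_, sigma=t, mode="reflect")
        sd = field_.std()
        field_ = field_ / sd if sd > 0 else field_
    else:
        field_ = np.zeros((size, size))

    img = np.zeros((size, size))
    img[mask] = 0.55 * hi + 0.12 * hi * field_[mask]
    img += rng.normal(0.0, config.sensor_noise_sd, (size, size))

    if rng.random() < config.label_artifact_prob:
        # detached bright label rectangle in the far corner, scaled with
        # the frame so it stays clear of the breast outline
        lh, lw = max(8, size // 13), max(16, size // 6)
        r0 = int(rng.integers(5, max(6, size // 10)))
        c0 = size - lw - 5
        img[r0:r0 + lh, c0:c0 + lw] = 0.95 * hi

    img = np.clip(np.round(img), 0, hi).astype(np.int64)
    return (
        RawImage(pixels=img, bit_depth=config.bit_depth, view="CC",
                 image_id=image_id, woman_id=woman_id, visit_index=visit_index),
        mask,
    )


# ---------------------------------------------------------------------------
# cohorts

def _covariates(config: SyntheticConfig, rng: np.random.Generator,
                n: int) -> tuple[np.ndarray, np.ndarray]:
    age = rng.uniform(*config.age_range, n)
    mu, sigma = config.bmi_lognormal_params
    bmi = rng.lognormal(mu, sigma, n)
    return age, bmi


def _latent_texture(config: SyntheticConfig, rng: np.random.Generator,
                    status: np.ndarray, bmi: np.ndarray) -> np.ndarray:
    """Per-woman texture factor: planted case-control shift + BMI link."""
    mu, sigma = config.bmi_lognormal_params
    logbmi_std = (np.log(bmi) - mu) / sigma
    z = rng.standard_normal(status.size)
    return (
        config.planted_effect * status
        + config.bmi_feature_effect * logbmi_std
        + z
    )


def sample_features(z_texture: np.ndarray, rng: np.random.Generator,
                    z_second: np.ndarray | None = None) -> pd.DataFrame:
    """Draw one feature vector per entry of the texture factor.

    ``z_texture`` should be approximately unit-SD; the factor model then
    reproduces the two-block correlation structure of real extractions.
    """
    n = z_texture.size
    if z_second is None:
        z_second = (_FACTOR_CORR * z_texture
                    + np.sqrt(1 - _FACTOR_CORR**2) * rng.standard_normal(n))
    cols = {}
    for name in FEATURE_NAMES:
        mu, sd = _FEATURE_SCALE[name]
        if name in TEXTURE_BLOCK:
            sign, load = TEXTURE_BLOCK[name], _LOAD_A
            factor = z_texture
        else:
            sign, load = SECOND_BLOCK[name], _LOAD_B
            factor = z_second
        eps = rng.standard_normal(n)
        cols[name] = mu + sd * (sign * load * factor
                                + np.sqrt(1 - load**2) * eps)
    return pd.DataFrame(cols)


def _density_columns(z_texture: np.ndarray, config: SyntheticConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Conventional-density surrogates: noisy copies of the texture factor.

    The fourth root of the absolute surrogate is linear in the noisy
    factor, so the standard transform recovers the intended structure.
    """
    noise = rng.standard_normal(z_texture.size)
    noisy = z_texture + config.density_noise_sd * noise
    fourth_root = np.clip(2.2 + 0.25 * noisy, 0.3, None)
    absolute = fourth_root**4
    noise2 = rng.standard_normal(z_texture.size)
    percent = 100.0 * stats.norm.cdf(
        0.5 * (z_texture + config.density_noise_sd * noise2) - 0.3
    )
    return {"absolute_density": absolute, "percent_density": percent}


@dataclass
class SimulatedStudy:
    """Per-mammogram feature rows, cohort covariates and generator truth."""

    per_mammogram: pd.DataFrame
    cohort: pd.DataFrame
    truth: pd.DataFrame
    images: list[tuple[RawImage, np.ndarray]] = field(default_factory=list)


def generate_cohort(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    mode: str = "features",
                    study_id: str = "S") -> SimulatedStudy:
    """Generate one synthetic study.

    mode='features' draws per-mammogram feature vectors directly from the
    factor model (fast path).  mode='images' renders every mammogram as a
    pixel phantom whose kernel width encodes the woman's texture factor;
    features must then be extracted through the imaging pipeline.
    mode='mixed' renders ``config.image_fraction`` of the women and keeps
    the rest at feature level (rendered women appear in ``images``, not
    in ``per_mammogram``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mode not in ("features", "images", "mixed"):
        raise ValueError(f"unknown mode {mode!r}")
    n = config.n_women
    n_cases = int(round(n * config.case_fraction))
    status = np.zeros(n, dtype=int)
    status[:n_cases] = 1
    woman_ids = np.array([f"{study_id}-W{i:05d}" for i in range(n)])
    age, bmi = _covariates(config, rng, n)
    z_woman = _latent_texture(config, rng, status, bmi)
    lo, hi = config.images_per_woman_range
    n_images = rng.integers(lo, hi + 1, size=n)

    # map the latent factor to a Gaussian kernel width (image mode) by
    # geometric interpolation: class-mean widths hit the configured
    # case/control correlation lengths; with no planted effect the
    # classes coincide and only the per-woman scatter remains
    log_mid = 0.5 * (np.log(config.correlation_length_case)
                     + np.log(config.correlation_length_control))
    log_gap = 0.5 * (np.log(config.correlation_length_case)
                     - np.log(config.correlation_length_control))
    if config.planted_effect > 1e-3:
        slope = 2.0 * log_gap / config.planted_effect * config.texture_effect_sd
    else:
        slope = config.texture_effect_sd * log_gap
    kernel_width = np.exp(
        log_mid + slope * (z_woman - 0.5 * config.planted_effect)
    )
    kernel_width = np.clip(
        kernel_width, 0.25 * config.correlation_length_control,
        4.0 * config.correlation_length_case,
    )

    if mode == "features":
        render = np.zeros(n, dtype=bool)
    elif mode == "images":
        render = np.ones(n, dtype=bool)
    else:
        render = rng.random(n) < config.image_fraction

    rows = []
    images: list[tuple[RawImage, np.ndarray]] = []
    for i in range(n):
        k = int(n_images[i])
        if render[i]:
            for v in range(k):
                image_id = f"{woman_ids[i]}-M{v}"
                images.append(generate_image(
                    kernel_width[i], config, rng,
                    image_id=image_id, woman_id=woman_ids[i], visit_index=v,
                ))
        else:
            # per-image latent keeps unit SD after within-woman noise
            z_img = (z_woman[i] + config.within_woman_sd
                     * rng.standard_normal(k)) / np.sqrt(
                         1 + config.within_woman_sd**2)
            feats = sample_features(z_img, rng)
            feats.insert(0, "visit_index", np.arange(k))
            feats.insert(0, "woman_id", woman_ids[i])
            feats.insert(0, "image_id",
                         [f"{woman_ids[i]}-M{v}" for v in range(k)])
            rows.append(feats)

    per_mammogram = (pd.concat(rows, ignore_index=True)
                     if rows else pd.DataFrame())
    cohort = pd.DataFrame({
        "woman_id": woman_ids, "status": status, "age": age, "bmi": bmi,
    })
    if config.include_density:
        for key, vals in _density_columns(z_woman, config, rng).items():
            cohort[key] = vals
    truth = pd.DataFrame({
        "woman_id": woman_ids,
        "z_texture": z_woman,
        "kernel_width": kernel_width,
        "rendered": render,
        "n_images": n_images,
    })
    return SimulatedStudy(per_mammogram=per_mammogram, cohort=cohort,
                          truth=truth, images=images)


def generate_risk_measure_cohort(n_cases: int, n_controls: int,
                                 true_or_per_sd: float,
                                 rng: np.random.Generator,
                                 config: SyntheticConfig | None = None,
                                 age_log_or: float = 0.03) -> pd.DataFrame:
    """Case-control cohort around a single unit-SD risk measure.

    The measure is standard normal and independent of age/BMI; disease
    risk is rare-baseline logistic in the measure (log OR per SD =
    log(true_or_per_sd)) and mildly in age, after which cases and
    controls are sampled to the requested counts — so the conditional OR
    per adjusted SD equals ``true_or_per_sd`` by construction.
    """
    config = config or SyntheticConfig()
    pool = max(20 * (n_cases + n_controls), 5000)
    age, bmi = _covariates(config, rng, pool)
    measure = rng.standard_normal(pool)
    logit = -2.5 + np.log(true_or_per_sd) * measure + age_log_or * (age - 55.0)
    y = rng.random(pool) < special.expit(logit)
    case_idx = np.flatnonzero(y)
    control_idx = np.flatnonzero(~y)
    if case_idx.size < n_cases or control_idx.size < n_controls:
        raise RuntimeError("pool too small for requested case/control counts")
    take = np.concatenate([
        rng.choice(case_idx, n_cases, replace=False),
        rng.choice(control_idx, n_controls, replace=False),
    ])
    return pd.DataFrame({
        "woman_id": [f"R{i:06d}" for i in range(take.size)],
        "status": y[take].astype(int),
        "age": age[take],
        "bmi": bmi[take],
        "measure": measure[take],
    })
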