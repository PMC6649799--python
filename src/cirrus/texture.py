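"""Digitizer-resistant gray-level co-occurrence matrix (GLCM) features.

Second-order texture statistics describe the joint distribution of the
gray levels of pixel pairs at a fixed spatial offset, rather than the
brightness histogram alone.  Film digitizers differ in gain, offset and
transfer curve, so raw intensities are not comparable across studies;
here the breast pixels are first requantized by *equal-mass* (quantile)
binning within the breast mask, which makes every downstream feature
invariant to any strictly monotone intensity transform — gain, offset and
gamma differences between digitizers are all absorbed.

Co-occurrence counts are pooled over the four symmetric offsets
(0,d), (d,0), (d,d), (d,-d), each counted in both directions, before
normalization.  Pooling makes the matrix — and every feature — exactly
invariant to 90/180/270-degree rotations, to horizontal and vertical
flips, and to translation of the masked content.

The 20 features computed here are the classical Haralick-family scalars
(contrast, correlation, entropy, homogeneity, ...) in their most common
modern conventions; see :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BreastMask, RawImage

#: Canonical feature order used in all tables and fitted models.
FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "info_correlation_1",
    "info_correlation_2",
    "maximum_probability",
    "moment_normalized_inverse_difference",
    "normalized_inverse_difference",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "variance",
)

DEFAULT_GRAY_LEVELS = 64
DEFAULT_DISTANCE = 1


@dataclass
class QuantizedImage:
    """Breast pixels mapped to levels 1..G; 0 marks pixels outside the mask."""

    levels: np.ndarray
    G: int
    mask: np.ndarray


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric pair-probability matrix p(i, j), i, j in 1..G."""

    p: np.ndarray
    G: int
    offsets_used: list[tuple[int, int]] = field(default_factory=list)


def quantize(image: RawImage | np.ndarray, mask: BreastMask | np.ndarray,
             G: int = DEFAULT_GRAY_LEVELS) -> QuantizedImage:
    """Equal-mass quantization of masked intensities into G gray levels.

    Bin edges are empirical quantiles taken as actual data values
    (``method='inverted_cdf'``), so equal intensities always map to the
    same level and the level image is unchanged by any strictly
    increasing transform of the intensities.

    Raises ValueError when the masked pixels hold fewer than G distinct
    values (levels would be degenerate).
    """
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    if G < 2:
        raise ValueError("G must be >= 2")
    values = np.asarray(pixels, dtype=np.float64)[m]
    if np.unique(values).size < G:
        raise ValueError(
            f"masked pixels have fewer than G={G} distinct values"
        )
    edges = np.quantile(values, np.arange(1, G) / G, method="inverted_cdf")
    levels = np.zeros(pixels.shape, dtype=np.int32)
    levels[m] = np.searchsorted(edges, values, side="left") + 1
    return QuantizedImage(levels=levels, G=G, mask=m)


_OFFSETS = lambda d: [(0, d), (d, 0), (d, d), (d, -d)]


def cooccurrence(q: QuantizedImage, distance: int = DEFAULT_DISTANCE) -> CooccurrenceMatrix:
    """Pooled symmetric co-occurrence matrix at the given pixel distance.

    Ordered pairs are counted for the four offsets (0,d), (d,0), (d,d),
    (d,-d), each together with its reverse; only pairs with both pixels
    inside the mask contribute.  Counts are pooled across offsets and
    normalized to sum 1.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    G = q.G
    lv = q.levels
    counts = np.zeros((G, G), dtype=np.float64)
    offsets = _OFFSETS(distance)
    nrow, ncol = lv.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = (a > 0) & (b > 0)
        ai = a[valid] - 1
        bi = b[valid] - 1
        flat = np.bincount(ai * G + bi, minlength=G * G).reshape(G, G)
        counts += flat
        counts += flat.T  # reverse offset
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs inside the mask")
    return CooccurrenceMatrix(p=counts / total, G=G, offsets_used=offsets)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 log 0 := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def compute_features(M: CooccurrenceMatrix) -> dict[str, float]:
    """The 20 GLCM scalar features of a pooled co-occurrence matrix.

    Indices run 1..G.  Correlation-type features (correlation and the two
    information correlations) are undefined for a degenerate matrix
    (zero marginal variance or zero marginal entropy) and are returned as
    NaN sentinels; all other features remain valid.
    """
    p = M.p
    G = M.G
    i = np.arange(1, G + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    # sum distribution p_{x+y}(k), k = 2..2G; difference |i-j| = 0..G-1
    k_sum = np.arange(2, 2 * G + 1, dtype=np.float64)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, G, dtype=np.float64)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())

    HX = _entropy(px)
    HY = _entropy(py)
    HXY = _entropy(p.ravel())
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log(pxpy), 0.0)
    HXY1 = float(-(p * log_pxpy).sum())
    HXY2 = _entropy(pxpy.ravel())

    sum_average = float((k_sum * p_sum).sum())
    diff_mean = float((k_diff * p_diff).sum())

    f: dict[str, float] = {}
    f["autocorrelation"] = float((I * J * p).sum())
    dev = I + J - mu_x - mu_y
    f["cluster_prominence"] = float((dev**4 * p).sum())
    f["cluster_shade"] = float((dev**3 * p).sum())
    f["contrast"] = float(((I - J) ** 2 * p).sum())
    if sd_x * sd_y > 0:
        f["correlation"] = float(((I - mu_x) * (J - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        f["correlation"] = float("nan")
    f["difference_entropy"] = _entropy(p_diff)
    f["difference_variance"] = float((k_diff**2 * p_diff).sum() - diff_mean**2)
    f["dissimilarity"] = float((np.abs(I - J) * p).sum())
    f["energy"] = float((p**2).sum())
    f["entropy"] = HXY
    f["homogeneity"] = float((p / (1.0 + (I - J) ** 2)).sum())
    if max(HX, HY) > 0:
        f["info_correlation_1"] = (HXY - HXY1) / max(HX, HY)
        f["info_correlation_2"] = float(
            np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY))))
        )
    else:
        f["info_correlation_1"] = float("nan")
        f["info_correlation_2"] = float("nan")
    f["maximum_probability"] = float(p.max())
    f["moment_normalized_inverse_difference"] = float(
        (p / (1.0 + (I - J) ** 2 / G**2)).sum()
    )
    f["normalized_inverse_difference"] = float(
        (p / (1.0 + np.abs(I - J) / G)).sum()
    )
    f["sum_average"] = sum_average
    f["sum_variance"] = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    f["sum_entropy"] = _entropy(p_sum)
    f["variance"] = float(((I - mu_x) ** 2 * p).sum())
    return {name: f[name] for name in FEATURE_NAMES}


def extract(image: RawImage | np.ndarray, mask: BreastMask | np.ndarray,
            G: int = DEFAULT_GRAY_LEVELS,
            distance: int = DEFAULT_DISTANCE) -> dict[str, float]:
    """quantize -> cooccurrence -> compute_features for one mammogram."""
    q = quantize(image, mask, G=G)
    M = cooccurrence(q, distance=distance)
    return compute_features(M)
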