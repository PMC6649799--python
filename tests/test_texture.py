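"""GLCM quantization, co-occurrence counting and the 20 texture features.

The co-occurrence path is checked against an exhaustive brute-force pair
enumeration, against skimage's unmasked GLCM on full-frame images, and
the feature formulas against an independent naive double-loop
implementation and hand-evaluated 2x2 matrices.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cirrus.texture import (
    FEATURE_NAMES,
    CooccurrenceMatrix,
    compute_features,
    cooccurrence,
    extract,
    quantize,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_cooccurrence(levels: np.ndarray, G: int, d: int) -> np.ndarray:
    """Exhaustive enumeration of ordered pixel pairs over the 4 offsets."""
    H, W = levels.shape
    counts = np.zeros((G, G))
    for r in range(H):
        for c in range(W):
            if levels[r, c] == 0:
                continue
            for dr, dc in [(0, d), (d, 0), (d, d), (d, -d)]:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and levels[r2, c2] > 0:
                    counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                    counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return counts / counts.sum()


def naive_features(p: np.ndarray) -> dict:
    """Straightforward loop evaluation of every feature formula."""
    G = p.shape[0]
    idx = range(1, G + 1)
    px = [sum(p[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1, j - 1] for i in idx) for j in idx]
    mx = sum(i * px[i - 1] for i in idx)
    my = sum(j * py[j - 1] for j in idx)
    sx = np.sqrt(sum((i - mx) ** 2 * px[i - 1] for i in idx))
    sy = np.sqrt(sum((j - my) ** 2 * py[j - 1] for j in idx))
    psum = {k: 0.0 for k in range(2, 2 * G + 1)}
    pdiff = {k: 0.0 for k in range(G)}
    for i in idx:
        for j in idx:
            psum[i + j] += p[i - 1, j - 1]
            pdiff[abs(i - j)] += p[i - 1, j - 1]

    def ent(vals):
        return -sum(v * np.log(v) for v in vals if v > 0)

    HX, HY = ent(px), ent(py)
    HXY = ent(p.ravel())
    HXY1 = -sum(
        p[i - 1, j - 1] * np.log(px[i - 1] * py[j - 1])
        for i in idx for j in idx
        if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0
    )
    HXY2 = ent([px[i - 1] * py[j - 1] for i in idx for j in idx])
    savg = sum(k * v for k, v in psum.items())
    dmean = sum(k * v for k, v in pdiff.items())
    f = {
        "autocorrelation": sum(i * j * p[i - 1, j - 1] for i in idx for j in idx),
        "cluster_prominence": sum(
            (i + j - mx - my) ** 4 * p[i - 1, j - 1] for i in idx for j in idx),
        "cluster_shade": sum(
            (i + j - mx - my) ** 3 * p[i - 1, j - 1] for i in idx for j in idx),
        "contrast": sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx),
        "correlation": (
            sum((i - mx) * (j - my) * p[i - 1, j - 1] for i in idx for j in idx)
            / (sx * sy) if sx * sy > 0 else np.nan),
        "difference_entropy": ent(pdiff.values()),
        "difference_variance": sum(k**2 * v for k, v in pdiff.items()) - dmean**2,
        "dissimilarity": sum(abs(i - j) * p[i - 1, j - 1] for i in idx for j in idx),
        "energy": sum(v**2 for v in p.ravel()),
        "entropy": HXY,
        "homogeneity": sum(
            p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx),
        "info_correlation_1": ((HXY - HXY1) / max(HX, HY)
                               if max(HX, HY) > 0 else np.nan),
        "info_correlation_2": (np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY))))
                               if max(HX, HY) > 0 else np.nan),
        "maximum_probability": p.max(),
        "moment_normalized_inverse_difference": sum(
            p[i - 1, j - 1] / (1 + (i - j) ** 2 / G**2) for i in idx for j in idx),
        "normalized_inverse_difference": sum(
            p[i - 1, j - 1] / (1 + abs(i - j) / G) for i in idx for j in idx),
        "sum_average": savg,
        "sum_variance": sum((k - savg) ** 2 * v for k, v in psum.items()),
        "sum_entropy": ent(psum.values()),
        "variance": sum((i - mx) ** 2 * p[i - 1, j - 1] for i in idx for j in idx),
    }
    return f


# ---------------------------------------------------------------------------
# quantization


def test_quantize_median_split():
    pixels = np.array([[10, 20], [30, 40]])
    mask = np.ones((2, 2), dtype=bool)
    # per-pixel levels follow the empirical median split
    q = quantize(pixels, mask, G=2)
    assert q.levels.tolist() == [[1, 1], [2, 2]]


def test_quantize_requires_distinct_values():
    pixels = np.full((4, 4), 7)
    with pytest.raises(ValueError, match="distinct"):
        quantize(pixels, np.ones((4, 4), bool), G=2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(2, 6))
def test_quantize_monotone_invariance(seed, G):
    """Any strictly increasing intensity remapping leaves levels unchanged."""
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 500, (12, 12))
    mask = rng.random((12, 12)) < 0.8
    if np.unique(pixels[mask]).size < G:
        return
    q1 = quantize(pixels, mask, G=G)
    affine = quantize(pixels * 3 + 7, mask, G=G)
    gamma = quantize(np.power(pixels.astype(float), 1.7), mask, G=G)
    assert np.array_equal(q1.levels, affine.levels)
    assert np.array_equal(q1.levels, gamma.levels)


def test_quantize_equal_mass_occupancy():
    rng = np.random.default_rng(0)
    pixels = rng.random((100, 100))
    mask = np.ones((100, 100), bool)
    q = quantize(pixels, mask, G=16)
    occ = np.bincount(q.levels.ravel(), minlength=17)[1:] / mask.sum()
    assert (occ > 0.9 / 16).all() and (occ < 1.1 / 16).all()


# ---------------------------------------------------------------------------
# co-occurrence


def test_cooccurrence_single_pair():
    levels = np.array([[1, 2]])
    from cirrus.texture import QuantizedImage
    M = cooccurrence(QuantizedImage(levels=levels, G=2,
                                    mask=np.ones((1, 2), bool)), distance=1)
    expected = np.array([[0.0, 0.5], [0.5, 0.0]])
    assert np.allclose(M.p, expected)


@pytest.mark.parametrize("seed", range(8))
def test_cooccurrence_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    G = int(rng.integers(2, 5))
    shape = tuple(rng.integers(6, 14, 2))
    levels = rng.integers(1, G + 1, shape)
    mask = rng.random(shape) < 0.85
    levels = np.where(mask, levels, 0)
    from cirrus.texture import QuantizedImage
    d = int(rng.integers(1, 3))
    M = cooccurrence(QuantizedImage(levels=levels, G=G, mask=mask), distance=d)
    assert np.array_equal(M.p, brute_force_cooccurrence(levels, G, d))


def test_cooccurrence_is_symmetric_and_normalized():
    rng = np.random.default_rng(3)
    pixels = rng.integers(0, 4096, (64, 64))
    q = quantize(pixels, np.ones((64, 64), bool), G=8)
    M = cooccurrence(q)
    assert abs(M.p.sum() - 1.0) < 1e-12
    assert np.max(np.abs(M.p - M.p.T)) < 1e-12
    assert (M.p >= 0).all()


def test_cooccurrence_rotation_exact():
    rng = np.random.default_rng(9)
    from cirrus.texture import QuantizedImage
    levels = rng.integers(1, 5, (10, 14))
    q = QuantizedImage(levels=levels, G=4, mask=np.ones(levels.shape, bool))
    qr = QuantizedImage(levels=np.rot90(levels), G=4,
                        mask=np.ones(levels.T.shape, bool))
    assert np.array_equal(cooccurrence(q).p, cooccurrence(qr).p)


def test_cooccurrence_no_pairs_error():
    from cirrus.texture import QuantizedImage
    levels = np.zeros((5, 5), dtype=int)
    levels[2, 2] = 1  # a single masked pixel has no neighbour pairs
    mask = levels > 0
    with pytest.raises(ValueError, match="no valid"):
        cooccurrence(QuantizedImage(levels=levels, G=2, mask=mask), distance=1)


def test_cooccurrence_matches_skimage_on_full_frame():
    """Unmasked pooled counting agrees with skimage's graycomatrix."""
    from skimage.feature import graycomatrix

    rng = np.random.default_rng(11)
    levels = rng.integers(1, 9, (40, 40))
    from cirrus.texture import QuantizedImage
    ours = cooccurrence(QuantizedImage(levels=levels, G=8,
                                       mask=np.ones(levels.shape, bool)))
    sk = graycomatrix(
        (levels - 1).astype(np.uint8), distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=8, symmetric=True, normed=False,
    ).astype(float).sum(axis=3)[..., 0]
    assert np.allclose(ours.p, sk / sk.sum())


# ---------------------------------------------------------------------------
# features


def test_features_hand_values_diagonal_matrix():
    M = CooccurrenceMatrix(p=np.array([[0.5, 0.0], [0.0, 0.5]]), G=2)
    f = compute_features(M)
    assert f["energy"] == pytest.approx(0.5)
    assert f["entropy"] == pytest.approx(np.log(2))
    assert f["contrast"] == 0.0
    assert f["maximum_probability"] == pytest.approx(0.5)
    assert f["autocorrelation"] == pytest.approx(2.5)
    assert f["correlation"] == pytest.approx(1.0)


def test_features_hand_values_antidiagonal_matrix():
    M = CooccurrenceMatrix(p=np.array([[0.0, 0.5], [0.5, 0.0]]), G=2)
    f = compute_features(M)
    assert f["contrast"] == pytest.approx(1.0)
    assert f["correlation"] == pytest.approx(-1.0)
    assert f["homogeneity"] == pytest.approx(0.5)
    assert f["sum_average"] == pytest.approx(3.0)


def test_features_degenerate_constant_image():
    p = np.zeros((4, 4))
    p[2, 2] = 1.0
    f = compute_features(CooccurrenceMatrix(p=p, G=4))
    assert f["energy"] == 1.0
    assert f["entropy"] == 0.0
    assert f["contrast"] == 0.0
    assert f["dissimilarity"] == 0.0
    assert f["homogeneity"] == 1.0
    assert f["maximum_probability"] == 1.0
    assert f["difference_variance"] == 0.0
    assert np.isnan(f["correlation"])
    assert np.isnan(f["info_correlation_1"])


@pytest.mark.parametrize("seed", range(5))
def test_features_match_naive_implementation(seed):
    rng = np.random.default_rng(seed)
    G = int(rng.integers(2, 7))
    raw = rng.random((G, G))
    p = raw + raw.T
    p /= p.sum()
    ours = compute_features(CooccurrenceMatrix(p=p, G=G))
    naive = naive_features(p)
    for name in FEATURE_NAMES:
        assert ours[name] == pytest.approx(naive[name], rel=1e-10), name


def test_feature_ranges_and_identities():
    rng = np.random.default_rng(21)
    pixels = rng.integers(0, 4096, (80, 80))
    q = quantize(pixels, np.ones((80, 80), bool), G=16)
    M = cooccurrence(q)
    f = compute_features(M)
    assert 0 < f["energy"] <= 1
    assert 0 < f["maximum_probability"] <= 1
    assert 0 < f["homogeneity"] <= 1
    assert f["entropy"] >= 0 and f["contrast"] >= 0
    assert -1 <= f["correlation"] <= 1
    assert 0 <= f["info_correlation_2"] <= 1
    # contrast equals the second moment of the difference distribution
    i = np.arange(1, 17)
    I, J = np.meshgrid(i, i, indexing="ij")
    p_diff = np.zeros(16)
    np.add.at(p_diff, np.abs(I - J).ravel(), M.p.ravel())
    assert abs(p_diff.sum() - 1) < 1e-12
    assert abs(f["contrast"] - (np.arange(16) ** 2 * p_diff).sum()) < 1e-12


# ---------------------------------------------------------------------------
# composed extraction


def test_extract_invariances(segmented_phantom):
    image, mask = segmented_phantom
    pixels = image.pixels.astype(float)
    m = mask.mask
    base = extract(pixels, m, G=32)
    flipped = extract(pixels[:, ::-1], m[:, ::-1], G=32)
    rotated = extract(np.rot90(pixels), np.rot90(m), G=32)
    gamma = extract(np.power(pixels / pixels.max(), 2.2), m, G=32)
    for name in FEATURE_NAMES:
        assert base[name] == flipped[name], name
        assert base[name] == rotated[name], name
        assert base[name] == gamma[name], name


def test_extract_translation_invariance():
    rng = np.random.default_rng(2)
    pixels = rng.integers(0, 1000, (40, 40))
    mask = np.zeros((40, 40), bool)
    mask[5:25, 5:25] = True
    shifted_pixels = np.roll(np.roll(pixels, 7, axis=0), -3, axis=1)
    shifted_mask = np.roll(np.roll(mask, 7, axis=0), -3, axis=1)
    a = extract(pixels, mask, G=8)
    b = extract(shifted_pixels, shifted_mask, G=8)
    for name in FEATURE_NAMES:
        assert a[name] == b[name], name


def test_smoother_texture_is_more_homogeneous(phantom_config):
    """Long-range smooth texture scores higher homogeneity than rough
    texture with the same marginal histogram (quantile-matched)."""
    from cirrus.preprocess import segment_breast
    from cirrus.synthetic import generate_image

    rng = np.random.default_rng(7)
    homog = []
    for width in (1.5, 6.0):
        vals = []
        for _ in range(4):
            img, _ = generate_image(width, phantom_config, rng)
            mask = segment_breast(img)
            vals.append(extract(img, mask, G=32)["homogeneity"])
        homog.append(np.mean(vals))
    assert homog[1] > homog[0]


def test_feature_stability_under_resolution_doubling(phantom_config):
    """Scale-free features move < 5% when a smooth texture is rendered at
    twice the resolution (kernel width and offset scaled with the grid)."""
    from dataclasses import replace

    from cirrus.preprocess import segment_breast
    from cirrus.synthetic import generate_image

    scale_free = ("energy", "entropy", "homogeneity", "correlation")
    rng = np.random.default_rng(15)
    cfg_lo = replace(phantom_config, image_size=128)
    cfg_hi = replace(phantom_config, image_size=256)
    lo = np.zeros(len(scale_free))
    hi = np.zeros(len(scale_free))
    n_rep = 6
    for _ in range(n_rep):
        img, _ = generate_image(4.0, cfg_lo, rng)
        f = extract(img, segment_breast(img), G=16)
        lo += [f[k] for k in scale_free]
        img, _ = generate_image(8.0, cfg_hi, rng)
        f = extract(img, segment_breast(img), G=16, distance=2)
        hi += [f[k] for k in scale_free]
    rel = np.abs(hi - lo) / np.abs(lo)
    assert (rel < 0.05).all(), dict(zip(scale_free, rel))
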