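"""Feature battery: hand-checked values, analytic limits, brute-force oracles."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from capsuletex import convert, features, synthgen
from capsuletex.features import (
    FEATURE_NAMES,
    BinaryImage,
    OrientationMap,
    binarize,
    build_glcm,
    extract_feature_vector,
    fractal_dimension,
    glcm_features,
    histogram_features,
    orientation_features,
    orientation_map,
    tc_ratio,
    triangle_threshold,
    triangle_threshold_from_histogram,
)

# ---------------------------------------------------------------------------
# independent oracles


def glcm_oracle(img, distance, angles_deg, symmetric, levels):
    """Two-loop GLCM construction: count pairs at (d sin, d cos) offsets."""
    h, w = img.shape
    mats = []
    for ang in angles_deg:
        dr = round(distance * math.sin(math.radians(ang)))
        dc = round(distance * math.cos(math.radians(ang)))
        m = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    m[img[r, c], img[r2, c2]] += 1
                    if symmetric:
                        m[img[r2, c2], img[r, c]] += 1
        mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def glcm_stats_oracle(p):
    """Two-loop evaluation of the five GLCM statistics."""
    g = p.shape[0]
    asm = contrast = idm = entropy = 0.0
    mu_x = mu_y = 0.0
    for i in range(g):
        for j in range(g):
            asm += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            idm += p[i, j] / (1 + (i - j) ** 2)
            if p[i, j] > 0:
                entropy -= p[i, j] * math.log(p[i, j])
            mu_x += i * p[i, j]
            mu_y += j * p[i, j]
    var_x = sum((i - mu_x) ** 2 * p[i, j] for i in range(g) for j in range(g))
    var_y = sum((j - mu_y) ** 2 * p[i, j] for i in range(g) for j in range(g))
    if var_x * var_y <= 0:
        corr = 0.0
    else:
        corr = sum(
            (i - mu_x) * (j - mu_y) * p[i, j] for i in range(g) for j in range(g)
        ) / math.sqrt(var_x * var_y)
    return asm, contrast, corr, idm, entropy


def triangle_oracle(hist):
    """Exhaustive perpendicular-distance maximization over all bins."""
    hist = np.asarray(hist, float)
    nz = np.flatnonzero(hist)
    peak = int(hist.argmax())
    lo, hi = int(nz[0]), int(nz[-1])
    if lo == hi:
        return lo
    tail = lo if (peak - lo) > (hi - peak) else hi
    if tail == peak:
        tail = lo if tail == hi else hi
    a, b = sorted((peak, tail))
    best, best_d = None, -1.0
    for i in range(a, b + 1):
        d = abs(
            (tail - peak) * (hist[i] - hist[peak]) - (hist[tail] - hist[peak]) * (i - peak)
        )
        if d > best_d + 1e-9:
            best, best_d = i, d
        elif abs(d - best_d) <= 1e-9 and abs(i - peak) < abs(best - peak):
            best = i
    return best


# ---------------------------------------------------------------------------
# histogram moments


def test_histogram_moments_hand_example():
    mean, sd, skew, _ = histogram_features(np.array([[10, 10], [20, 20]], np.uint8))
    assert mean == 15.0
    assert sd == pytest.approx(5.7735, abs=1e-4)
    assert skew == 0.0


def test_constant_image_moment_conventions():
    assert histogram_features(np.full((8, 8), 42, np.uint8)) == (42.0, 0.0, 0.0, 0.0)


def test_skewness_matches_moment_oracle():
    vals = np.array([0, 0, 0, 12], dtype=float)
    m2 = ((vals - 3) ** 2).mean()
    m3 = ((vals - 3) ** 3).mean()
    _, _, skew, _ = histogram_features(vals.reshape(2, 2).astype(np.uint8))
    assert skew == pytest.approx(m3 / m2**1.5, abs=1e-12)
    assert skew == pytest.approx(1.1547, abs=1e-4)


def test_histogram_path_matches_direct_sample_moments(rng):
    img = rng.integers(0, 256, (40, 40), dtype=np.uint8)
    from_hist = histogram_features(img)
    direct = features._moment_stats(img.astype(float))
    np.testing.assert_allclose(from_hist, direct, atol=1e-9)


# ---------------------------------------------------------------------------
# GLCM


def test_glcm_two_pixel_pairs_hand_enumeration():
    img = np.array([[0, 0], [1, 1]], np.uint8)
    M = build_glcm(img, distance=1, angles_deg=(0.0,), levels=256)
    assert M.probabilities[0, 0] == pytest.approx(0.5)
    assert M.probabilities[1, 1] == pytest.approx(0.5)
    assert M.probabilities.sum() == pytest.approx(1.0)


def test_constant_image_glcm_is_a_single_entry():
    M = build_glcm(np.full((6, 6), 9, np.uint8), angles_deg=(0.0, 90.0))
    assert M.probabilities[9, 9] == pytest.approx(1.0)


def test_symmetric_glcm_equals_transpose(rng):
    img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
    M = build_glcm(img, symmetric=True)
    np.testing.assert_allclose(M.probabilities, M.probabilities.T, atol=1e-12)


def test_glcm_distance_validation():
    with pytest.raises(ValueError):
        build_glcm(np.zeros((4, 4), np.uint8), distance=4)


def test_glcm_construction_matches_two_loop_oracle(rng):
    img = (rng.integers(0, 256, (14, 14)) * 8 // 256).astype(np.uint8)
    for symmetric in (False, True):
        M = build_glcm(
            img, distance=1, angles_deg=(0.0, 45.0, 90.0, 135.0),
            symmetric=symmetric, levels=256,
        )
        oracle = glcm_oracle(img, 1, (0.0, 45.0, 90.0, 135.0), symmetric, 256)
        np.testing.assert_allclose(M.probabilities, oracle, atol=1e-9)


def test_glcm_statistics_hand_values():
    p = np.zeros((2, 2))
    p[0, 0] = p[1, 1] = 0.5
    asm, contrast, corr, idm, entropy = glcm_features(p)
    assert asm == pytest.approx(0.5)
    assert contrast == 0.0
    assert idm == pytest.approx(1.0)
    assert entropy == pytest.approx(math.log(2), abs=1e-12)
    assert corr == pytest.approx(1.0)


def test_constant_image_glcm_statistic_conventions():
    M = build_glcm(np.full((8, 8), 7, np.uint8))
    asm, contrast, corr, idm, entropy = glcm_features(M)
    assert (asm, contrast, corr, idm, entropy) == (1.0, 0.0, 0.0, 1.0, 0.0)


def test_checkerboard_contrast_and_idm():
    img = np.indices((16, 16)).sum(axis=0) % 2 * 255
    M = build_glcm(img.astype(np.uint8), distance=1, angles_deg=(0.0,))
    asm, contrast, _, idm, _ = glcm_features(M)
    assert contrast == pytest.approx(255**2)
    assert idm == pytest.approx(1 / (1 + 255**2))
    assert asm == pytest.approx(0.5)


def test_glcm_statistics_match_two_loop_oracle(rng):
    for _ in range(5):
        img = (rng.integers(0, 256, (12, 12)) // 16 * 16).astype(np.uint8)
        M = build_glcm(img)
        np.testing.assert_allclose(
            glcm_features(M), glcm_stats_oracle(M.probabilities), atol=1e-9
        )


def test_unnormalized_matrix_is_rejected():
    with pytest.raises(ValueError):
        glcm_features(np.ones((4, 4)))


def test_asm_entropy_and_contrast_idm_anticorrelate_with_noise():
    """Across tiles of increasing noise, ASM falls as Entropy rises and IDM
    falls as Contrast rises."""
    stats = []
    for i, noise in enumerate(np.linspace(0.0, 30.0, 8)):
        params = synthgen.FiberParams(noise_sd=float(noise))
        tile = synthgen.make_fiber_tile(96, params, seed=100 + i)
        M = build_glcm(convert.convert_8b(tile))
        stats.append(glcm_features(M))
    asm, contrast, _, idm, entropy = map(np.array, zip(*stats))
    assert scipy.stats.spearmanr(asm, entropy).statistic < 0
    assert scipy.stats.spearmanr(contrast, idm).statistic < 0


# ---------------------------------------------------------------------------
# orientation


def test_horizontal_stripes_orient_at_zero_degrees():
    img = 127.5 + 100 * np.sin(2 * np.pi * np.arange(128) / 16)
    img = np.tile(img[:, None], (1, 128)).astype(np.uint8)
    omap = orientation_map(img)
    assert abs(np.median(omap.angles_deg[omap.valid])) < 2.0


@pytest.mark.parametrize("angle", [30.0, -45.0, 60.0])
def test_orientation_mode_follows_planted_stripe_angle(angle):
    params = synthgen.FiberParams(
        orientation_deg=angle, orientation_jitter_deg=0.0, waviness=0.0,
        noise_sd=0.0, n_waves=1, od_contrast=0.5,
    )
    tile = synthgen.make_fiber_tile(128, params, seed=2)
    omap = orientation_map(convert.convert_8b(tile))
    angles = omap.angles_deg[omap.valid]
    hist, edges = np.histogram(angles, bins=180, range=(-90, 90))
    mode = edges[hist.argmax()] + 0.5
    assert abs((mode - angle + 90) % 180 - 90) < 3.0


def test_constant_image_has_no_valid_orientation():
    omap = orientation_map(np.full((32, 32), 7, np.uint8))
    assert not omap.valid.any()
    assert orientation_features(omap) == (0.0, 0.0, 0.0)


def test_aligned_stripes_have_small_orientation_spread():
    params = synthgen.FiberParams(
        orientation_deg=0.0, orientation_jitter_deg=0.0, waviness=0.0,
        noise_sd=0.0, n_waves=1, od_contrast=0.5,
    )
    tile = synthgen.make_fiber_tile(128, params, seed=5)
    sd, _, _ = orientation_features(orientation_map(convert.convert_8b(tile)))
    assert sd < 3.0


def test_uniform_angles_have_analytic_spread(rng):
    angles = rng.uniform(-90, 90, (100, 100))
    omap = OrientationMap(angles, np.ones_like(angles, dtype=bool))
    sd, _, _ = orientation_features(omap)
    assert sd == pytest.approx(180 / math.sqrt(12), rel=0.05)


def test_symmetric_bimodal_angles_have_zero_skewness():
    angles = np.array([[-30.0] * 8, [30.0] * 8])
    omap = OrientationMap(angles, np.ones_like(angles, dtype=bool))
    _, skew, _ = orientation_features(omap)
    assert skew == pytest.approx(0.0, abs=1e-12)


def test_window_sigma_must_be_positive():
    with pytest.raises(ValueError):
        orientation_map(np.zeros((8, 8), np.uint8), window_sigma=0.0)


# ---------------------------------------------------------------------------
# Triangle threshold and binary measures


def test_two_delta_histogram_threshold_separates_modes():
    hist = np.zeros(256)
    hist[200] = 900
    hist[50] = 100
    t = triangle_threshold_from_histogram(hist)
    assert 50 < t < 200


def test_constant_image_threshold_is_the_constant():
    img = np.full((16, 16), 77, np.uint8)
    assert triangle_threshold(img) == 77
    assert not binarize(img).mask.any()


def test_ramp_histogram_matches_exhaustive_oracle():
    hist = np.arange(256, dtype=float)
    assert triangle_threshold_from_histogram(hist) == triangle_oracle(hist)


def test_random_histograms_match_exhaustive_oracle(rng):
    for _ in range(20):
        hist = rng.integers(0, 1000, 256).astype(float)
        hist[rng.integers(0, 256)] += 5000  # a clear peak
        assert triangle_threshold_from_histogram(hist) == triangle_oracle(hist)


def test_binarization_recovers_planted_fibers():
    tile = synthgen.make_fiber_tile(
        256, synthgen.DEFAULT_CLASS_EFFECTS["FA"], seed=17
    )
    mask = binarize(convert.convert_8b(tile)).mask
    planted = tile.fiber_mask
    iou = (mask & planted).sum() / (mask | planted).sum()
    assert iou > 0.7


def test_all_bright_image_has_empty_foreground():
    assert not binarize(np.full((16, 16), 255, np.uint8)).mask.any()


def test_inverted_polarity_swaps_foreground_counts(rng):
    img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    fg = binarize(img).mask.sum()
    bg = binarize(img, invert=True).mask.sum()
    assert fg + bg == img.size


def test_tc_ratio_limits_and_count_arithmetic(rng):
    assert tc_ratio(np.ones((8, 8), bool)) == 1.0
    assert tc_ratio(np.zeros((8, 8), bool)) == 0.0
    mask = np.zeros((512, 512), bool)
    flat = rng.choice(512 * 512, 65536, replace=False)
    mask.ravel()[flat] = True
    assert tc_ratio(mask) == pytest.approx(0.25)
    # permutation invariance
    assert tc_ratio(mask.ravel()[rng.permutation(mask.size)].reshape(512, 512)) == (
        pytest.approx(0.25)
    )


def sierpinski_carpet(depth):
    m = np.ones((1, 1), bool)
    cell = np.ones((3, 3), bool)
    cell[1, 1] = False
    for _ in range(depth):
        m = np.kron(m, cell)
    return m


def test_fractal_dimension_analytic_limits():
    full = np.ones((512, 512), bool)
    assert fractal_dimension(full) == pytest.approx(2.0, abs=0.05)
    line = np.zeros((512, 512), bool)
    line[256, :] = True
    assert fractal_dimension(line) == pytest.approx(1.0, abs=0.05)
    carpet = np.zeros((256, 256), bool)
    carpet[:243, :243] = sierpinski_carpet(5)
    assert fractal_dimension(carpet) == pytest.approx(math.log(8) / math.log(3), abs=0.1)


def test_fractal_dimension_invariant_under_box_aligned_translation(rng):
    mask = np.zeros((256, 256), bool)
    mask[8:72, 8:72] = rng.random((64, 64)) > 0.6
    shifted = np.roll(np.roll(mask, 64, axis=0), 64, axis=1)
    assert fractal_dimension(mask) == pytest.approx(fractal_dimension(shifted), abs=1e-12)


def test_empty_mask_has_zero_fd():
    assert fractal_dimension(np.zeros((64, 64), bool)) == 0.0


# ---------------------------------------------------------------------------
# the assembled vector


def test_feature_vector_has_56_stable_names(small_cohort):
    vec = extract_feature_vector(small_cohort[0])
    assert tuple(vec) == FEATURE_NAMES
    assert len(vec) == 56
    assert all(math.isfinite(v) for v in vec.values())


def test_white_tile_degenerate_feature_values():
    from capsuletex.types import RGBTile

    tile = RGBTile(np.full((96, 96, 3), 255, np.uint8), "FA", "p", "t")
    vec = extract_feature_vector(tile)
    for s in ("8b", "8bw", "RED", "EOSIN"):
        assert vec[f"{s}.histogram.Mean"] == 255.0
        assert vec[f"{s}.histogram.SD"] == 0.0
        assert vec[f"{s}.glcm.ASM"] == 1.0
        assert vec[f"{s}.glcm.Contrast"] == 0.0
        assert vec[f"{s}.binary.TCratio"] == 0.0
        assert vec[f"{s}.binary.FD"] == 0.0
        assert vec[f"{s}.helmholtz.SD"] == 0.0


def test_vector_entries_equal_direct_family_calls(small_cohort):
    """Compositional oracle: the assembled vector reproduces each family
    computed by hand from the same conversions."""
    tile = small_cohort[3]
    vec = extract_feature_vector(tile)
    for strategy in ("8b", "RED"):
        gray = convert.convert(tile, strategy)
        mean, sd, skew, kurt = histogram_features(gray)
        assert vec[f"{strategy}.histogram.Mean"] == mean
        assert vec[f"{strategy}.histogram.Kurtosis"] == kurt
        asm, contrast, corr, idm, entropy = glcm_features(build_glcm(gray))
        assert vec[f"{strategy}.glcm.ASM"] == asm
        assert vec[f"{strategy}.glcm.Correlation"] == corr
        osd, oskew, okurt = orientation_features(orientation_map(gray))
        assert vec[f"{strategy}.helmholtz.SD"] == osd
        b = binarize(gray)
        assert vec[f"{strategy}.binary.TCratio"] == tc_ratio(b)
        assert vec[f"{strategy}.binary.FD"] == fractal_dimension(b)


def test_feature_extraction_is_pure(small_cohort):
    a = extract_feature_vector(small_cohort[1])
    b = extract_feature_vector(small_cohort[1])
    assert a == b


@given(st.integers(0, 2**31 - 1))
def test_glcm_probabilities_sum_to_one(seed):
    img = np.random.default_rng(seed).integers(0, 256, (12, 12), dtype=np.uint8)
    for symmetric in (False, True):
        M = build_glcm(img, symmetric=symmetric)
        assert M.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
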