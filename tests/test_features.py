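"""Feature extractors versus independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from chillgrade.features import (FEATURE_NAMES, FeatureConfig, build_ggcm,
                                 build_glcm, color_features, extract_all,
                                 feature_table, ggcm_features, glcm_features,
                                 histogram_features)
from chillgrade.synthetic import make_leaf_image

import oracles

FULL = np.ones((12, 12), dtype=bool)


# -- color ------------------------------------------------------------------

def test_pure_red_patch_descriptors():
    rgb = np.zeros((16, 16, 3), dtype=np.uint8)
    rgb[..., 0] = 255
    f = dict(zip(FEATURE_NAMES[:18], color_features(rgb, np.ones((16, 16), bool))))
    assert f["H"] == 0 and f["S"] == 1 and f["V"] == 1
    assert f["G/R"] == 0 and f["B/R"] == 0


def test_mid_gray_patch_is_achromatic():
    rgb = np.full((16, 16, 3), 128, dtype=np.uint8)
    f = dict(zip(FEATURE_NAMES[:18], color_features(rgb, np.ones((16, 16), bool))))
    assert f["S"] == 0
    assert abs(f["a"]) < 0.5 and abs(f["b"]) < 0.5


def test_color_descriptors_match_reference_conversions(rng):
    rgb = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
    mask = rng.random((12, 12)) < 0.8
    mask[5, 5] = True
    vals = color_features(rgb, mask)
    rgb01 = rgb / 255.0
    expected_rgb = [rgb01[mask][:, c].mean() * 255 for c in range(3)]
    np.testing.assert_allclose(vals[:3], expected_rgb, atol=1e-9)
    np.testing.assert_allclose(vals[3:6], oracles.hsv_means(rgb01, mask), atol=1e-6)
    np.testing.assert_allclose(vals[6:9], oracles.lab_means(rgb01, mask), atol=1e-6)


def test_color_features_empty_mask_errors():
    rgb = np.zeros((16, 16, 3), dtype=np.uint8)
    with pytest.raises(ValueError):
        color_features(rgb, np.zeros((16, 16), bool))


# -- histogram ---------------------------------------------------------------

def test_constant_image_histogram_degenerate():
    gray = np.full((12, 12), 77, dtype=np.uint8)
    e, sd, skew, smooth = histogram_features(gray, FULL)
    assert (e, sd, skew, smooth) == (77.0, 0.0, 0.0, 0.0)


def test_two_point_histogram_closed_form():
    gray = np.zeros((12, 12), dtype=np.uint8)
    gray[:6] = 0
    gray[6:] = 255
    e, sd, skew, smooth = histogram_features(gray, FULL)
    assert e == pytest.approx(127.5)
    assert sd == pytest.approx(127.5)
    assert skew == pytest.approx(0.0, abs=1e-9)


def test_histogram_matches_pixelwise_moments(random_gray):
    gray, mask = random_gray
    got = histogram_features(gray, mask)
    np.testing.assert_allclose(got, oracles.pixel_moments(gray, mask), atol=1e-9)


# -- GGCM ---------------------------------------------------------------------

def test_constant_image_ggcm_lowest_gradient_bin():
    gray = np.full((12, 12), 100, dtype=np.uint8)
    m = build_ggcm(gray, FULL)
    assert m.counts[:, 0].sum() == m.total
    t1, t2, t3, t4, mu, sd = ggcm_features(m)
    assert t1 == 1.0 and t2 == 0.0 and sd == 0.0
    # all mass in one cell: both non-uniformities equal the total count
    assert t3 == m.total and t4 == m.total


def test_ggcm_normalization_and_counts_match_enumeration(random_gray):
    gray, mask = random_gray
    ng = ns = 8
    m = build_ggcm(gray, mask, ng=ng, ns=ns, t=4)
    assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
    expected = oracles.ggcm_counts(gray, mask, ng, ns)
    for (i, j), v in expected.items():
        assert m.counts[i - 1, j - 1] == v
    assert m.counts.sum() == sum(expected.values())


def test_ggcm_toy_image_hand_enumerated():
    gray = np.array([[0, 0, 0, 0],
                     [0, 255, 255, 0],
                     [0, 255, 255, 0],
                     [0, 0, 0, 0]], dtype=np.uint8)
    mask = np.ones((4, 4), dtype=bool)
    m = build_ggcm(gray, mask, ng=2, ns=2, t=1)
    expected = oracles.ggcm_counts(gray, mask, 2, 2)
    assert {(i + 1, j + 1): int(v) for (i, j), v in np.ndenumerate(m.counts) if v} \
        == expected


def test_ggcm_features_match_direct_summation(random_gray):
    gray, mask = random_gray
    m = build_ggcm(gray, mask, ng=8, ns=8, t=4)
    expected = oracles.ggcm_features_direct(
        oracles.ggcm_counts(gray, mask, 8, 8), 8, 8, 4)
    np.testing.assert_allclose(ggcm_features(m), expected, atol=1e-9)


def test_ggcm_rejects_tiny_mask():
    gray = np.zeros((12, 12), dtype=np.uint8)
    mask = np.zeros((12, 12), dtype=bool)
    mask[3, 3:6] = True  # 1x3: no 3x3 support
    with pytest.raises(ValueError):
        build_ggcm(gray, mask)


# -- GLCM ---------------------------------------------------------------------

def test_constant_image_glcm_single_cell():
    gray = np.full((12, 12), 40, dtype=np.uint8)
    for m in build_glcm(gray, FULL):
        nz = np.nonzero(m.q)
        assert len(nz[0]) == 1
        assert m.q[nz] == pytest.approx(1.0)


def test_glcm_is_normalized_and_symmetric(random_gray):
    gray, mask = random_gray
    for m in build_glcm(gray, mask):
        assert m.q.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.q, m.q.T, atol=1e-15)


def test_glcm_matches_pair_enumeration(random_gray):
    gray, mask = random_gray
    for m in build_glcm(gray, mask, levels=8, distance=1):
        expected = oracles.glcm_matrix(gray, mask, 8, 1, m.angle_deg)
        np.testing.assert_allclose(m.q, expected, atol=1e-12)


def test_checkerboard_inertia_closed_form():
    levels = 16
    gray = np.indices((12, 12)).sum(axis=0) % 2 * 255
    m0 = build_glcm(gray.astype(np.uint8), FULL, levels=levels)[0]  # 0 degrees
    feats = glcm_features([m0, m0, m0, m0])
    ine_mean = feats[2]
    assert ine_mean == pytest.approx((levels - 1) ** 2)


def test_glcm_features_match_direct_summation(random_gray):
    gray, mask = random_gray
    mats = build_glcm(gray, mask, levels=8)
    got = glcm_features(mats)
    per_dir = np.array([oracles.glcm_features_direct(m.q) for m in mats])
    expected = np.concatenate([per_dir.mean(axis=0), per_dir.std(axis=0)])
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_constant_image_glcm_degenerate_features():
    gray = np.full((12, 12), 200, dtype=np.uint8)
    feats = dict(zip(FEATURE_NAMES[28:], glcm_features(build_glcm(gray, FULL))))
    assert feats["energy_mean"] == 1.0
    assert feats["entropy_mean"] == 0.0
    assert feats["inertia_mean"] == 0.0
    assert feats["corr_mean"] == 0.0  # sigma_x*sigma_y = 0 convention
    assert all(feats[k] == 0.0 for k in
               ("energy_sd", "entropy_sd", "inertia_sd", "corr_sd"))


# -- composition --------------------------------------------------------------

def test_extract_all_is_composition(clean_image):
    mask = clean_image.truth.leaf_mask
    cfg = FeatureConfig()
    fv = extract_all(clean_image, mask, cfg)
    assert len(fv.values) == 36 and np.all(np.isfinite(fv.values))
    parts = np.concatenate([
        color_features(clean_image.rgb, mask),
        histogram_features(clean_image.gray, mask),
        ggcm_features(build_ggcm(clean_image.gray, mask, cfg.ng, cfg.ns, cfg.t)),
        glcm_features(build_glcm(clean_image.gray, mask, cfg.glcm_levels,
                                 cfg.glcm_distance)),
    ])
    np.testing.assert_array_equal(fv.values, parts)
    again = extract_all(clean_image, mask, cfg)
    np.testing.assert_array_equal(fv.values, again.values)


def test_feature_invariants(noisy_image):
    fv = extract_all(noisy_image).as_dict()
    assert 0 <= fv["hist_smooth"] < 1
    assert 0 < fv["energy_mean"] <= 1
    assert fv["entropy_mean"] >= 0


def test_gray_histogram_responds_monotonically_to_injury():
    """More injured area -> darker, more dispersed fluorescence histogram."""
    targets = np.linspace(0.01, 0.5, 21)
    rows = [extract_all(make_leaf_image(100 + i, t, size=(48, 48))).as_dict()
            for i, t in enumerate(targets)]
    means = [r["hist_mean"] for r in rows]
    sds = [r["hist_sd"] for r in rows]
    assert stats.spearmanr(targets, means).statistic < -0.8
    assert stats.spearmanr(targets, sds).statistic > 0.8


def test_feature_table_shape_and_index():
    imgs = [make_leaf_image(s, 0.1, size=(48, 48)) for s in (1, 2)]
    table = feature_table(imgs)
    assert table.shape == (2, 36)
    assert list(table.columns) == list(FEATURE_NAMES)
    assert list(table.index) == [im.id for im in imgs]
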