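"""Radiomic feature extraction against worked examples and brute-force oracles."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.feature import graycomatrix

from radfuse.radiomics import (
    FeatureConfig,
    FeatureTable,
    RadiomicsExtractor,
    extract_features,
    first_order_features,
    glcm,
    glcm_features,
    glrlm_features,
    quantize,
    shape2d_features,
)

_OFFS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# -- independent oracles -------------------------------------------------------


def brute_glcm(q, mask, distance, angles):
    """Pair enumeration with explicit loops and symmetric counting."""
    n_levels = int(q[mask].max()) + 1
    P = np.zeros((n_levels, n_levels))
    h, w = q.shape
    for angle in angles:
        dr, dc = _OFFS[angle]
        dr, dc = dr * distance, dc * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    P[q[r, c], q[r2, c2]] += 1
                    P[q[r2, c2], q[r, c]] += 1
    return P / P.sum()


def brute_glcm_features(P):
    n = P.shape[0]
    contrast = dissim = energy = homog = entropy = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            contrast += (i - j) ** 2 * p
            dissim += abs(i - j) * p
            energy += p * p
            homog += p / (1 + abs(i - j))
            if p > 0:
                entropy -= p * np.log2(p)
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(n))
    var = sum((i - mu) ** 2 * px[i] for i in range(n))
    corr = 0.0
    if var > 0:
        for i in range(n):
            for j in range(n):
                corr += (i - mu) * (j - mu) * P[i, j] / var
    return {"contrast": contrast, "dissimilarity": dissim, "energy": energy,
            "homogeneity": homog, "correlation": corr, "entropy": entropy}


def brute_runs(q, mask, angle):
    """Scan maximal equal-level runs pixel by pixel along one direction."""
    h, w = q.shape
    dr, dc = _OFFS[angle]
    runs = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            starts = not (0 <= pr < h and 0 <= pc < w
                          and mask[pr, pc] and q[pr, pc] == q[r, c])
            if not mask[r, c] or not starts:
                continue
            length, rr, cc = 0, r, c
            while 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and q[rr, cc] == q[r, c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            runs.append((q[r, c], length))
    return runs


def brute_glrlm_features(q, mask, angles):
    n_pixels = mask.sum()
    feats = dict.fromkeys(["glrlm_sre", "glrlm_lre", "glrlm_gln",
                           "glrlm_rln", "glrlm_rp"], 0.0)
    for angle in angles:
        runs = brute_runs(q, mask, angle)
        nr = len(runs)
        levels = [lv for lv, _ in runs]
        lengths = [ln for _, ln in runs]
        feats["glrlm_sre"] += sum(1 / ln**2 for ln in lengths) / nr
        feats["glrlm_lre"] += sum(ln**2 for ln in lengths) / nr
        feats["glrlm_gln"] += sum(levels.count(lv) ** 2 for lv in set(levels)) / nr
        feats["glrlm_rln"] += sum(lengths.count(ln) ** 2 for ln in set(lengths)) / nr
        feats["glrlm_rp"] += nr / n_pixels
    return {k: v / len(angles) for k, v in feats.items()}


# -- quantization --------------------------------------------------------------


def test_quantize_binary_and_constant():
    img = np.zeros((4, 4))
    img[0, 1] = 1.0
    q = quantize(img, None, 2)
    assert set(np.unique(q)) == {0, 1}
    const = quantize(np.full((4, 4), 3.7), None, 8)
    assert (const == 0).all()


def test_quantize_equal_width_binning():
    img = np.zeros((4, 4))
    img[0, :3] = [0.0, 0.5, 1.0]
    mask = np.zeros((4, 4), bool)
    mask[0, :3] = True
    q = quantize(img, mask, 4)
    np.testing.assert_array_equal(q[0, :3], [0, 2, 3])
    assert (q[~mask] == -1).all()


def test_quantize_empty_roi_raises():
    with pytest.raises(ValueError):
        quantize(np.zeros((4, 4)), np.zeros((4, 4), bool), 4)


# -- first order ---------------------------------------------------------------


def test_first_order_direct_arithmetic():
    img = np.zeros((4, 4))
    img[0, :3] = [1.0, 2.0, 3.0]
    mask = np.zeros((4, 4), bool)
    mask[0, :3] = True
    f = first_order_features(img, mask)
    assert f["fo_mean"] == pytest.approx(2.0)
    assert f["fo_sd"] == pytest.approx(np.sqrt(2 / 3))
    assert f["fo_energy"] == pytest.approx(1 + 4 + 9)


def test_first_order_symmetric_and_constant_conventions():
    img = np.zeros((4, 4))
    img[0, :4] = [1.0, 2.0, 2.0, 3.0]
    mask = np.zeros((4, 4), bool)
    mask[0, :4] = True
    assert first_order_features(img, mask)["fo_skewness"] == pytest.approx(0.0)
    const = first_order_features(np.full((4, 4), 2.0), None)
    assert const["fo_sd"] == 0.0
    assert const["fo_skewness"] == 0.0
    assert const["fo_kurtosis"] == 0.0
    assert const["fo_entropy"] == 0.0


# -- shape ---------------------------------------------------------------------


def test_shape_square_area():
    mask = np.zeros((14, 14), bool)
    mask[2:12, 2:12] = True
    assert shape2d_features(mask)["shape_area"] == 100.0


def test_shape_disk_circularity_near_one():
    mask = np.zeros((50, 50), bool)
    rr, cc = disk((25, 25), 20.5)
    mask[rr, cc] = True
    assert 0.9 <= shape2d_features(mask)["shape_circularity"] <= 1.1


def test_shape_line_eccentricity():
    mask = np.zeros((40, 40), bool)
    mask[5, 3:33] = True
    assert shape2d_features(mask)["shape_eccentricity"] > 0.99


def test_shape_uses_largest_component_and_rejects_empty():
    mask = np.zeros((20, 20), bool)
    mask[2:10, 2:10] = True
    mask[15, 15] = True  # small separate speck
    assert shape2d_features(mask)["shape_area"] == 64.0
    with pytest.raises(ValueError):
        shape2d_features(np.zeros((5, 5), bool))


# -- GLCM ----------------------------------------------------------------------


def test_glcm_worked_examples():
    q = np.full((4, 4), -1)
    q[0, :2] = [0, 0]
    q[1, :2] = [1, 1]
    P = glcm(q, None, distance=1, angles=[0])
    np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])
    f = glcm_features(P)
    assert f["contrast"] == pytest.approx(0.0)
    assert f["energy"] == pytest.approx(0.5)

    checker = np.indices((4, 4)).sum(0) % 2
    P2 = glcm(checker, None, distance=1, angles=[0])
    np.testing.assert_allclose(P2, [[0.0, 0.5], [0.5, 0.0]])
    f2 = glcm_features(P2)
    assert f2["contrast"] == pytest.approx(1.0)
    assert f2["homogeneity"] == pytest.approx(0.5)


def test_glcm_diagonal_matrix_has_zero_contrast():
    P = np.eye(5) / 5
    assert glcm_features(P)["contrast"] == 0.0


def test_glcm_symmetry_and_unit_mass(rng):
    for _ in range(20):
        q = rng.integers(0, 5, size=(8, 8))
        mask = rng.random((8, 8)) > 0.2
        if mask.sum() < 4:
            continue
        P = glcm(q, mask)
        assert abs(P.sum() - 1.0) <= 1e-9
        np.testing.assert_allclose(P, P.T, atol=1e-12)


def test_glcm_matches_brute_force_enumeration(rng):
    for _ in range(30):
        q = rng.integers(0, 4, size=(8, 8))
        mask = rng.random((8, 8)) > 0.25
        if mask.sum() < 6:
            continue
        for dist in (1, 2):
            mine = glcm(q, mask, distance=dist)
            brute = brute_glcm(q, mask, dist, (0, 45, 90, 135))
            np.testing.assert_allclose(mine, brute, atol=1e-9)
            f_mine = glcm_features(mine)
            f_brute = brute_glcm_features(brute)
            for k in f_brute:
                assert f_mine[k] == pytest.approx(f_brute[k], abs=1e-9)


def test_glcm_cross_check_against_scikit_image(rng):
    """Unmasked single-angle case agrees with skimage.feature.graycomatrix."""
    q = rng.integers(0, 6, size=(10, 10))
    ref = graycomatrix(q.astype(np.uint8), [1], [0], levels=6,
                       symmetric=True, normed=True)[:, :, 0, 0]
    np.testing.assert_allclose(glcm(q, None, 1, [0]), ref, atol=1e-12)


def test_glcm_no_valid_pairs_raises():
    q = np.full((4, 4), -1)
    q[0, 0] = 0
    with pytest.raises(ValueError):
        glcm(q, None, distance=1, angles=[0])


# -- GLRLM ---------------------------------------------------------------------


def test_glrlm_single_row_runs():
    q = np.full((4, 4), -1)
    q[0] = [0, 0, 0, 1]
    mask = q >= 0
    runs = brute_runs(q, mask, 0)
    assert sorted(runs) == [(0, 3), (1, 1)]
    f = glrlm_features(q, mask, angles=[0])
    # one run of length 3 and one of length 1: SRE = (1/9 + 1)/2
    assert f["glrlm_sre"] == pytest.approx((1 / 9 + 1) / 2)


def test_glrlm_constant_region_run_percentage():
    q = np.zeros((4, 4), int)
    f = glrlm_features(q, None, angles=[0])
    assert f["glrlm_rp"] == pytest.approx(4 / 16)


def test_glrlm_alternating_row_all_unit_runs():
    q = np.full((6, 6), -1)
    q[0] = [0, 1, 0, 1, 0, 1]
    f = glrlm_features(q, q >= 0, angles=[0])
    assert f["glrlm_sre"] == pytest.approx(1.0)
    assert f["glrlm_lre"] == pytest.approx(1.0)


def test_glrlm_matches_brute_force_scanner(rng):
    for _ in range(30):
        q = rng.integers(0, 4, size=(8, 8))
        mask = rng.random((8, 8)) > 0.25
        if mask.sum() < 6:
            continue
        mine = glrlm_features(q, mask)
        brute = brute_glrlm_features(q, mask, (0, 45, 90, 135))
        for k in brute:
            assert mine[k] == pytest.approx(brute[k], abs=1e-9)


def test_glrlm_empty_roi_raises():
    with pytest.raises(ValueError):
        glrlm_features(np.zeros((4, 4), int), np.zeros((4, 4), bool))


# -- full extraction -----------------------------------------------------------


def test_extraction_is_deterministic_with_stable_names(rng):
    img = rng.random((20, 20))
    mask = np.zeros((20, 20), bool)
    mask[4:16, 4:16] = True
    v1, n1 = extract_features(img, mask)
    v2, n2 = extract_features(img, mask)
    np.testing.assert_array_equal(v1, v2)
    assert n1 == n2
    assert len(n1) == len(v1) >= 40


def test_whole_image_fallback_equals_full_mask(rng):
    img = rng.random((16, 16))
    v_none, _ = extract_features(img, None)
    v_full, _ = extract_features(img, np.ones((16, 16), bool))
    np.testing.assert_array_equal(v_none, v_full)


def test_extraction_translation_invariance(rng):
    img = rng.random((32, 32))
    mask = np.zeros((32, 32), bool)
    mask[8:20, 10:22] = True
    v1, _ = extract_features(img, mask)
    v2, _ = extract_features(np.roll(img, (3, -4), (0, 1)),
                             np.roll(mask, (3, -4), (0, 1)))
    np.testing.assert_allclose(v1, v2, atol=1e-12)


def test_feature_table_csv_roundtrip(tmp_path, rng):
    imgs = rng.random((3, 16, 16))
    table = RadiomicsExtractor(FeatureConfig(distances=(1,))).extract_table(imgs)
    path = tmp_path / "features.csv"
    table.to_csv(str(path))
    back = FeatureTable.from_csv(str(path))
    assert back.feature_names == table.feature_names
    np.testing.assert_allclose(back.values, table.values, rtol=1e-12)
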