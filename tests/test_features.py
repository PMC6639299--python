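import math

import numpy as np
import pytest

from npcradiomics import features as ft
from npcradiomics.imaging_io import EmptyROIError, ImageVolume, ROIMask
from npcradiomics.synthetic_data import PhantomSpec, generate_phantom

SPEC2 = ft.QuantizationSpec(n_levels=2)
SPEC4 = ft.QuantizationSpec(n_levels=4)


# ---------------------------------------------------------------------------
# Independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def brute_glcm(quantized, mask, n_levels):
    """Pair enumeration over the 4 in-plane directions, both orderings."""
    counts = np.zeros((n_levels, n_levels))
    ns, nr, nc = quantized.shape
    for s in range(ns):
        for r in range(nr):
            for c in range(nc):
                if not mask[s, r, c]:
                    continue
                # both orderings of every in-plane unit-distance pair
                for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1),
                               (0, -1), (1, -1), (1, 0), (1, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and mask[s, rr, cc]:
                        counts[quantized[s, r, c] - 1,
                               quantized[s, rr, cc] - 1] += 1
    return counts / counts.sum()


def brute_glcm_features(p):
    """Direct double-loop evaluation of all 22 co-occurrence features."""
    ng = p.shape[0]
    def log2(v):
        return math.log2(v) if v > 0 else 0.0
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    hxy = -sum(p[i][j] * log2(p[i][j]) for i in range(ng) for j in range(ng))
    hxy1 = -sum(p[i][j] * log2(px[i] * py[j])
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j])
                for i in range(ng) for j in range(ng))
    hx = -sum(px[i] * log2(px[i]) for i in range(ng))
    hy = -sum(py[j] * log2(py[j]) for j in range(ng))
    out = {}
    out["angular_second_moment"] = sum(p[i][j] ** 2 for i in range(ng)
                                       for j in range(ng))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng)
                          for j in range(ng))
    if var_x > 0 and var_y > 0:
        out["correlation"] = (sum((i + 1) * (j + 1) * p[i][j]
                                  for i in range(ng) for j in range(ng))
                              - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        out["correlation"] = 0.0
    out["sum_of_squares_variance"] = sum((i + 1 - mu_x) ** 2 * p[i][j]
                                         for i in range(ng)
                                         for j in range(ng))
    out["inverse_difference_moment"] = sum(p[i][j] / (1 + (i - j) ** 2)
                                           for i in range(ng)
                                           for j in range(ng))
    sa = sum(k * psum[k] for k in psum)
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in psum)
    out["sum_entropy"] = -sum(psum[k] * log2(psum[k]) for k in psum)
    out["entropy"] = hxy
    da = sum(k * pdiff[k] for k in pdiff)
    out["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in pdiff)
    out["difference_entropy"] = -sum(pdiff[k] * log2(pdiff[k]) for k in pdiff)
    out["information_Measure_I"] = ((hxy - hxy1) / max(hx, hy)
                                    if max(hx, hy) > 0 else 0.0)
    arg = 1 - math.exp(-2 * (hxy2 - hxy))
    out["information_Measure_II"] = math.sqrt(arg) if arg > 0 else 0.0
    out["autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j]
                                 for i in range(ng) for j in range(ng))
    out["cluster_shade"] = sum((i + j + 2 - mu_x - mu_y) ** 3 * p[i][j]
                               for i in range(ng) for j in range(ng))
    out["cluster_prominence"] = sum((i + j + 2 - mu_x - mu_y) ** 4 * p[i][j]
                                    for i in range(ng) for j in range(ng))
    out["dissimilarity"] = sum(abs(i - j) * p[i][j] for i in range(ng)
                               for j in range(ng))
    out["homogeneity2"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng)
                              for j in range(ng))
    out["maximum_probability"] = max(p[i][j] for i in range(ng)
                                     for j in range(ng))
    out["inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    out["inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / ng ** 2)
        for i in range(ng) for j in range(ng))
    return out


def brute_glrlm(quantized, mask, n_levels, directions):
    """Run enumeration by walking each lattice line explicitly."""
    max_len = max(quantized.shape[1], quantized.shape[2])
    counts = np.zeros((n_levels, max_len))
    ns, nr, nc = quantized.shape
    q = np.where(mask, quantized, 0)
    for s in range(ns):
        for dr, dc in directions:
            starts = []
            for r in range(nr):
                for c in range(nc):
                    rp, cp = r - dr, c - dc
                    if not (0 <= rp < nr and 0 <= cp < nc):
                        starts.append((r, c))
            for r0, c0 in starts:
                r, c = r0, c0
                run_val, run_len = 0, 0
                while 0 <= r < nr and 0 <= c < nc:
                    v = q[s, r, c]
                    if v == run_val:
                        run_len += 1
                    else:
                        if run_val > 0:
                            counts[run_val - 1, run_len - 1] += 1
                        run_val, run_len = v, 1
                    r, c = r + dr, c + dc
                if run_val > 0:
                    counts[run_val - 1, run_len - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# Quantization and histogram features
# ---------------------------------------------------------------------------

def test_quantize_equal_width_bins():
    vol = np.arange(32, dtype=float).reshape(1, 4, 8)
    mask = np.ones_like(vol, dtype=np.uint8)
    q = ft.quantize_roi(vol, mask)
    assert sorted(np.unique(q[mask == 1])) == list(range(1, 33))


def test_quantize_degenerate_and_two_level():
    const = np.full((1, 3, 3), 7.0)
    mask = np.ones_like(const, dtype=np.uint8)
    assert set(np.unique(ft.quantize_roi(const, mask)[mask == 1])) == {1}
    two = np.array([[[0.0, 10.0]]])
    m = np.ones_like(two, dtype=np.uint8)
    assert sorted(ft.quantize_roi(two, m, SPEC2)[m == 1]) == [1, 2]


def test_histogram_moments_match_hand_values():
    vol = np.array([[[1.0, 2.0, 3.0, 4.0]]])
    mask = np.ones_like(vol, dtype=np.uint8)
    h = ft.histogram_features(vol, mask)
    assert h["mean"] == pytest.approx(2.5)
    assert h["range"] == pytest.approx(3.0)
    assert h["variance"] == pytest.approx(1.25)
    # population m4/m2^2 = 2.5625 / 1.5625
    assert h["kurtosis"] == pytest.approx(1.64)


def test_histogram_degenerate_conventions():
    vol = np.full((1, 3, 3), 5.0)
    mask = np.ones_like(vol, dtype=np.uint8)
    h = ft.histogram_features(vol, mask)
    assert h["variance"] == 0 and h["skewness"] == 0 and h["kurtosis"] == 0
    assert h["entropy"] == 0 and h["energy"] == 1
    with pytest.raises(EmptyROIError):
        ft.histogram_features(vol, np.zeros_like(mask))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_toy_image_matches_brute_force(toy_image):
    volume, mask = toy_image
    g = ft.glcm(volume, mask, SPEC4)
    q = ft.quantize_roi(volume, mask, SPEC4)
    expected = brute_glcm(q, mask.voxels.astype(bool), 4)
    np.testing.assert_allclose(g.p, expected, atol=1e-12)
    assert g.p.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(g.p, g.p.T)


def test_glcm_random_images_match_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(50):
        vol = rng.integers(0, 5, size=(1, 6, 6)).astype(float)
        mask = (rng.random((1, 6, 6)) < 0.8).astype(np.uint8)
        if mask.sum() < 4:
            continue
        spec = ft.QuantizationSpec(n_levels=5)
        try:
            g = ft.glcm(vol, mask, spec)
        except ValueError:
            continue  # no valid pair
        q = ft.quantize_roi(vol, mask, spec)
        np.testing.assert_allclose(
            g.p, brute_glcm(q, mask.astype(bool), 5), atol=1e-12)


def test_glcm_constant_roi_single_entry():
    vol = np.full((1, 4, 4), 3.0)
    mask = np.ones_like(vol, dtype=np.uint8)
    g = ft.glcm(vol, mask)
    assert g.p[0, 0] == pytest.approx(1.0)
    assert g.p.sum() == pytest.approx(1.0)


def test_glcm_features_independent_marginals_imc2_zero():
    px = np.array([0.1, 0.2, 0.3, 0.4])
    g = ft.GLCMatrix(np.outer(px, px))
    f = ft.glcm_features(g)
    assert f["information_Measure_II"] == pytest.approx(0.0, abs=1e-7)


def test_glcm_features_identity_matrix():
    ng = 8
    g = ft.GLCMatrix(np.eye(ng) / ng)
    f = ft.glcm_features(g)
    assert f["angular_second_moment"] == pytest.approx(1 / ng)
    assert f["contrast"] == pytest.approx(0.0)


def test_glcm_features_toy_image_match_direct_summation(toy_image):
    volume, mask = toy_image
    g = ft.glcm(volume, mask, SPEC4)
    ours = ft.glcm_features(g)
    oracle = brute_glcm_features(g.p)
    for name, val in oracle.items():
        assert ours[name] == pytest.approx(val, abs=1e-10), name


def test_maximal_correlation_coefficient_range(phantom_pair):
    g = ft.glcm(*phantom_pair)
    mcc = ft.glcm_features(g)["maximal_correlation_coefficient"]
    assert 0.0 <= mcc <= 1.0


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def test_glrlm_single_row_single_direction():
    vol = np.full((1, 1, 5), 2.0)
    mask = np.ones_like(vol, dtype=np.uint8)
    f = ft.glrlm_features(vol, mask, directions=((0, 1),))
    assert f["RP"] == pytest.approx(1 / 5)
    assert f["SRE"] == pytest.approx(1 / 25)
    assert f["LRE"] == pytest.approx(25)


def test_glrlm_checkerboard_all_short_runs():
    vol = np.indices((1, 6, 6)).sum(axis=0) % 2 * 10.0
    mask = np.ones_like(vol, dtype=np.uint8)
    f = ft.glrlm_features(vol, mask, SPEC2, directions=((0, 1), (-1, 0)))
    assert f["SRE"] == pytest.approx(1.0)
    assert f["RP"] == pytest.approx(1.0)


def test_glrlm_toy_image_matches_brute_force(toy_image):
    volume, mask = toy_image
    ours = ft.glrlm(volume, mask, SPEC4)
    q = ft.quantize_roi(volume, mask, SPEC4)
    oracle = brute_glrlm(q, mask.voxels.astype(bool), 4,
                         ft.INPLANE_DIRECTIONS)
    np.testing.assert_array_equal(ours, oracle)


def test_glrlm_random_images_match_brute_force():
    rng = np.random.default_rng(17)
    for _ in range(30):
        vol = rng.integers(0, 4, size=(2, 6, 6)).astype(float)
        mask = (rng.random((2, 6, 6)) < 0.75).astype(np.uint8)
        if mask.sum() < 3:
            continue
        spec = ft.QuantizationSpec(n_levels=4)
        ours = ft.glrlm(vol, mask, spec)
        q = ft.quantize_roi(vol, mask, spec)
        oracle = brute_glrlm(q, mask.astype(bool), 4, ft.INPLANE_DIRECTIONS)
        np.testing.assert_array_equal(ours, oracle)


# ---------------------------------------------------------------------------
# Wavelet sub-bands
# ---------------------------------------------------------------------------

def test_wavelet_constant_image_has_zero_detail():
    vol = np.full((2, 8, 8), 42.0)
    mask = np.ones_like(vol, dtype=np.uint8)
    bands = ft.wavelet_subbands(vol, mask)
    for name in ("LH", "HL", "HH"):
        assert np.allclose(bands[name][0], 0.0, atol=1e-10)
    assert np.allclose(bands["LL"][0], 84.0)  # orthonormal scaling: x2 per level


def test_wavelet_energy_conservation(phantom_pair):
    volume, mask = phantom_pair
    bands = ft.wavelet_subbands(volume, mask)
    total = sum(np.sum(sub ** 2) for sub, _ in bands.values())
    assert total == pytest.approx(np.sum(volume.voxels ** 2), rel=1e-6)


def test_wavelet_emits_164_names(phantom_pair):
    fv = ft.extract_all(*phantom_pair)
    wavelet_names = [n for n in fv if n.split("_")[0] in ft.SUBBANDS]
    assert len(wavelet_names) == 164


def test_subband_mask_any_parent_rule():
    mask = np.zeros((1, 4, 4), dtype=np.uint8)
    mask[0, 1, 2] = 1  # single voxel -> its 2x2 block is foreground
    sub = ft._downsample_mask(mask, (2, 2))
    assert sub[0, 0, 1] == 1 and sub.sum() == 1


# ---------------------------------------------------------------------------
# Fractal features
# ---------------------------------------------------------------------------

def test_box_counting_dimension_limits():
    cube = ROIMask(np.ones((16, 16, 16), dtype=np.uint8))
    vol = np.random.default_rng(0).random((16, 16, 16)) + 1
    f = ft.fractal_features(vol, cube)
    assert f["box_counting_dimension"] == pytest.approx(3.0, abs=0.15)

    square = np.zeros((1, 32, 32), dtype=np.uint8)
    square[0] = 1
    vol2 = np.random.default_rng(0).random((1, 32, 32)) + 1
    d = ft._box_counting_dimension(square.astype(bool))
    assert d == pytest.approx(2.0, abs=0.15)


def test_lacunarity_constant_roi_is_one():
    vol = np.full((8, 8, 8), 5.0)
    mask = np.ones_like(vol, dtype=np.uint8)
    assert ft._lacunarity(vol, mask.astype(bool)) == pytest.approx(1.0)


def test_fractal_too_small_mask_raises():
    mask = np.zeros((4, 4, 4), dtype=np.uint8)
    mask[1, 1, 1] = 1
    with pytest.raises(ValueError):
        ft.fractal_features(np.ones((4, 4, 4)), ROIMask(mask))


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def test_extract_all_roster(phantom_pair):
    fv = ft.extract_all(*phantom_pair)
    assert list(fv.keys()) == ft.FEATURE_ROSTER
    assert len(fv) == 208
    assert all(math.isfinite(v) for v in fv.values())
    assert "LL_HIST.kurtosis" in fv
    assert "HL_GLCM.information_Measure_II" in fv


def test_roster_family_counts():
    roster = ft.feature_roster()
    fam = lambda pref: sum(n.startswith(pref) for n in roster)
    assert fam("HIST.") == 10
    assert fam("GLCM.") == 22
    assert fam("GLRLM.") == 9
    assert fam("FRAC.") == 3
    wavelet = [n for n in roster if n.split("_")[0] in ft.SUBBANDS]
    assert len(wavelet) == 164


def test_shipped_roster_json_matches():
    import json
    from importlib import resources
    data = json.loads(resources.files("npcradiomics")
                      .joinpath("data/feature_roster.json").read_text())
    assert data == ft.FEATURE_ROSTER


def test_translation_invariance(phantom_pair):
    volume, mask = phantom_pair
    fv = ft.extract_all(volume, mask)
    # interior shift: 1 slice, even in-plane steps (the slice-wise dyadic
    # wavelet grid is invariant to even shifts only)
    shifted_v = np.roll(volume.voxels, (1, 2, -2), axis=(0, 1, 2))
    shifted_m = np.roll(mask.voxels, (1, 2, -2), axis=(0, 1, 2))
    fv2 = ft.extract_all(ImageVolume(shifted_v), ROIMask(shifted_m))
    for name in ft.FEATURE_ROSTER:
        assert fv[name] == pytest.approx(fv2[name], rel=1e-9), name


def test_extraction_deterministic(phantom_pair):
    a = ft.extract_all(*phantom_pair)
    b = ft.extract_all(*phantom_pair)
    assert a == b
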