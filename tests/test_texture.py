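"""Texture features against brute-force enumeration and closed forms."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from usfusion.texture import (FEATURE_NAMES, GCM, GCMConfig,
                              ORDER2_DIRECTIONS, ORDER3_CONFIGURATIONS,
                              autocorrelation_index, compute_gcm,
                              default_config, edge_features, feature_table,
                              gcm_per_displacement, haralick, haralick_mean,
                              hurst_index, laws_features, quantize,
                              texture_vector, wavelet_entropies)


# ---------------------------------------------------------------------------
# Brute-force oracles

def gcm2_brute(q, dx, dy, n):
    counts = np.zeros((n, n), dtype=np.int64)
    h, w = q.shape
    for y in range(h):
        for x in range(w):
            x2, y2 = x + dx, y + dy
            if 0 <= x2 < w and 0 <= y2 < h:
                counts[q[y, x], q[y2, x2]] += 1
    return counts


def gcm3_brute(q, d1, d2, n):
    counts = np.zeros((n, n, n), dtype=np.int64)
    h, w = q.shape
    (dx1, dy1), (dx2, dy2) = d1, d2
    for y in range(h):
        for x in range(w):
            xa, ya, xb, yb = x + dx1, y + dy1, x + dx2, y + dy2
            if 0 <= xa < w and 0 <= ya < h and 0 <= xb < w and 0 <= yb < h:
                counts[q[ya, xa], q[y, x], q[yb, xb]] += 1
    return counts


def haralick_naive(dense):
    """Direct-formula Haralick statistics on a dense order-2 GCM."""
    p = dense / dense.sum()
    n = dense.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt(((i - mu_i) ** 2 * p).sum())
    sd_j = np.sqrt(((j - mu_j) ** 2 * p).sum())
    nz = p > 0
    corr = 0.0 if sd_i < 1e-12 or sd_j < 1e-12 else \
        (((i - mu_i) * (j - mu_j) * p).sum() / (sd_i * sd_j))
    return {
        "homogeneity": (p / (1.0 + (i - j) ** 2)).sum(),
        "energy": (p ** 2).sum(),
        "entropy": -(p[nz] * np.log2(p[nz])).sum(),
        "correlation": corr,
        "contrast": (p * (i - j) ** 2).sum(),
        "variance": (p * (((i - mu_i) ** 2) + ((j - mu_j) ** 2)) / 2).sum(),
    }


# ---------------------------------------------------------------------------
# Quantization

def test_quantize_identity_and_threshold():
    v = np.arange(256, dtype=np.uint8).reshape(16, 16)
    assert np.array_equal(quantize(v, 256), v)
    two = quantize(v, 2)
    assert np.array_equal(two.ravel() == 1, np.arange(256) >= 128)


def test_quantize_histogram_matches_binning_oracle(rng):
    patch = rng.integers(0, 256, (16, 16))
    q = quantize(patch, 7)
    oracle = np.floor(patch * 7 / 256).astype(int)
    assert np.array_equal(q, oracle)


def test_quantize_validation():
    with pytest.raises(ValueError):
        quantize(np.zeros((4, 4)), 1)
    with pytest.raises(ValueError):
        quantize(np.full((4, 4), 300), 8)


# ---------------------------------------------------------------------------
# GCM counting

def test_gcm_order2_counts_match_enumeration(rng):
    for _ in range(100):
        q = rng.integers(0, 4, (8, 8))
        cfg = GCMConfig(2, 4, ((1, 0),))
        assert np.array_equal(compute_gcm(q, cfg).to_dense(),
                              gcm2_brute(q, 1, 0, 4))


def test_gcm_order2_family_sums_over_directions(rng):
    q = rng.integers(0, 4, (8, 8))
    cfg = GCMConfig(2, 4, ORDER2_DIRECTIONS)
    total = sum(gcm2_brute(q, dx, dy, 4) for dx, dy in ORDER2_DIRECTIONS)
    assert np.array_equal(compute_gcm(q, cfg).to_dense(), total)


def test_gcm_order3_counts_match_enumeration(rng):
    for d1, d2 in ORDER3_CONFIGURATIONS:
        q = rng.integers(0, 4, (8, 8))
        cfg = GCMConfig(3, 4, ((d1, d2),))
        assert np.array_equal(compute_gcm(q, cfg).to_dense(),
                              gcm3_brute(q, d1, d2, 4))


def test_gcm_constant_patch_mass_in_diagonal_cell():
    q = np.full((6, 6), 2)
    g2 = compute_gcm(q, GCMConfig(2, 4, ((1, 0),)))
    assert g2.total == 6 * 5
    assert np.array_equal(g2.levels, [[2, 2]])
    g3 = compute_gcm(q, GCMConfig(3, 4, (((1, 0), (-1, 0)),)))
    assert np.array_equal(g3.levels, [[2, 2, 2]])
    assert g3.total == 6 * 4


def test_gcm_too_small_patch_gives_empty_total():
    q = np.zeros((1, 1), dtype=int)
    g = compute_gcm(q, GCMConfig(2, 4, ((1, 0),)))
    assert g.total == 0
    with pytest.raises(ValueError):
        haralick(g)


def test_gcm_full_family_is_symmetric(rng):
    q = rng.integers(0, 8, (20, 20))
    dense = compute_gcm(q, GCMConfig(2, 8, ORDER2_DIRECTIONS)).to_dense()
    assert np.array_equal(dense, dense.T)


def test_gcm_probabilities_sum_to_one(rng):
    q = rng.integers(0, 16, (12, 12))
    g = compute_gcm(q, GCMConfig(2, 16, ORDER2_DIRECTIONS))
    assert abs(g.probabilities().sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# Haralick statistics

def test_haralick_constant_image_closed_forms():
    q = np.full((8, 8), 3)
    feats = haralick(compute_gcm(q, GCMConfig(2, 8, ((1, 0),))))
    assert feats["energy"] == 1.0
    assert feats["entropy"] == 0.0
    assert feats["contrast"] == 0.0
    assert feats["homogeneity"] == 1.0


def test_haralick_uniform_gcm_entropy_log2k():
    levels = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    g = GCM(levels=levels, counts=np.ones(4, dtype=np.int64),
            config=GCMConfig(2, 4, ((1, 0),)))
    assert abs(haralick(g)["entropy"] - 2.0) < 1e-12  # log2(4)


def test_haralick_matches_naive_formula_oracle(rng):
    for _ in range(20):
        q = rng.integers(0, 4, (8, 8))
        g = compute_gcm(q, GCMConfig(2, 4, ((1, 1),)))
        mine = haralick(g)
        oracle = haralick_naive(g.to_dense())
        for k, v in oracle.items():
            assert abs(mine[k] - v) < 1e-10, k


def test_order3_haralick_constant_and_contrast(rng):
    q = np.full((8, 8), 1)
    feats = haralick(compute_gcm(q, GCMConfig(3, 4, (((1, 0), (-1, 0)),))))
    assert feats["energy"] == 1.0 and feats["contrast"] == 0.0
    # stripes along x: every horizontal triple is (0,1,0) or (1,0,1)
    q = (np.arange(8)[None, :] % 2) * np.ones((8, 1), dtype=int)
    feats = haralick(compute_gcm(q, GCMConfig(3, 2, (((1, 0), (-1, 0)),))))
    assert abs(feats["contrast"] - 1.0) < 1e-12  # ((1)^2 + (1)^2)/2


# ---------------------------------------------------------------------------
# Edge features

def test_edge_features_constant_patch_is_zero():
    assert edge_features(np.full((10, 10), 37)) == (0.0, 0.0, 0.0)


def test_edge_features_step_edge_has_zero_orientation_variability():
    patch = np.zeros((12, 12))
    patch[:, 6:] = 200.0
    freq, contrast, orient_var = edge_features(patch)
    assert freq > 0 and contrast > 0
    assert orient_var < 1e-12


def test_sobel_on_ramp_matches_hand_convolution():
    from scipy import ndimage
    ramp = np.arange(25, dtype=float).reshape(5, 5)
    gx = ndimage.sobel(ramp, axis=1, mode="reflect")
    kernel = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    oracle = convolve2d(ramp, kernel[:, ::-1][::-1, :], mode="same",
                        boundary="symm")
    assert np.allclose(gx, oracle)


# ---------------------------------------------------------------------------
# Laws features

def test_laws_constant_patch_all_zero():
    feats = laws_features(np.full((10, 10), 99))
    assert all(v == 0.0 for v in feats.values())


def test_laws_stripes_excite_ripple_detector():
    """Period-2 vertical stripes are pure high-frequency texture: the R5
    ripple mask responds while the constant patch stays at zero."""
    stripes = np.tile([0.0, 200.0], (10, 5))
    feats = laws_features(stripes)
    assert feats["laws_L5R5_frequency"] > 0.0
    assert feats["laws_L5R5_density"] > 0.0
    assert laws_features(np.full((10, 10), 100.0))["laws_L5R5_frequency"] == 0.0


def test_laws_energy_map_matches_direct_convolution(rng):
    from usfusion.texture import _LAWS_1D, _laws_energy_map
    patch = rng.normal(size=(9, 9))
    k = np.outer(_LAWS_1D["L5"], _LAWS_1D["E5"])
    oracle = np.abs(convolve2d(patch, k[::-1, ::-1], mode="same",
                               boundary="symm"))
    k2 = np.outer(_LAWS_1D["E5"], _LAWS_1D["L5"])
    oracle2 = np.abs(convolve2d(patch, k2[::-1, ::-1], mode="same",
                                boundary="symm"))
    assert np.allclose(_laws_energy_map(patch, "L5E5"),
                       0.5 * (oracle + oracle2), atol=1e-10)


# ---------------------------------------------------------------------------
# Hurst, wavelets, autocorrelation

def _fbm_surface(h_exp, size, seed):
    """Spectral-synthesis fractional Brownian surface with exponent H."""
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC divergence
    amp = f ** (-(h_exp + 1.0))
    phase = rng.uniform(0, 2 * np.pi, (size, size))
    spec = amp * np.exp(1j * phase)
    surf = np.real(np.fft.ifft2(spec))
    surf = (surf - surf.mean()) / surf.std()
    return surf * 30.0 + 128.0


def test_hurst_constant_patch_zero():
    assert hurst_index(np.full((20, 20), 50)) == 0.0


def test_hurst_recovers_known_exponent():
    estimates = [hurst_index(np.clip(_fbm_surface(0.7, 64, s), 0, 255))
                 for s in range(20)]
    assert abs(np.mean(estimates) - 0.7) < 0.1


def test_hurst_iid_noise_is_rough(rng):
    estimates = [hurst_index(np.random.default_rng(s).integers(0, 256, (32, 32)))
                 for s in range(10)]
    assert np.mean(estimates) < 0.2


def test_wavelet_entropies_constant_patch_zero():
    assert wavelet_entropies(np.full((16, 16), 7)) == (0.0, 0.0)


def test_haar_energy_conservation():
    rng = np.random.default_rng(1)
    patch = rng.normal(size=(16, 16))
    from usfusion.texture import haar_level
    approx, (h, v, d) = haar_level(patch)
    total = (approx ** 2).sum() + (h ** 2).sum() + (v ** 2).sum() + (d ** 2).sum()
    assert abs(total - (patch ** 2).sum()) < 1e-6


def test_haar_2x2_closed_form():
    from usfusion.texture import haar_level
    block = np.array([[1.0, 3.0], [5.0, 7.0]])
    approx, (h, v, d) = haar_level(block)
    assert np.isclose(approx[0, 0], (1 + 3 + 5 + 7) / 2)   # orthonormal scaling
    assert np.isclose(abs(h[0, 0]), abs(1 + 3 - 5 - 7) / 2)
    assert np.isclose(abs(v[0, 0]), abs(1 - 3 + 5 - 7) / 2)
    assert np.isclose(abs(d[0, 0]), abs(1 - 3 - 5 + 7) / 2)


def test_autocorrelation_constant_is_one_checkerboard_minus_one():
    assert autocorrelation_index(np.full((8, 8), 9)) == 1.0
    cb = (np.indices((8, 8)).sum(axis=0) % 2) * 255
    assert abs(autocorrelation_index(cb) + 1.0) < 1e-12


def test_autocorrelation_matches_covariance_oracle(rng):
    p = rng.normal(size=(10, 10))
    mu, var = p.mean(), ((p - p.mean()) ** 2).mean()
    rho_h = ((p[:, 1:] - mu) * (p[:, :-1] - mu)).mean() / var
    rho_v = ((p[1:, :] - mu) * (p[:-1, :] - mu)).mean() / var
    assert abs(autocorrelation_index(p) - 0.5 * (rho_h + rho_v)) < 1e-10


# ---------------------------------------------------------------------------
# The 41-feature vector

def test_texture_vector_length_and_names(small_patches):
    vec = texture_vector(small_patches[0].bmode)
    assert len(vec) == 41
    assert len(FEATURE_NAMES) == 41
    assert len(set(FEATURE_NAMES)) == 41


def test_texture_vector_deterministic(small_patches):
    p = small_patches[1].ceus
    assert np.array_equal(texture_vector(p), texture_vector(p))


def test_haralick_block_invariant_under_90_degree_rotation(small_patches):
    """The 45-degree direction family is closed under quarter turns."""
    p = small_patches[0].bmode
    cfg = default_config(2)
    a = haralick_mean(quantize(p, 256), cfg)
    b = haralick_mean(quantize(np.rot90(p), 256), cfg)
    for k in a:
        assert abs(a[k] - b[k]) < 1e-9


def test_texture_vector_finite_on_random_patches(rng):
    for _ in range(25):
        patch = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        vec = texture_vector(patch)
        assert np.all(np.isfinite(vec)) and len(vec) == 41


def test_texture_vector_finite_on_extreme_patches():
    for patch in (np.zeros((16, 16), np.uint8),
                  np.full((16, 16), 255, np.uint8)):
        assert np.all(np.isfinite(texture_vector(patch)))


def test_hcc_patches_have_higher_gcm_entropy(small_patches):
    """Heterogeneous HCC texture carries more co-occurrence entropy."""
    cfg = default_config(2)
    ent = {"HCC": [], "PAR": []}
    for p in small_patches:
        ent[p.label].append(haralick_mean(quantize(p.bmode, 256),
                                          cfg)["entropy"])
    assert np.mean(ent["HCC"]) > np.mean(ent["PAR"])


def test_feature_table_columns(small_patches):
    table = feature_table(small_patches[:4], channels="both")
    assert len(table) == 4
    feat_cols = [c for c in table.columns
                 if c.startswith(("bmode_", "ceus_"))]
    assert len(feat_cols) == 82
    assert set(table["label"]) <= {"HCC", "PAR"}
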