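"""Texture-bank tests: brute-force oracle agreement, closed-form degenerate
cases, parameter recovery, and invariances."""

import numpy as np
import pytest
from oracles import (fbm_surface, haralick14_bruteforce, histogram10_bruteforce,
                     ngtdm5_bruteforce, periodogram_slope)

from mammoseq import radiomics as rad
from mammoseq import synthetic as syn


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_matches_enumerated_binning_rule():
    v = np.arange(256).reshape(16, 16)
    q = rad.quantize(v, 16)
    assert np.array_equal(q, v // 16)


def test_quantize_degenerate_and_shift_invariance(rng):
    assert np.all(rad.quantize(np.full((8, 8), 3.7)) == 0)
    a = rng.normal(size=(32, 32))
    assert np.array_equal(rad.quantize(a), rad.quantize(a + 123.4))
    with pytest.raises(ValueError):
        rad.quantize(a, n_levels=1)


# ---------------------------------------------------------------------------
# GLCM + Haralick
# ---------------------------------------------------------------------------

def test_glcm_checkerboard_and_degenerate():
    checker = np.array([[0, 1], [1, 0]])
    g = rad.compute_glcm(checker, angles_deg=(0,), n_levels=2)
    assert g.probs[0, 1] == pytest.approx(0.5)
    assert g.probs[1, 0] == pytest.approx(0.5)
    const = rad.compute_glcm(np.zeros((4, 4), dtype=int), n_levels=2)
    assert const.probs[0, 0] == pytest.approx(1.0)


def test_glcm_always_normalized(rng):
    for _ in range(5):
        q = rng.integers(0, 16, (20, 20))
        g = rad.compute_glcm(q, n_levels=16)
        assert g.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.probs, g.probs.T)


def test_haralick_closed_forms():
    const = rad.compute_glcm(np.zeros((4, 4), dtype=int), n_levels=2)
    f = rad.haralick14(const)
    assert f[0] == pytest.approx(1.0)   # energy
    assert f[1] == pytest.approx(0.0)   # contrast
    assert f[8] == pytest.approx(0.0)   # entropy
    checker = rad.compute_glcm(np.array([[0, 1], [1, 0]]), angles_deg=(0,), n_levels=2)
    f = rad.haralick14(checker)
    assert f[1] == pytest.approx(1.0)   # contrast
    assert f[0] == pytest.approx(0.5)   # energy


def test_haralick_matches_bruteforce_on_random_matrices(rng):
    for _ in range(50):
        m = rng.random((8, 8))
        m = m + m.T
        p = m / m.sum()
        ours = rad.haralick14(rad.GLCMMatrix(p, n_levels=8))
        ref = haralick14_bruteforce(p)
        np.testing.assert_allclose(ours, ref, atol=1e-10)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def test_ngtdm_constant_grid():
    f = rad.ngtdm5(np.zeros((8, 8)))
    assert f[0] == pytest.approx(1.0 / rad.EPS)  # coarseness capped at 1/eps
    assert np.all(f[1:] == 0.0)


def test_ngtdm_matches_bruteforce(rng):
    for _ in range(50):
        q = rng.integers(0, 6, (16, 16)).astype(float)
        np.testing.assert_allclose(
            rad.ngtdm5(q), ngtdm5_bruteforce(q), atol=1e-10
        )
    assert len(rad.ngtdm5(rng.integers(0, 4, (4, 4)).astype(float))) == 5


# ---------------------------------------------------------------------------
# histogram family
# ---------------------------------------------------------------------------

def test_histogram_degenerate_and_symmetry():
    f = rad.histogram10(np.full((16, 16), 7.0))
    # sd, skewness, entropy zero; energy 1 for a constant patch
    assert f[1] == 0 and f[2] == 0 and f[7] == 0 and f[8] == pytest.approx(1.0)
    bimodal = np.array([0.0, 1.0] * 128)
    f = rad.histogram10(bimodal)
    assert f[0] == pytest.approx(0.5)
    assert f[2] == pytest.approx(0.0, abs=1e-12)


def test_histogram_normal_moments(rng):
    x = rng.standard_normal((512, 512))
    f = rad.histogram10(x)
    assert abs(f[0]) < 0.02        # mean
    assert abs(f[3]) < 0.05        # excess kurtosis


def test_histogram_matches_bruteforce(rng):
    for _ in range(50):
        arr = rng.normal(size=(16, 16))
        np.testing.assert_allclose(
            rad.histogram10(arr), histogram10_bruteforce(arr), atol=1e-10
        )


# ---------------------------------------------------------------------------
# edge gradient
# ---------------------------------------------------------------------------

def test_edge_gradient_constant_and_step():
    assert np.all(rad.edge_gradient4(np.full((32, 32), 5.0)) == 0.0)
    step = np.zeros((32, 32))
    step[:, 16:] = 1.0
    mag_band = 2.0 / 32  # classic Sobel responds in the two columns at the edge
    f = rad.edge_gradient4(step)
    assert f[3] == pytest.approx(mag_band)


def test_edge_gradient_axis_swap_invariance(rng):
    a = rng.normal(size=(64, 64))
    f1 = rad.edge_gradient4(a)
    f2 = rad.edge_gradient4(np.rot90(a))
    assert f1[0] == pytest.approx(f2[0], rel=1e-12)


# ---------------------------------------------------------------------------
# spectral families
# ---------------------------------------------------------------------------

def test_radial_psd_sinusoid_concentration():
    n = 64
    k0 = 8
    yy = np.arange(n)
    img = np.cos(2 * np.pi * k0 * yy / n)[None, :] * np.ones((n, 1))
    psd = rad.radial_psd(img, window="none")
    assert int(np.argmax(psd.power)) == k0 - 1  # annulus index k0 (freq excl. DC)


def test_radial_psd_parseval(rng):
    x = rng.normal(size=(64, 64))
    psd_input = x - x.mean()
    n = 64
    power = np.abs(np.fft.fft2(psd_input)) ** 2 / n**2
    assert power.sum() == pytest.approx(psd_input.var() * n**2, rel=1e-6)


def test_fourier2_closed_forms(rng):
    zero = rad.radial_psd(np.zeros((64, 64)), window="none")
    assert np.all(rad.fourier2(zero) == 0.0)
    n, k0 = 64, 12
    img = np.cos(2 * np.pi * k0 * np.arange(n) / n)[None, :] * np.ones((n, 1))
    psd = rad.radial_psd(img, window="none")
    r, m = rad.fourier2(psd)
    assert m == pytest.approx(k0 / n, rel=1e-6)
    # direct-summation oracle on the stored psd
    band = psd.freq >= 3 / n
    assert r == pytest.approx(np.sqrt(psd.power[band].sum()), rel=1e-12)


def test_powerlaw_recovers_generator_slope():
    est = []
    for s in range(5):
        img = syn.render_texture(
            syn.TextureParams(beta=2.0, lump_density=0, noise_sd=0), (512, 512), rng=s
        )
        est.append(rad.powerlaw8(img)[0])  # hann, full band
    assert abs(np.mean(est) - 2.0) < 0.15


def test_powerlaw_white_noise_flat():
    vals = []
    for s in range(10):
        img = np.random.default_rng(s).standard_normal((256, 256))
        vals.append(rad.powerlaw8(img))
    mean8 = np.mean(vals, axis=0)
    assert np.all(np.abs(mean8) < 0.2)
    assert len(mean8) == 8


def test_powerlaw_agrees_with_independent_periodogram_regression():
    img = syn.render_texture(
        syn.TextureParams(beta=2.5, lump_density=0, noise_sd=0), (512, 512), rng=3
    )
    ours = rad.powerlaw8(img)[4]  # no window, full band
    assert ours == pytest.approx(periodogram_slope(img), abs=1e-6)


# ---------------------------------------------------------------------------
# fractal families
# ---------------------------------------------------------------------------

def test_boxcount_smooth_surface_limit():
    ramp = np.tile(np.linspace(0, 1, 512), (512, 1))
    f = rad.boxcount6(ramp)
    assert len(f) == 6
    assert abs(f[0] - 2.0) < 0.1
    with pytest.raises(ValueError):
        rad.boxcount6(np.zeros((64, 64)))


def test_minkowski_constant_is_exactly_two():
    assert rad.minkowski1(np.ones((128, 128))) == pytest.approx(2.0, abs=1e-6)


def test_fractal_estimators_track_roughness():
    """FD estimates decrease monotonically with the Hurst exponent and agree
    with 3-H at the smooth end of the range; both estimators stay mutually
    consistent.  (Both carry the known negative max-statistic bias on rough
    lattice fBm, so the smoothest case is the quantitative anchor.)"""
    bc, mk = {}, {}
    for hurst in (0.3, 0.7):
        imgs = [fbm_surface(hurst, 512, s) for s in range(3)]
        bc[hurst] = np.mean([rad.boxcount6(i)[0] for i in imgs])
        mk[hurst] = np.mean([rad.minkowski1(i) for i in imgs])
    assert bc[0.3] > bc[0.7] and mk[0.3] > mk[0.7]
    assert abs(bc[0.7] - 2.3) < 0.2
    assert abs(mk[0.7] - 2.3) < 0.2
    for hurst in (0.3, 0.7):
        assert abs(bc[hurst] - mk[hurst]) < 0.25


# ---------------------------------------------------------------------------
# the full bank
# ---------------------------------------------------------------------------

def test_bank_structure_and_determinism(texture_roi):
    fv = rad.extract_radiomics(texture_roi)
    fv2 = rad.extract_radiomics(texture_roi)
    assert len(fv) == 50
    assert fv.category_counts() == rad.CATEGORY_COUNTS
    np.testing.assert_array_equal(fv.values, fv2.values)
    with pytest.raises(ValueError):
        rad.extract_radiomics(np.zeros((256, 256)))


def test_bank_shift_invariance(texture_roi):
    base = rad.extract_radiomics(texture_roi)
    shifted = rad.extract_radiomics(texture_roi + 250.0)
    offset_feats = {"hist_mean", "hist_median", "hist_p05", "hist_p95"}
    for name, v0, v1 in zip(base.names, base.values, shifted.values):
        if name in offset_feats:
            assert v1 - v0 == pytest.approx(250.0, abs=1e-6), name
        else:
            assert v1 == pytest.approx(v0, abs=1e-8), name
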