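"""Fourier-optics forward model: defocus phase, PSF synthesis and image
formation, checked against hand values and brute-force oracles."""

import numpy as np
import pytest

from edofstain.optics import (OpticalConfig, PhaseMask, SceneSample,
                              add_read_noise, compute_psf, cubic_mask,
                              defocus_phase, form_image, mask_phase,
                              path_length_error, psf_from_phase, pupil_coords,
                              pupil_phase, toy_optics)
from edofstain.zernike import unit_disk_grid


# --------------------------------------------------------------------------- #
# configuration contracts
# --------------------------------------------------------------------------- #

@pytest.mark.parametrize("kw", [
    dict(wavelengths=(473.0, 473.0)),
    dict(wavelengths=(-1.0, 640.0)),
    dict(numerical_aperture=1.2),
    dict(n_depths=20),          # must be odd
    dict(dof_range=-5.0),
    dict(read_noise_sigma=-0.1),
    dict(defocus_model="exact-z0", in_focus_depth=0.0),
])
def test_config_invariants_rejected(kw):
    with pytest.raises(ValueError):
        OpticalConfig(**kw)


def test_depth_grid_symmetric_about_focus():
    cfg = OpticalConfig()
    grid = cfg.depth_grid
    assert len(grid) == 21
    assert np.allclose(grid + grid[::-1], 2 * cfg.in_focus_depth)
    assert np.allclose(np.diff(grid), 10.0)  # 200 µm over 21 planes


# --------------------------------------------------------------------------- #
# defocus phase
# --------------------------------------------------------------------------- #

def test_defocus_hand_value_exact_model():
    """R = 1000 µm, z0 = 10 mm, z = 9.9 mm, λ = 473 nm:
    W_m = (R²/2)(z0−z)/z0² = 0.5 µm, edge phase 2π·0.5/0.473 = 6.642 rad."""
    cfg = OpticalConfig(pupil_radius=1000.0, in_focus_depth=10000.0,
                        defocus_model="exact-z0")
    assert path_length_error(cfg, 9900.0) == pytest.approx(0.5)
    rho = np.array([[1.0]])
    phi = defocus_phase(cfg, 9900.0, 473.0, rho=rho)
    assert phi[0, 0] == pytest.approx(2 * np.pi * 0.5 / 0.473, rel=1e-6)
    assert phi[0, 0] == pytest.approx(6.642, abs=1e-3)


def test_defocus_zero_at_focus_and_linear_in_offset():
    cfg = toy_optics()
    z0 = cfg.in_focus_depth
    rho, _, _ = pupil_coords(cfg, 473.0)
    assert np.all(defocus_phase(cfg, z0, 473.0, rho=rho) == 0.0)
    p1 = defocus_phase(cfg, z0 - 50.0, 473.0, rho=rho)
    p2 = defocus_phase(cfg, z0 - 100.0, 473.0, rho=rho)
    assert np.allclose(p2, 2 * p1, atol=1e-12)


def test_defocus_scales_inversely_with_wavelength():
    """(2π/λ)W_m at fixed geometry scales as 1/λ across the two channels."""
    cfg = toy_optics()
    z = cfg.in_focus_depth - 80.0
    rho = np.array([[0.7]])
    p473 = defocus_phase(cfg, z, 473.0, rho=rho)[0, 0]
    p640 = defocus_phase(cfg, z, 640.0, rho=rho)[0, 0]
    assert p473 / p640 == pytest.approx(640.0 / 473.0, rel=1e-9)


def test_defocus_errors():
    cfg = toy_optics()
    with pytest.raises(ValueError, match="outside"):
        defocus_phase(cfg, cfg.in_focus_depth + cfg.dof_range, 473.0)
    with pytest.raises(ValueError, match="not configured"):
        defocus_phase(cfg, cfg.in_focus_depth, 550.0)


# --------------------------------------------------------------------------- #
# mask phase
# --------------------------------------------------------------------------- #

def test_mask_phase_zero_height_and_wavelength_ratio():
    rho, theta, _ = unit_disk_grid(64)
    zero = PhaseMask()
    assert np.all(mask_phase(zero, 473.0, rho, theta) == 0.0)
    mask = cubic_mask(alpha=5.0)
    p1 = mask_phase(mask, 473.0, rho, theta)
    p2 = mask_phase(mask, 640.0, rho, theta)
    n1 = mask.refractive_index(473.0) - 1
    n2 = mask.refractive_index(640.0) - 1
    expected = (n1 * 0.640) / (n2 * 0.473)
    nz = p2 != 0
    assert np.allclose(p1[nz] / p2[nz], expected, rtol=1e-9)


def test_cubic_mask_reproduces_analytic_cubic_field():
    """The 55-mode fit recovers the target α-rad edge phase against a direct
    cubic oracle to basis-truncation/quadrature residual."""
    alpha = 20.0
    mask = cubic_mask(alpha=alpha, wavelength_nm=473.0)
    rho, theta, inside = unit_disk_grid(96)
    x, y = rho * np.cos(theta), rho * np.sin(theta)
    oracle = alpha * (x**3 + y**3)          # rad at 473 nm
    fitted = mask_phase(mask, 473.0, rho, theta)
    resid = np.abs(fitted - oracle)[inside].max()
    assert resid < 1e-6 * alpha


def test_total_phase_is_exact_sum_of_components():
    cfg = toy_optics()
    mask = cubic_mask(alpha=8.0)
    pp = pupil_phase(cfg, mask, cfg.in_focus_depth - 60.0, 640.0)
    assert np.array_equal(pp.total, pp.defocus + pp.mask)
    assert pp.defocus[pp.aperture].max() > 0


# --------------------------------------------------------------------------- #
# PSF synthesis
# --------------------------------------------------------------------------- #

def test_psf_stack_normalized_nonnegative_centered(flat_psfs, toy_cfg):
    v = flat_psfs.values
    assert v.shape == (2, 21, toy_cfg.psf_support, toy_cfg.psf_support)
    assert np.all(v >= 0)
    assert np.allclose(v.sum(axis=(2, 3)), 1.0, atol=1e-9)
    # in-focus slice is Airy-like: peak at the center pixel
    s = toy_cfg.psf_support
    for ch in range(2):
        p = v[ch, 10]
        assert np.unravel_index(p.argmax(), p.shape) == (s // 2, s // 2)


def test_psf_width_nondecreasing_with_defocus(flat_psfs, toy_cfg):
    """Without a mask, defocus can only broaden the PSF."""
    s = toy_cfg.psf_support
    c = np.arange(s) - s // 2
    xx, yy = np.meshgrid(c, c)
    r2 = xx**2 + yy**2
    for ch in range(2):
        widths = [(flat_psfs.values[ch, d] * r2).sum() for d in range(10, 21)]
        assert all(w2 >= w1 - 1e-9 for w1, w2 in zip(widths, widths[1:]))


def test_psf_matches_bruteforce_dft():
    """|F{A e^{iΦ}}|² against a direct double-loop DFT on a 64² pupil."""
    rng = np.random.default_rng(3)
    n = 64
    rho, _, inside = unit_disk_grid(n)
    phase = np.where(inside, rng.uniform(-2, 2, size=(n, n)), 0.0)
    pupil = np.where(inside, np.exp(1j * phase), 0.0)

    # oracle: explicit centered DFT, O(n^4) via outer products per row/col
    k = np.arange(n) - n // 2
    x = np.arange(n) - n // 2
    w = np.exp(-2j * np.pi * np.outer(k, x) / n)
    oracle = np.abs(w @ pupil @ w.T) ** 2
    oracle /= oracle.sum()

    psf = psf_from_phase(np.where(inside, phase, 0.0), inside.astype(float), n)
    assert np.max(np.abs(psf - oracle)) < 1e-10


# --------------------------------------------------------------------------- #
# image formation
# --------------------------------------------------------------------------- #

def test_delta_scene_reproduces_psf(flat_psfs, toy_cfg):
    s = toy_cfg.psf_support
    sc = np.zeros((2, s, s))
    sc[:, s // 2, s // 2] = 1.0
    z = toy_cfg.depth_grid[4]
    img = form_image(SceneSample(planes=sc[None], depths=[z]), flat_psfs)
    for ch in range(2):
        assert np.allclose(img.values[ch], flat_psfs.values[ch, 4], atol=1e-12)


def test_two_depth_scene_matches_spatial_convolution_oracle(flat_psfs, toy_cfg):
    """Multi-depth formation equals the explicit sum of per-depth periodic
    convolutions computed by a direct O(N²·S²) loop."""
    rng = np.random.default_rng(7)
    n = 32
    planes = rng.uniform(size=(2, 2, n, n))
    depths = toy_cfg.depth_grid[[2, 17]]
    small = flat_psfs.values[:, :, 16:48, 16:48].copy()
    small /= small.sum(axis=(2, 3), keepdims=True)
    from edofstain.optics import PSFStack
    psfs32 = PSFStack(values=small, depth_grid=flat_psfs.depth_grid,
                      wavelengths=flat_psfs.wavelengths,
                      pixel_pitch=flat_psfs.pixel_pitch)

    img = form_image(SceneSample(planes=planes, depths=depths), psfs32)

    def conv_loop(scene, psf):
        out = np.zeros_like(scene)
        s = psf.shape[0]
        for dy in range(s):
            for dx in range(s):
                out += psf[dy, dx] * np.roll(scene, (dy - s // 2, dx - s // 2),
                                             axis=(0, 1))
        return out

    for ch in range(2):
        oracle = sum(conv_loop(planes[pi, ch], psfs32.slice(ch, z))
                     for pi, z in enumerate(depths))
        assert np.max(np.abs(img.values[ch] - oracle)) < 1e-10


def test_form_image_linear_shift_equivariant_flux_conserving(flat_psfs, toy_cfg):
    rng = np.random.default_rng(11)
    n = 64
    a = rng.uniform(size=(2, n, n))
    b = rng.uniform(size=(2, n, n)) * 0.3
    z = toy_cfg.depth_grid[6]

    def im(x):
        return form_image(SceneSample(planes=x[None], depths=[z]), flat_psfs).values

    # linearity
    assert np.allclose(im(np.clip(0.5 * a + 0.5 * b, 0, 1)),
                       0.5 * im(a) + 0.5 * im(b), atol=1e-9)
    # integer-pixel shift equivariance under periodic boundaries
    shifted = np.roll(a, (5, -3), axis=(1, 2))
    assert np.allclose(im(shifted), np.roll(im(a), (5, -3), axis=(1, 2)), atol=1e-9)
    # flux conservation per channel (PSFs unit-sum, periodic boundaries)
    out = im(a)
    for ch in range(2):
        assert out[ch].sum() == pytest.approx(a[ch].sum(), rel=1e-6)
    # zero scene -> zero image
    assert np.allclose(im(np.zeros_like(a)), 0.0, atol=1e-12)


def test_form_image_rejects_depth_not_in_grid(flat_psfs, toy_cfg):
    sc = np.zeros((1, 2, 16, 16))
    with pytest.raises(ValueError, match="depth"):
        form_image(SceneSample(planes=sc, depths=[toy_cfg.in_focus_depth + 3.3]),
                   flat_psfs)


# --------------------------------------------------------------------------- #
# read noise
# --------------------------------------------------------------------------- #

def test_read_noise_statistics_and_determinism():
    from edofstain.optics import SensorImage
    img = SensorImage(values=np.full((2, 1000, 500), 0.5))
    out = add_read_noise(img, sigma=0.01, seed=42)
    assert out.values.shape == img.values.shape
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0
    # 10⁶ samples per channel: sample std within 0.01 ± 5e-4
    assert np.std(out.values - img.values) == pytest.approx(0.01, abs=5e-4)
    # reproducible under the same seed
    again = add_read_noise(img, sigma=0.01, seed=42)
    assert np.array_equal(out.values, again.values)
    # sigma = 0 is the identity
    ident = add_read_noise(img, sigma=0.0, seed=1)
    assert np.array_equal(ident.values, img.values)
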