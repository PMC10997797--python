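"""Two-stage end-to-end training: freezing contracts, loss behavior,
reconstruction contracts, and fine-tuning against measured PSFs."""

import numpy as np
import pytest

from edofstain.autograd import default_dtype
from edofstain.optics import (PSFStack, SceneSample, SensorImage, add_read_noise,
                              compute_psf, form_image, toy_optics)
from edofstain.recon import (DifferentiableOptics, ReconNetConfig, _init_state,
                             _iterate, finetune_with_measured_psf, load_checkpoint,
                             reconstruct, rms_loss, save_checkpoint, train_edof)
from edofstain.autograd import Tensor


@pytest.fixture(scope="module")
def tiny_run(train_scenes, toy_cfg):
    """Short two-step reference run: 8 scenes, 64², seed 0, 50 iterations.

    Runs in float64 so that the published 1e-9 optical learning rate
    produces representable (bit-level) coefficient updates."""
    cfg = ReconNetConfig.toy(step1_iterations=30, step2_iterations=20,
                             seed=0, batch=2)
    return train_edof(train_scenes[:8], cfg, toy_cfg), cfg


def test_step1_freezes_mask_step2_trains_it(tiny_run, toy_cfg, train_scenes):
    state, cfg = tiny_run
    init = state.mask_template.zernike_coeffs.astype(state.mask_coeffs.data.dtype)
    # step-2 joint training moved at least one coefficient
    assert not np.array_equal(state.mask_coeffs.data, init)
    # step-1-only run keeps the mask bit-identical to its initialization
    cfg1 = ReconNetConfig.toy(step1_iterations=10, step2_iterations=0, seed=0)
    s1 = train_edof(train_scenes[:8], cfg1, toy_cfg)
    assert np.array_equal(
        s1.mask_coeffs.data,
        s1.mask_template.zernike_coeffs.astype(s1.mask_coeffs.data.dtype))


def test_loss_history_decreases_on_tiny_reference_run(tiny_run):
    """Recorded reference run of this repository: mean loss over the last
    iterations falls below the mean over the first iterations."""
    state, cfg = tiny_run
    lh = np.asarray(state.loss_history)
    assert len(lh) == 50
    assert np.all(lh >= 0)
    assert lh[-10:].mean() < lh[:10].mean()


def test_full_scale_schedule_defaults():
    """The full-scale profile keeps the published schedule: learning rates
    1e-9 (optical) / 1e-4 (digital) and a 30-40k iteration budget."""
    cfg = ReconNetConfig()
    assert cfg.lr_optical == 1e-9
    assert cfg.lr_digital == 1e-4
    assert 30_000 <= cfg.step1_iterations <= 40_000
    assert 30_000 <= cfg.step2_iterations <= 40_000


def test_reconstruct_contract(tiny_run, toy_cfg, flat_psfs, train_scenes):
    state, _ = tiny_run
    scene = train_scenes[0]
    img = form_image(SceneSample(planes=scene[None],
                                 depths=[toy_cfg.depth_grid[3]]), flat_psfs)
    img = add_read_noise(img, seed=0)
    rec = reconstruct(img, state)
    assert rec.values.shape == img.values.shape
    assert rec.values.min() >= 0.0 and rec.values.max() <= 1.0
    # inference determinism: identical input and state -> identical output
    again = reconstruct(img, state)
    assert np.array_equal(rec.values, again.values)
    # untrained state is rejected
    fresh = _init_state(ReconNetConfig.toy(seed=1), toy_cfg, None)
    with pytest.raises(ValueError, match="untrained"):
        reconstruct(img, fresh)


def test_finetune_frozen_mask_and_substitution_identity(toy_cfg, train_scenes):
    """Fine-tuning with measured == simulated PSFs reproduces, under the
    same seed, exactly the dynamics of continuing with the frozen mask; the
    mask coefficients never move."""
    cfg = ReconNetConfig.toy(seed=3)
    simulated = None

    def fresh_state():
        state = _init_state(cfg, toy_cfg, None)
        do = DifferentiableOptics(toy_cfg, state.mask_template)
        return state, do

    state_a, do_a = fresh_state()
    state_b, do_b = fresh_state()
    simulated = compute_psf(toy_cfg, state_a.current_mask())

    with default_dtype(np.float32):
        _iterate(state_a, do_a, train_scenes[:4], 6, joint=False,
                 rng=np.random.default_rng(9))
        _iterate(state_b, do_b, train_scenes[:4], 6, joint=False,
                 rng=np.random.default_rng(9), psf_override=simulated)
    assert np.allclose(state_a.loss_history, state_b.loss_history, rtol=1e-5)

    # public entry point: frozen mask, depth-grid checking
    state_c, _ = fresh_state()
    before = state_c.mask_coeffs.data.copy()
    with default_dtype(np.float32):
        finetune_with_measured_psf(state_c, simulated, train_scenes[:4],
                                   iterations=3)
    assert np.array_equal(state_c.mask_coeffs.data, before)
    assert state_c.phase == "finetune"


def test_finetune_rejects_depth_mismatch(toy_cfg, flat_psfs, train_scenes):
    state = _init_state(ReconNetConfig.toy(seed=4), toy_cfg, None)
    wrong = PSFStack(values=flat_psfs.values,
                     depth_grid=flat_psfs.depth_grid + 3.0,
                     wavelengths=flat_psfs.wavelengths,
                     pixel_pitch=flat_psfs.pixel_pitch)
    with pytest.raises(ValueError, match="missing depths"):
        finetune_with_measured_psf(state, wrong, train_scenes[:2], iterations=1)


def test_finetune_adapts_to_perturbed_psfs(toy_cfg, train_scenes):
    """Controlled mismatch: when the measured PSFs are a blurred version of
    the simulated ones, fine-tuning lowers the loss on perturbed-PSF data
    relative to the unfine-tuned state."""
    import scipy.ndimage as ndi
    cfg = ReconNetConfig.toy(step1_iterations=120, step2_iterations=0, seed=5)
    with default_dtype(np.float32):
        state = train_edof(train_scenes[:8], cfg, toy_cfg)
    sim = compute_psf(toy_cfg, state.current_mask())
    pert = np.stack([[ndi.gaussian_filter(p, 1.0) for p in ch] for ch in sim.values])
    pert /= pert.sum(axis=(2, 3), keepdims=True)
    perturbed = PSFStack(values=pert, depth_grid=sim.depth_grid,
                         wavelengths=sim.wavelengths, pixel_pitch=sim.pixel_pitch)

    def val_loss(st):
        losses = []
        rng = np.random.default_rng(123)
        for scene in train_scenes[8:12]:
            di = int(rng.integers(toy_cfg.n_depths))
            img = form_image(SceneSample(planes=scene[None],
                                         depths=[toy_cfg.depth_grid[di]]),
                             perturbed)
            img = add_read_noise(img, seed=int(rng.integers(2**31)))
            rec = reconstruct(img, st, allow_untrained=True)
            losses.append(np.sqrt(((rec.values - scene) ** 2).mean()))
        return float(np.mean(losses))

    before = val_loss(state)
    with default_dtype(np.float32):
        finetune_with_measured_psf(state, perturbed, train_scenes[:8],
                                   iterations=120)
    after = val_loss(state)
    assert after < before


def test_noise_floor_sanity(toy_cfg):
    """Zero-strength mask, untrained (identity) network, in-focus plane,
    flat scene: the RMS loss sits at the read-noise floor."""
    from edofstain.optics import PhaseMask
    state = _init_state(ReconNetConfig.toy(seed=6),
                        toy_cfg, PhaseMask())  # zero mask
    flat_scene = np.full((2, 64, 64), 0.5)
    psfs = compute_psf(toy_cfg, PhaseMask())
    img = form_image(SceneSample(planes=flat_scene[None],
                                 depths=[toy_cfg.in_focus_depth]), psfs)
    img = add_read_noise(img, seed=7)
    rec = reconstruct(img, state, allow_untrained=True)
    rms = np.sqrt(((rec.values - flat_scene) ** 2).mean())
    assert rms == pytest.approx(toy_cfg.read_noise_sigma, rel=0.15)


def test_rms_loss_zero_iff_exact():
    x = np.random.default_rng(0).uniform(size=(4, 4))
    assert rms_loss(Tensor(x), x).item() == pytest.approx(0.0, abs=1e-10)
    assert rms_loss(Tensor(x + 0.1), x).item() == pytest.approx(0.1, rel=1e-6)


def test_checkpoint_roundtrip(tiny_run, toy_cfg, tmp_path):
    state, cfg = tiny_run
    p = tmp_path / "ckpt.npz"
    save_checkpoint(state, p)
    back = load_checkpoint(p, cfg, toy_cfg)
    assert np.allclose(back.mask_coeffs.data, state.mask_coeffs.data)
    assert back.iteration == state.iteration
    for na, nb in zip(state.nets, back.nets):
        for a, b in zip(na.state_arrays(), nb.state_arrays()):
            assert np.allclose(a, b)
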