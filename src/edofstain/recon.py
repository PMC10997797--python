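"""Digital layer and two-stage end-to-end training of the extended-DOF system.

The optical layer (Zernike mask coefficients) and the digital layer (two
independent encoder-decoder reconstruction networks, one per fluorescence
channel) are optimized jointly against a root-mean-square reconstruction
loss.  Training follows the published two-step schedule:

* step 1 — the mask is frozen at a cubic wavefront-coding initialization and
  only the networks train;
* step 2 — mask coefficients and network weights train jointly, with
  separate learning rates for the optical (default 1e-9) and digital
  (default 1e-4) parameters;
* fine-tuning — simulated PSFs are replaced by measured ones and the
  optical layer stays frozen.

Per iteration: sample a ground-truth scene and a depth from the 21-plane
grid, compute the PSF from the current mask, blur, add read noise,
reconstruct, and update on the RMS loss.  The pupil→PSF map is made
differentiable with respect to the Zernike coefficients through an analytic
adjoint of the Fourier-optics chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concat, custom, no_grad
from .images import TwoChannelImage
from .optics import (N_ZERNIKE, OpticalConfig, PhaseMask, PSFStack, SensorImage,
                     cubic_mask, defocus_phase, mask_phase_basis, pupil_coords)

__all__ = ["ReconNetConfig", "TrainState", "DifferentiableOptics", "train_edof",
           "reconstruct", "finetune_with_measured_psf", "rms_loss",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ReconNetConfig:
    """Reconstruction-stage configuration.

    ``profile`` "paper" follows the published description (4-resolution
    encoder-decoder, base width 32, 256² patches); "toy" is the CPU-scale
    profile used by the test suite (3 resolutions, width 8, 64² patches).
    """

    levels: int = 4
    base_width: int = 32
    patch: int = 256
    lr_optical: float = 1e-9
    lr_digital: float = 1e-4
    batch: int = 2
    step1_iterations: int = 30000
    step2_iterations: int = 30000
    cubic_alpha: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_optical <= 0 or self.lr_digital <= 0:
            raise ValueError("learning rates must be > 0")
        if self.patch % 2 ** (self.levels - 1):
            raise ValueError("patch must be divisible by 2**(levels-1)")

    @classmethod
    def toy(cls, **kw) -> "ReconNetConfig":
        """Desk-scale profile: smaller net and patches, a shorter schedule,
        and a faster digital learning rate to converge within the reduced
        iteration budget.  The cubic strength keeps the package-wide
        default (α ≈ 2x the maximum defocus edge phase over the DOF)."""
        defaults = dict(levels=3, base_width=8, patch=64,
                        step1_iterations=150, step2_iterations=50,
                        lr_digital=1e-3)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrainState:
    """Mask coefficients, the two channel networks, optimizers and history."""

    mask_coeffs: Tensor
    nets: list
    optics: OpticalConfig
    cfg: ReconNetConfig
    mask_template: PhaseMask
    phase: str = "init"           # init | step1-fixed-mask | step2-joint | finetune
    iteration: int = 0
    loss_history: list = field(default_factory=list)
    opt_digital: nn.Adam | None = None
    opt_optical: nn.Adam | None = None
    measured_psfs: PSFStack | None = None

    @property
    def trained(self) -> bool:
        return self.iteration > 0

    def current_mask(self) -> PhaseMask:
        return PhaseMask(zernike_coeffs=self.mask_coeffs.data.copy(),
                         cauchy=self.mask_template.cauchy)


# --------------------------------------------------------------------------- #
# differentiable optical layer
# --------------------------------------------------------------------------- #

class DifferentiableOptics:
    """Pupil→PSF→blur chain with an analytic backward pass.

    Precomputes, per channel, the defocus phases for every depth plane and
    the Zernike phase basis restricted to the aperture.  The PSF gradient
    with respect to the pupil phase follows from the adjoint of the DFT:
    for a loss l with dl/dPSF = h, dl/dφ = −2 Im(P · F[h · conj(U)]) where
    P is the pupil function and U its transform.
    """

    def __init__(self, cfg: OpticalConfig, mask_template: PhaseMask | None = None):
        if cfg.fft_grid % 2:
            raise ValueError("fft_grid must be even")
        self.cfg = cfg
        mask_template = mask_template or PhaseMask()
        self.inside = []      # aperture index per channel
        self.basis = []       # (55, n_inside) phase rad per µm of coefficient
        self.defocus = []     # (n_depths, n_inside) rad
        for ch, lam in enumerate(cfg.wavelengths):
            rho, theta, aperture = pupil_coords(cfg, lam)
            idx = np.where(aperture)
            self.inside.append(idx)
            b = mask_phase_basis(mask_template, lam, rho, theta)
            self.basis.append(np.ascontiguousarray(b[:, idx[0], idx[1]]))
            dph = np.stack([defocus_phase(cfg, z, lam, rho=rho)[idx]
                            for z in cfg.depth_grid])
            self.defocus.append(dph)

    def psf(self, coeffs: Tensor, channel: int, depth_index: int) -> Tensor:
        """Energy-normalized PSF patch as a Tensor differentiable in ``coeffs``."""
        cfg = self.cfg
        n, s = cfg.fft_grid, cfg.psf_support
        idx = self.inside[channel]
        basis = self.basis[channel]
        phi_in = self.defocus[channel][depth_index] + coeffs.data @ basis
        pupil = np.zeros((n, n), dtype=complex)
        pupil[idx] = np.exp(1j * phi_in)
        u = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil)))
        psf_full = np.abs(u) ** 2
        c = n // 2
        lo = c - s // 2
        patch = psf_full[lo:lo + s, lo:lo + s]
        total = patch.sum()
        psf = patch / total

        def backward(g):
            # through normalization
            h_patch = (g - (g * psf).sum()) / total
            h_full = np.zeros((n, n))
            h_full[lo:lo + s, lo:lo + s] = h_patch
            # adjoint of |F{.}|² through the symmetric (even-grid) DFT chain
            q = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(h_full * np.conj(u))))
            grad_phi = -2.0 * np.imag(pupil * q)
            return (basis @ grad_phi[idx],)

        return custom(psf, (coeffs,), backward)


def blur_with_psf(scene: np.ndarray, psf: Tensor) -> Tensor:
    """Periodic convolution of a fixed 2-D scene with a differentiable PSF patch."""
    h, w = scene.shape
    s = psf.shape[0]
    if s > h or s > w:
        raise ValueError("PSF support exceeds scene size")
    top, left = (h - s) // 2, (w - s) // 2
    shift = (-(top + s // 2), -(left + s // 2))
    k = np.zeros((h, w))
    k[top:top + s, left:left + s] = psf.data
    k = np.roll(k, shift, axis=(0, 1))
    scene_f = np.fft.fft2(scene)
    out = np.real(np.fft.ifft2(scene_f * np.fft.fft2(k)))

    def backward(g):
        gk = np.real(np.fft.ifft2(np.conj(scene_f) * np.fft.fft2(g)))
        gk = np.roll(gk, (-shift[0], -shift[1]), axis=(0, 1))
        return (gk[top:top + s, left:left + s],)

    return custom(out, (psf,), backward)


def rms_loss(recon: Tensor, target: np.ndarray) -> Tensor:
    """Root-mean-square reconstruction error (non-negative, 0 iff exact)."""
    d = recon - Tensor(target)
    return ((d * d).mean() + 1e-24) ** 0.5


# --------------------------------------------------------------------------- #
# training
# --------------------------------------------------------------------------- #

def _init_state(cfg: ReconNetConfig, optics: OpticalConfig,
                mask_init: PhaseMask | None) -> TrainState:
    rng = np.random.default_rng(cfg.seed)
    if mask_init is None:
        mask_init = cubic_mask(alpha=cfg.cubic_alpha,
                               wavelength_nm=optics.wavelengths[0])
    nets = [nn.UNet(channels=1, levels=cfg.levels, base=cfg.base_width, rng=rng)
            for _ in range(2)]
    coeffs = Tensor(mask_init.zernike_coeffs.copy(), requires_grad=True)
    state = TrainState(mask_coeffs=coeffs, nets=nets, optics=optics, cfg=cfg,
                       mask_template=mask_init)
    digital_params = [p for net in nets for p in net.parameters()]
    state.opt_digital = nn.Adam(digital_params, lr=cfg.lr_digital)
    state.opt_optical = nn.Adam([coeffs], lr=cfg.lr_optical)
    return state


def _iterate(state: TrainState, diff_optics: DifferentiableOptics,
             scenes: list[np.ndarray], n_iters: int, joint: bool,
             rng: np.random.Generator,
             psf_override: PSFStack | None = None) -> None:
    cfg = state.cfg
    optics = state.optics
    psf_cache: dict[tuple[int, int], Tensor] = {}
    if not joint and psf_override is None:
        # mask frozen: PSFs are constants for the whole phase
        for ch in range(2):
            for di in range(optics.n_depths):
                psf_cache[(ch, di)] = Tensor(
                    diff_optics.psf(state.mask_coeffs.detach(), ch, di).data)
    for _ in range(n_iters):
        state.opt_digital.zero_grad()
        if joint:
            state.opt_optical.zero_grad()
        picks = [(scenes[rng.integers(len(scenes))], int(rng.integers(optics.n_depths)))
                 for _ in range(cfg.batch)]
        ch_losses = []
        for ch in range(2):
            noisy_list, targets = [], []
            for scene, di in picks:
                if psf_override is not None:
                    psf = Tensor(psf_override.values[ch, di])
                elif not joint:
                    psf = psf_cache[(ch, di)]
                else:
                    psf = diff_optics.psf(state.mask_coeffs, ch, di)
                blurred = blur_with_psf(scene[ch], psf)
                noise = rng.normal(0.0, optics.read_noise_sigma, size=blurred.shape)
                noisy_list.append((blurred + Tensor(noise)).reshape(1, 1, *blurred.shape))
                targets.append(scene[ch])
            x = concat(noisy_list, axis=0) if len(noisy_list) > 1 else noisy_list[0]
            rec = state.nets[ch](x)
            ch_losses.append(rms_loss(rec, np.stack(targets)[:, None]))
        loss = (ch_losses[0] + ch_losses[1]) * 0.5
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"training diverged at iteration {state.iteration}: loss={loss.item()}")
        loss.backward()
        state.opt_digital.step()
        if joint:
            state.opt_optical.step()
        state.iteration += 1
        state.loss_history.append(loss.item())


def train_edof(data, cfg: ReconNetConfig, optics: OpticalConfig,
               mask_init: PhaseMask | None = None) -> TrainState:
    """Run the two-step end-to-end schedule on ground-truth scene images.

    ``data`` is a sequence of two-channel ground-truth images, each a
    (2, H, W) array (or TwoChannelImage) in [0,1] with H = W = cfg.patch.
    Each training sample places the scene at a single depth drawn uniformly
    from the configured depth grid.
    """
    scenes = [s.values if isinstance(s, TwoChannelImage) else np.asarray(s, dtype=float)
              for s in data]
    if not scenes:
        raise ValueError("empty training data")
    for s in scenes:
        if s.shape != (2, cfg.patch, cfg.patch):
            raise ValueError(f"expected scenes of shape (2, {cfg.patch}, {cfg.patch})")
    state = _init_state(cfg, optics, mask_init)
    diff_optics = DifferentiableOptics(optics, state.mask_template)
    rng = np.random.default_rng(cfg.seed + 1)
    state.phase = "step1-fixed-mask"
    _iterate(state, diff_optics, scenes, cfg.step1_iterations, joint=False, rng=rng)
    state.phase = "step2-joint"
    _iterate(state, diff_optics, scenes, cfg.step2_iterations, joint=True, rng=rng)
    return state


def finetune_with_measured_psf(state: TrainState, measured: PSFStack, data,
                               iterations: int | None = None) -> TrainState:
    """Fine-tune the networks against measured PSFs; the optical layer is frozen."""
    optics = state.optics
    if measured.n_channels != 2:
        raise ValueError("measured stack must have 2 channels")
    mismatched = [z for z in optics.depth_grid
                  if np.min(np.abs(measured.depth_grid - z)) > 1e-6]
    if mismatched:
        raise ValueError(f"measured stack missing depths (µm): {mismatched}")
    order = [int(np.argmin(np.abs(measured.depth_grid - z))) for z in optics.depth_grid]
    aligned = PSFStack(values=measured.values[:, order],
                       depth_grid=optics.depth_grid,
                       wavelengths=measured.wavelengths,
                       pixel_pitch=measured.pixel_pitch)
    scenes = [s.values if isinstance(s, TwoChannelImage) else np.asarray(s, dtype=float)
              for s in data]
    diff_optics = DifferentiableOptics(optics, state.mask_template)
    rng = np.random.default_rng(state.cfg.seed + 2)
    state.phase = "finetune"
    state.measured_psfs = aligned
    n = iterations if iterations is not None else state.cfg.step2_iterations
    _iterate(state, diff_optics, scenes, n, joint=False, rng=rng, psf_override=aligned)
    return state


def reconstruct(blurred: SensorImage, state: TrainState,
                allow_untrained: bool = False) -> TwoChannelImage:
    """Channel-wise restoration of a blurred sensor image; deterministic."""
    if not state.trained and not allow_untrained:
        raise ValueError("reconstruct called with an untrained state")
    h, w = blurred.values.shape[1:]
    mult = 2 ** (state.cfg.levels - 1)
    ph, pw = (-h) % mult, (-w) % mult
    out = np.empty_like(blurred.values)
    with no_grad():
        for ch in range(2):
            plane = blurred.values[ch]
            if ph or pw:  # pad to the network's stride multiple, crop after
                plane = np.pad(plane, ((0, ph), (0, pw)), mode="reflect")
            x = Tensor(plane[None, None])
            out[ch] = state.nets[ch](x).data[0, 0, :h, :w]
    return TwoChannelImage(values=np.clip(out, 0.0, 1.0))


# --------------------------------------------------------------------------- #
# checkpoints
# --------------------------------------------------------------------------- #

def save_checkpoint(state: TrainState, path) -> None:
    """Single-file checkpoint: mask coefficients, both nets, optimizer state."""
    payload = {
        "mask_coeffs": state.mask_coeffs.data,
        "cauchy": np.asarray(state.mask_template.cauchy),
        "phase": np.asarray(state.phase),
        "iteration": np.asarray(state.iteration),
        "loss_history": np.asarray(state.loss_history),
    }
    for i, net in enumerate(state.nets):
        for j, arr in enumerate(net.state_arrays()):
            payload[f"net{i}_p{j}"] = arr
    np.savez(path, **payload)


def load_checkpoint(path, cfg: ReconNetConfig, optics: OpticalConfig) -> TrainState:
    with np.load(path, allow_pickle=False) as z:
        mask = PhaseMask(zernike_coeffs=z["mask_coeffs"],
                         cauchy=tuple(z["cauchy"].tolist()))
        state = _init_state(cfg, optics, mask)
        for i, net in enumerate(state.nets):
            arrays = []
            j = 0
            while f"net{i}_p{j}" in z:
                arrays.append(z[f"net{i}_p{j}"])
                j += 1
            net.load_state_arrays(arrays)
        state.phase = str(z["phase"])
        state.iteration = int(z["iteration"])
        state.loss_history = list(z["loss_history"])
    return state
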