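"""Fourier-optics forward model of a dual-channel fluorescence microscope.

Image formation with a pupil phase mask is simulated per emission channel
(DAPI-like ~473 nm, Rhodamine-B-like ~640 nm):

* the pupil function carries a defocus phase (quadratic in normalized pupil
  radius, scaled by the path-length error W_m at the pupil edge) plus a
  depth-independent mask phase derived from a physical height map,
* the incoherent PSF is the squared magnitude of the Fourier transform of
  the pupil function, energy-normalized,
* the sensor image is the scene convolved with the PSF at each depth,
  summed across depths, with optional Gaussian read noise.

The pupil is sampled on the frequency grid conjugate to the sensor grid, so
PSFs come out sampled at the configured object-space pixel pitch and can be
applied to scenes by direct (FFT) convolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .zernike import unit_disk_grid, zernike_basis, zernike_mode

__all__ = [
    "OpticalConfig",
    "PhaseMask",
    "PupilPhase",
    "PSFStack",
    "SceneSample",
    "SensorImage",
    "defocus_phase",
    "mask_phase",
    "compute_psf",
    "form_image",
    "add_read_noise",
    "cubic_mask",
    "toy_optics",
    "pupil_coords",
]

N_ZERNIKE = 55  # complete radial orders 0..9, OSA/ANSI ordering


# --------------------------------------------------------------------------- #
# configuration and domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class OpticalConfig:
    """Physical and sampling parameters of the two-channel microscope.

    Wavelengths are emission-band centers in nm; all lengths are µm.  The
    depth grid is ``n_depths`` planes evenly spanning ``dof_range`` and
    symmetric about the in-focus depth ``z0`` (``n_depths`` must be odd so
    the in-focus plane itself is in the grid).
    """

    wavelengths: tuple[float, float] = (473.0, 640.0)
    numerical_aperture: float = 0.13
    pupil_radius: float = 1000.0        # R, µm; used by the exact-z0 defocus model
    in_focus_depth: float = 10000.0     # z0, µm
    dof_range: float = 200.0            # total axial span, µm
    n_depths: int = 21
    pupil_grid: int = 128               # samples across the pupil diameter (height-map export)
    fft_grid: int = 512                 # FFT grid for PSF synthesis
    psf_support: int = 128              # cropped PSF patch side, px
    image_grid: int = 256               # sensor-plane samples
    pixel_pitch: float = 0.3            # object-space µm per pixel
    read_noise_sigma: float = 0.01      # Gaussian std on the [0,1] intensity scale
    defocus_model: str = "paraxial-NA"  # or "exact-z0"

    def __post_init__(self) -> None:
        lam = tuple(float(w) for w in self.wavelengths)
        if len(lam) != 2 or min(lam) <= 0 or lam[0] == lam[1]:
            raise ValueError("wavelengths must be two distinct positive values (nm)")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.dof_range <= 0:
            raise ValueError("dof_range must be > 0")
        if self.n_depths < 1 or self.n_depths % 2 == 0:
            raise ValueError("n_depths must be >= 1 and odd (z = z0 must be a plane)")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")
        if self.defocus_model not in ("paraxial-NA", "exact-z0"):
            raise ValueError(f"unknown defocus_model {self.defocus_model!r}")
        if self.defocus_model == "exact-z0" and self.in_focus_depth == 0:
            raise ValueError("exact-z0 defocus model requires z0 != 0")
        if self.psf_support > self.fft_grid:
            raise ValueError("psf_support cannot exceed fft_grid")

    @property
    def depth_grid(self) -> np.ndarray:
        """Depth planes, µm, evenly spaced and symmetric about z0."""
        half = self.dof_range / 2.0
        return self.in_focus_depth + np.linspace(-half, half, self.n_depths)

    def wavelength_um(self, channel: int) -> float:
        return self.wavelengths[channel] * 1e-3

    def channel_of(self, wavelength_nm: float) -> int:
        for i, w in enumerate(self.wavelengths):
            if abs(w - wavelength_nm) < 1e-6:
                return i
        raise ValueError(
            f"wavelength {wavelength_nm} nm is not configured (have {self.wavelengths})"
        )


def pupil_coords(cfg: OpticalConfig, wavelength_nm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized pupil coordinates (rho, theta, aperture) on the FFT grid.

    The FFT grid spans spatial frequencies with spacing 1/(N * pitch); the
    coherent cutoff NA/λ maps to rho = 1.
    """
    lam_um = wavelength_nm * 1e-3
    n = cfg.fft_grid
    f = np.fft.fftshift(np.fft.fftfreq(n, d=cfg.pixel_pitch))
    fx, fy = np.meshgrid(f, f)
    fc = cfg.numerical_aperture / lam_um  # coherent cutoff, cycles/µm
    rho = np.hypot(fx, fy) / fc
    theta = np.arctan2(fy, fx)
    radius_px = fc / (f[1] - f[0])
    if radius_px < 8:
        raise ValueError(
            f"pupil sampled with radius {radius_px:.1f} px on the FFT grid; "
            "increase fft_grid or pixel_pitch"
        )
    return rho, theta, rho <= 1.0


@dataclass
class PhaseMask:
    """Phase mask parameterized by 55 Zernike coefficients of its height map (µm).

    The per-wavelength pupil phase is 2π (n(λ) − 1) h / λ, with the material
    index n(λ) given by a two-term Cauchy dispersion (fused-silica-like by
    default), so phase maps at the two wavelengths differ only by a scalar
    factor for a fixed height map.
    """

    zernike_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(N_ZERNIKE))
    cauchy: tuple[float, float] = (1.4580, 0.00354)  # n(λ) = A + B/λ², λ in µm

    def __post_init__(self) -> None:
        self.zernike_coeffs = np.asarray(self.zernike_coeffs, dtype=float)
        if self.zernike_coeffs.shape != (N_ZERNIKE,):
            raise ValueError(f"expected {N_ZERNIKE} Zernike coefficients")

    def refractive_index(self, wavelength_nm: float) -> float:
        lam_um = wavelength_nm * 1e-3
        a, b = self.cauchy
        return a + b / lam_um**2

    def height_map(self, grid: int | None = None,
                   rho: np.ndarray | None = None,
                   theta: np.ndarray | None = None) -> np.ndarray:
        """Height map in µm, zero outside the aperture."""
        if rho is None or theta is None:
            rho, theta, _ = unit_disk_grid(grid or 128)
        h = np.zeros_like(rho)
        for j, c in enumerate(self.zernike_coeffs):
            if c != 0.0:
                h += c * zernike_mode(j, rho, theta)
        h[rho > 1.0] = 0.0
        return h

    def phase_scale(self, wavelength_nm: float) -> float:
        """rad of pupil phase per µm of height at this wavelength."""
        lam_um = wavelength_nm * 1e-3
        return 2.0 * np.pi * (self.refractive_index(wavelength_nm) - 1.0) / lam_um


@dataclass
class PupilPhase:
    """Total pupil phase (rad) split into defocus and mask components."""

    defocus: np.ndarray
    mask: np.ndarray
    aperture: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.defocus + self.mask


@dataclass
class PSFStack:
    """Energy-normalized PSFs indexed (channel, depth, y, x)."""

    values: np.ndarray
    depth_grid: np.ndarray
    wavelengths: tuple[float, float]
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("PSFStack values must be (channel, depth, y, x)")
        if self.values.shape[1] != self.depth_grid.size:
            raise ValueError("depth axis does not match depth grid")
        if np.any(self.values < 0):
            raise ValueError("PSF values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_depths(self) -> int:
        return self.values.shape[1]

    def slice(self, channel: int, depth: float) -> np.ndarray:
        idx = self.depth_index(depth)
        return self.values[channel, idx]

    def depth_index(self, depth: float) -> int:
        d = np.abs(self.depth_grid - depth)
        idx = int(np.argmin(d))
        if d[idx] > 1e-6:
            raise ValueError(f"depth {depth} µm not in PSF depth grid")
        return idx


@dataclass
class SceneSample:
    """Two-channel scene intensities in [0,1], one plane per occupied depth."""

    planes: np.ndarray  # (n_planes, 2, H, W)
    depths: np.ndarray  # (n_planes,), µm

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        if self.planes.ndim == 3:
            self.planes = self.planes[None]
        if self.planes.ndim != 4 or self.planes.shape[1] != 2:
            raise ValueError("planes must be (n_planes, 2, H, W)")
        if self.planes.shape[0] != self.depths.size:
            raise ValueError("one depth label per plane required")
        if self.planes.min() < 0 or self.planes.max() > 1 + 1e-9:
            raise ValueError("scene intensities must lie in [0, 1]")


@dataclass
class SensorImage:
    """Blurred two-channel sensor-plane image."""

    values: np.ndarray  # (2, H, W)
    noise_applied: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 2:
            raise ValueError("SensorImage values must be (2, H, W)")


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def path_length_error(cfg: OpticalConfig, z: float) -> float:
    """Maximum defocus path-length error W_m (µm) at the pupil edge for depth z."""
    z0 = cfg.in_focus_depth
    if cfg.defocus_model == "exact-z0":
        if z0 == 0:
            raise ValueError("exact-z0 defocus model requires z0 != 0")
        return (cfg.pupil_radius**2 / 2.0) * (z0 - z) / z0**2
    return (cfg.numerical_aperture**2 / 2.0) * (z0 - z)


def defocus_phase(cfg: OpticalConfig, z: float, wavelength_nm: float,
                  rho: np.ndarray | None = None) -> np.ndarray:
    """Defocus pupil phase (rad): (2π/λ) W_m ρ², zero outside the aperture.

    ``rho`` is the normalized pupil radius grid; defaults to the config's
    FFT-grid pupil coordinates at this wavelength.
    """
    cfg.channel_of(wavelength_nm)
    half = cfg.dof_range / 2.0
    if not (cfg.in_focus_depth - half - 1e-9 <= z <= cfg.in_focus_depth + half + 1e-9):
        raise ValueError(f"depth {z} µm outside the configured DOF")
    if rho is None:
        rho, _, _ = pupil_coords(cfg, wavelength_nm)
    lam_um = wavelength_nm * 1e-3
    wm = path_length_error(cfg, z)
    phi = (2.0 * np.pi / lam_um) * wm * rho**2
    phi = np.where(rho <= 1.0, phi, 0.0)
    return phi


def mask_phase(mask: PhaseMask, wavelength_nm: float,
               rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Depth-independent mask pupil phase (rad) on the given pupil coordinates."""
    h = mask.height_map(rho=rho, theta=theta)
    return mask.phase_scale(wavelength_nm) * h


def mask_phase_basis(mask: PhaseMask, wavelength_nm: float,
                     rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-coefficient phase basis (rad per µm of coefficient), shape (55, ...)."""
    scale = mask.phase_scale(wavelength_nm)
    basis = np.stack([zernike_mode(j, rho, theta) for j in range(N_ZERNIKE)])
    basis[:, rho > 1.0] = 0.0
    return scale * basis


def pupil_phase(cfg: OpticalConfig, mask: PhaseMask, z: float,
                wavelength_nm: float) -> PupilPhase:
    """Total pupil phase at depth z: defocus plus mask components (additive)."""
    rho, theta, aperture = pupil_coords(cfg, wavelength_nm)
    dphi = defocus_phase(cfg, z, wavelength_nm, rho=rho)
    mphi = mask_phase(mask, wavelength_nm, rho, theta)
    return PupilPhase(defocus=dphi, mask=mphi, aperture=aperture)


def psf_from_phase(total_phase: np.ndarray, aperture: np.ndarray,
                   support: int) -> np.ndarray:
    """Intensity PSF |F{A e^{iΦ}}|², cropped to ``support`` and unit-sum."""
    pupil = aperture * np.exp(1j * total_phase)
    apsf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil)))
    psf = np.abs(apsf) ** 2
    n = psf.shape[0]
    c = n // 2
    s = support
    patch = psf[c - s // 2: c - s // 2 + s, c - s // 2: c - s // 2 + s]
    tot = patch.sum()
    if tot <= 0:
        raise ValueError("degenerate pupil: zero PSF energy")
    return patch / tot


def _check_sampling(phase: np.ndarray, aperture: np.ndarray) -> None:
    # aliasing guard: per-pixel phase step inside the aperture must stay < pi
    inner = aperture.copy()
    gx = np.abs(np.diff(phase, axis=1))[inner[:, 1:] & inner[:, :-1]]
    gy = np.abs(np.diff(phase, axis=0))[inner[1:, :] & inner[:-1, :]]
    gmax = max(gx.max(initial=0.0), gy.max(initial=0.0))
    if gmax > np.pi:
        warnings.warn(
            f"pupil phase gradient {gmax:.2f} rad/px exceeds π; PSF may alias "
            "(increase fft_grid)", RuntimeWarning, stacklevel=3)


def compute_psf(cfg: OpticalConfig, mask: PhaseMask | None = None) -> PSFStack:
    """PSF stack over both channels and the configured depth grid."""
    mask = mask or PhaseMask()
    depths = cfg.depth_grid
    out = np.empty((2, depths.size, cfg.psf_support, cfg.psf_support))
    for ch, lam in enumerate(cfg.wavelengths):
        rho, theta, aperture = pupil_coords(cfg, lam)
        mphi = mask_phase(mask, lam, rho, theta)
        for di, z in enumerate(depths):
            phi = defocus_phase(cfg, z, lam, rho=rho) + mphi
            if di == 0:
                _check_sampling(phi, aperture)
            out[ch, di] = psf_from_phase(phi, aperture, cfg.psf_support)
    return PSFStack(values=out, depth_grid=depths,
                    wavelengths=tuple(cfg.wavelengths), pixel_pitch=cfg.pixel_pitch)


def embed_kernel(psf: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed a centered PSF patch into an image-shaped periodic kernel (DC at [0,0])."""
    s = psf.shape[0]
    h, w = shape
    if s > h or s > w:
        raise ValueError(f"PSF support {s} exceeds image shape {shape}")
    k = np.zeros(shape)
    top, left = (h - s) // 2, (w - s) // 2
    k[top:top + s, left:left + s] = psf
    # patch center s//2 must land on [0,0] after the shift
    return np.roll(k, (-(top + s // 2), -(left + s // 2)), axis=(0, 1))


def fftconv_same(img: np.ndarray, psf: np.ndarray, boundary: str = "periodic") -> np.ndarray:
    """Convolve a 2-D image with a centered PSF patch, keeping the image shape."""
    if boundary == "reflect":
        p = psf.shape[0] // 2
        padded = np.pad(img, p, mode="reflect")
        out = fftconv_same(padded, psf, boundary="periodic")
        return out[p:p + img.shape[0], p:p + img.shape[1]]
    if boundary != "periodic":
        raise ValueError(f"unknown boundary {boundary!r}")
    k = embed_kernel(psf, img.shape)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * np.fft.fft2(k)))


def form_image(scene: SceneSample, psfs: PSFStack, boundary: str = "periodic") -> SensorImage:
    """Blur a scene: per channel, sum over depths of scene-plane ⊛ PSF(depth).

    Linear in the scene; no noise applied.  Scene depth labels must match
    PSF depth-grid entries exactly (1e-6 µm tolerance).
    """
    h, w = scene.planes.shape[2:]
    out = np.zeros((2, h, w))
    for plane, z in zip(scene.planes, scene.depths):
        for ch in range(2):
            out[ch] += fftconv_same(plane[ch], psfs.slice(ch, z), boundary=boundary)
    return SensorImage(values=out, noise_applied=False)


def add_read_noise(img: SensorImage, sigma: float | None = None,
                   seed: int | None = None) -> SensorImage:
    """Add i.i.d. Gaussian read noise on the [0,1] scale, then clip to [0,1]."""
    if sigma is None:
        sigma = 0.01
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return SensorImage(values=img.values.copy(), noise_applied=True, seed=seed)
    rng = np.random.default_rng(seed)
    noisy = img.values + rng.normal(0.0, sigma, size=img.values.shape)
    return SensorImage(values=np.clip(noisy, 0.0, 1.0), noise_applied=True, seed=seed)


def toy_optics(**overrides) -> OpticalConfig:
    """CPU-scale simulation profile: coarser pitch (0.6 µm/px), 384-pt FFT
    grid, 64-px PSF support, 64-px sensor patches.  Same physics, smaller
    arrays; 0.6 µm/px still samples 2.46 µm bar targets at ~4 px per line,
    and the 384-pt grid keeps learned-mask phase gradients below the
    aliasing limit."""
    kw = dict(pixel_pitch=0.6, fft_grid=384, psf_support=64, image_grid=64)
    kw.update(overrides)
    return OpticalConfig(**kw)


def cubic_mask(alpha: float = 20.0, wavelength_nm: float = 473.0,
               fit_grid: int = 128) -> PhaseMask:
    """Cubic phase mask h ∝ x³ + y³ expressed in the 55-coefficient Zernike basis.

    ``alpha`` is the design pupil phase (rad) of each cubic term at the pupil
    edge (x = 1) at ``wavelength_nm``.  The cubic field is fitted to the basis
    by least squares over the discrete disk; a pure cubic lies in radial
    orders <= 3 so the truncation residual is at the quadrature level.
    """
    ref = PhaseMask()
    h0 = alpha / ref.phase_scale(wavelength_nm)  # µm of height per cubic term
    rho, theta, inside = unit_disk_grid(fit_grid)
    x = rho * np.cos(theta)
    y = rho * np.sin(theta)
    target = h0 * (x**3 + y**3)
    basis = zernike_basis(N_ZERNIKE, fit_grid)
    a = basis[:, inside].T
    coeffs, *_ = np.linalg.lstsq(a, target[inside], rcond=None)
    return PhaseMask(zernike_coeffs=coeffs)
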