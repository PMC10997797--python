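"""Synthetic fixtures and phantoms: feature textures, channel pairing,
augmentation, three-bar resolution targets, bead calibration stacks, and
nuclei/cytoplasm tissue phantoms.

Every generator is seed-deterministic, emits values in [0,1], and returns
ground truth alongside the data, so each pipeline stage is testable with no
instrument and no downloads.  The feature-image pool stands in for the
mixed training corpus the real system uses (histology plus natural
images): multi-scale filtered noise and blob fields provide a comparable
spread of spatial frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize

from .calibration import BeadStack
from .images import TwoChannelImage
from .optics import OpticalConfig, PSFStack, fftconv_same

__all__ = ["PhantomSpec", "AugmentSpec", "BarTarget", "feature_pool",
           "pair_channels", "augment", "gen_bars", "gen_bead_stack",
           "gen_nuclei_scene", "gen_he_scene"]


@dataclass
class PhantomSpec:
    """Geometry of a nuclei-plus-cytoplasm tissue phantom."""

    size: int = 192                 # canvas side, px
    n_nuclei: int = 25
    nucleus_radius: float = 6.0     # mean semi-axis, px
    radius_jitter: float = 0.2      # relative spread of semi-axes
    max_eccentricity: float = 0.6
    edge_softness: float = 1.5      # px of soft falloff at the nuclear rim
    nuclear_amplitude: tuple[float, float] = (0.7, 1.0)
    cyto_range: tuple[float, float] = (0.15, 0.55)
    cyto_scale: float = 12.0        # correlation length of cytoplasm texture, px
    min_separation: float = 4.0     # extra clearance between nuclei, px
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size, self.n_nuclei) < 1 or self.nucleus_radius <= 0 \
                or self.cyto_scale <= 0 or self.edge_softness <= 0:
            raise ValueError("all geometric parameters must be > 0")


# --------------------------------------------------------------------------- #
# feature pool and channel pairing
# --------------------------------------------------------------------------- #

def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

def feature_pool(n: int, size: int, seed: int = 0,
                 sigma_range: tuple[float, float] = (0.6, 4.0),
                 blobs: bool = True) -> np.ndarray:
    """Pool of grayscale feature images: filtered noise across scales plus
    occasional blob fields; shape (n, size, size), values in [0,1].

    ``sigma_range`` sets the correlation scale (px) of the filtered noise.
    ``blobs=False`` with a narrow fine-scale range (e.g. (1.5, 3.5) at
    0.3 µm/px) produces purely high-frequency textures, the scene class
    used for defocus-collapse sweeps.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n, size, size))
    for i in range(n):
        sigma = float(rng.uniform(*sigma_range))
        img = ndi.gaussian_filter(rng.uniform(size=(size, size)), sigma)
        if blobs and rng.uniform() < 0.4:    # sprinkle blob features
            field = np.zeros((size, size))
            for _ in range(rng.integers(5, 20)):
                cy, cx = rng.uniform(0, size, 2)
                r = rng.uniform(2.0, size / 10.0)
                yy, xx = np.ogrid[:size, :size]
                field += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2)))
            img = img + 0.8 * _normalize(field)
        out[i] = _normalize(img)
    return out


def pair_channels(pool: np.ndarray, seed: int = 0, n_samples: int | None = None):
    """Yield two-channel scenes by pairing two *different* pool images.

    Drawing distinct images per sample removes cross-channel correlation by
    construction (the two fluorescence channels of the real system carry
    independent content).  Infinite generator unless ``n_samples`` is given.
    """
    pool = np.asarray(pool, dtype=float)
    if len(pool) < 2:
        raise ValueError("need a pool of at least 2 images to pair channels")
    rng = np.random.default_rng(seed)
    produced = 0
    while n_samples is None or produced < n_samples:
        i, j = rng.choice(len(pool), size=2, replace=False)
        yield TwoChannelImage(values=np.stack([pool[i], pool[j]]))
        produced += 1


# --------------------------------------------------------------------------- #
# augmentation
# --------------------------------------------------------------------------- #

@dataclass
class AugmentSpec:
    """Random crop (side uniform in [crop_min, crop_max], resized to
    out_size), right-angle rotation, flips, multiplicative brightness."""

    crop_min: int = 256
    crop_max: int = 326
    out_size: int = 256
    rotate: bool = True
    flip: bool = True
    brightness: tuple[float, float] = (0.7, 1.3)

    @classmethod
    def identity(cls, size: int) -> "AugmentSpec":
        return cls(crop_min=size, crop_max=size, out_size=size,
                   rotate=False, flip=False, brightness=(1.0, 1.0))


def augment(img: np.ndarray, spec: AugmentSpec, seed: int = 0) -> np.ndarray:
    """Apply the augmentation spec to a (H, W) or (C, H, W) image; seeded."""
    arr = np.asarray(img, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    h, w = arr.shape[1:]
    if h < spec.crop_min or w < spec.crop_min:
        raise ValueError(f"image {h}x{w} smaller than minimum crop {spec.crop_min}")
    rng = np.random.default_rng(seed)
    side = int(rng.integers(spec.crop_min, min(spec.crop_max, h, w) + 1))
    top = int(rng.integers(0, h - side + 1))
    left = int(rng.integers(0, w - side + 1))
    out = arr[:, top:top + side, left:left + side]
    if side != spec.out_size:
        out = np.stack([resize(c, (spec.out_size, spec.out_size),
                               anti_aliasing=side > spec.out_size) for c in out])
    if spec.rotate:
        out = np.rot90(out, k=int(rng.integers(4)), axes=(1, 2))
    if spec.flip:
        if rng.uniform() < 0.5:
            out = out[:, ::-1, :]
        if rng.uniform() < 0.5:
            out = out[:, :, ::-1]
    lo, hi = spec.brightness
    out = np.clip(out * rng.uniform(lo, hi), 0.0, 1.0)
    out = np.ascontiguousarray(out)
    return out[0] if squeeze else out


# --------------------------------------------------------------------------- #
# resolution targets
# --------------------------------------------------------------------------- #

@dataclass
class BarTarget:
    """Negative three-bar target (bright bars on dark) in both orientations.

    ``bar_centers``/``gap_centers`` hold pixel coordinates along the
    modulation axis of each orientation, for contrast profiling; ``rows``
    is the slice across the bar length over which profiles are averaged.
    """

    image: np.ndarray
    line_width_um: float
    pixel_pitch: float
    geometry: dict


def _render_bars_1d(canvas: np.ndarray, x0: float, y0: float, wpx: float,
                    lpx: float, vertical: bool) -> tuple[list, list]:
    """Three bars (width wpx, gap wpx, length lpx) with antialiased edges."""
    h, w = canvas.shape
    yy, xx = np.mgrid[:h, :w].astype(float)
    centers, gaps = [], []
    for b in range(3):
        start = x0 + 2 * b * wpx
        if vertical:   # bars run along y, modulate along x
            inside = (np.clip(np.minimum(xx + 0.5 - start, start + wpx - (xx - 0.5)) / 1.0, 0, 1)
                      * ((yy >= y0) & (yy < y0 + lpx)))
        else:
            inside = (np.clip(np.minimum(yy + 0.5 - start, start + wpx - (yy - 0.5)) / 1.0, 0, 1)
                      * ((xx >= y0) & (xx < y0 + lpx)))
        np.maximum(canvas, inside, out=canvas)
        centers.append(start + wpx / 2.0)
        if b < 2:
            gaps.append(start + 1.5 * wpx)
    return centers, gaps


def gen_bars(line_width: float, cfg: OpticalConfig, canvas: int | None = None) -> BarTarget:
    """USAF-style three-bar group at ``line_width`` µm (bar = gap = width,
    length 5x width), both orientations, unit amplitude on dark background."""
    pitch = cfg.pixel_pitch
    wpx = line_width / pitch
    if wpx < 2.0:
        raise ValueError(
            f"line width {line_width} µm is {wpx:.2f} px at {pitch} µm/px; "
            "need >= 2 px (use a finer pixel pitch)")
    lpx = 5.0 * wpx
    group_w = 5.0 * wpx          # 3 bars + 2 gaps
    margin = max(8, int(2 * wpx))
    required = int(np.ceil(group_w + lpx + 4 * margin))
    if canvas is None:
        canvas = required
    elif canvas < required:
        raise ValueError(f"canvas {canvas} px too small for {line_width} µm "
                         f"bars at {pitch} µm/px (need >= {required})")
    img = np.zeros((canvas, canvas))
    # vertical-bar group (modulation along x), upper-left
    vx0, vy0 = float(margin), float(margin)
    v_centers, v_gaps = _render_bars_1d(img, vx0, vy0, wpx, lpx, vertical=True)
    # horizontal-bar group (modulation along y), lower-right
    hx0 = margin + group_w + margin
    h_centers, h_gaps = _render_bars_1d(img, hx0, hx0, wpx, lpx, vertical=False)
    geometry = {
        "vertical": {"bar_centers": v_centers, "gap_centers": v_gaps,
                     "rows": (int(vy0 + 0.2 * lpx), int(vy0 + 0.8 * lpx))},
        "horizontal": {"bar_centers": h_centers, "gap_centers": h_gaps,
                       "rows": (int(hx0 + 0.2 * lpx), int(hx0 + 0.8 * lpx))},
    }
    return BarTarget(image=img, line_width_um=line_width, pixel_pitch=pitch,
                     geometry=geometry)


# --------------------------------------------------------------------------- #
# bead stacks
# --------------------------------------------------------------------------- #

def gen_bead_stack(density: float, diameter: float, psfs: PSFStack,
                   noise_sigma: float = 0.005, seed: int = 0,
                   repeats: int = 5, fov: int = 256,
                   amplitude: float = 1.0, background: float = 0.0) -> tuple[BeadStack, np.ndarray]:
    """Simulate a dilute fluorescent-bead monolayer imaged through a PSF stack.

    ``density`` is beads per (100 px)²; ``diameter`` is the physical bead
    size in µm (default use: 1 µm beads), rendered as an antialiased disk.
    Every depth images the *same* bead field through that depth's PSF, and
    each of ``repeats`` frames gets independent Gaussian noise.  Returns the
    stack and the ground-truth bead centers (n, 2) in (y, x) pixels.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    rng = np.random.default_rng(seed)
    n_beads = max(1, int(round(density * (fov / 100.0) ** 2))) if density > 0 else 0
    centers = rng.uniform(psfs.values.shape[-1] // 2,
                          fov - psfs.values.shape[-1] // 2,
                          size=(n_beads, 2)) if n_beads else np.empty((0, 2))
    field = np.full((fov, fov), background)
    r = max(diameter / psfs.pixel_pitch / 2.0, 0.5)
    yy, xx = np.mgrid[:fov, :fov].astype(float)
    for cy, cx in centers:
        d = np.hypot(yy - cy, xx - cx)
        field += amplitude * np.clip(r + 0.5 - d, 0.0, 1.0)
    frames = np.empty((psfs.n_depths, repeats, psfs.n_channels, fov, fov))
    for di in range(psfs.n_depths):
        for ch in range(psfs.n_channels):
            clean = fftconv_same(field, psfs.values[ch, di])
            for rep in range(repeats):
                noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
                frames[di, rep, ch] = np.clip(noisy, 0.0, None)
    stack = BeadStack(frames=frames, depth_grid=psfs.depth_grid.copy())
    return stack, centers


# --------------------------------------------------------------------------- #
# tissue phantoms
# --------------------------------------------------------------------------- #

def gen_nuclei_scene(spec: PhantomSpec) -> tuple[TwoChannelImage, list[dict]]:
    """Nuclei-plus-cytoplasm phantom with exact ground truth.

    Nuclear channel: non-overlapping soft-edged elliptical blobs.
    Cytoplasm channel: correlated low-frequency texture, attenuated inside
    nuclei.  Returns the scene and one record per nucleus with center
    (y, x), semi-axes, orientation and analytic area (px²).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    nuclei: list[dict] = []
    attempts, max_attempts = 0, 200 * spec.n_nuclei
    while len(nuclei) < spec.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in "
                f"{size}x{size} px after {max_attempts} attempts")
        a = spec.nucleus_radius * (1 + spec.radius_jitter * rng.uniform(-1, 1))
        ecc = rng.uniform(0.0, spec.max_eccentricity)
        b = a * np.sqrt(1 - ecc**2)
        theta = rng.uniform(0, np.pi)
        margin = a + spec.edge_softness + 1
        cy, cx = rng.uniform(margin, size - margin, size=2)
        rmax = a + spec.edge_softness
        if any(np.hypot(cy - n["center"][0], cx - n["center"][1])
               < rmax + n["rmax"] + spec.min_separation for n in nuclei):
            continue
        nuclei.append({"center": (cy, cx), "axes": (a, b), "theta": theta,
                       "rmax": rmax, "area_px": np.pi * a * b,
                       "amplitude": rng.uniform(*spec.nuclear_amplitude)})
    yy, xx = np.mgrid[:size, :size].astype(float)
    nuc = np.zeros((size, size))
    for n in nuclei:
        cy, cx = n["center"]
        a, b = n["axes"]
        ct, st = np.cos(n["theta"]), np.sin(n["theta"])
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        # soft rim: full amplitude inside, linear falloff over edge_softness
        soft = np.clip((1.0 + spec.edge_softness / a - rho) * (a / spec.edge_softness), 0.0, 1.0)
        nuc = np.maximum(nuc, n["amplitude"] * soft)
    lo, hi = spec.cyto_range
    cyto = ndi.gaussian_filter(rng.uniform(size=(size, size)), spec.cyto_scale / 3.0)
    cyto = lo + (hi - lo) * _normalize(cyto)
    cyto = cyto * (1.0 - 0.8 * (nuc > 0.05))
    scene = np.clip(np.stack([nuc, cyto]), 0.0, 1.0)
    return TwoChannelImage(values=scene), nuclei


def gen_he_scene(spec: PhantomSpec, stain_params=None) -> tuple[np.ndarray, list[dict]]:
    """H&E-appearance RGB phantom: Beer-Lambert rendering of a nuclei scene.

    Serves as the stand-in for the real stained-slide domain in unpaired
    stain-transfer training.  Returns ((3, H, W) array in [0,1], nuclei
    ground truth).
    """
    from .beer_lambert import bl_render
    scene, nuclei = gen_nuclei_scene(spec)
    return bl_render(scene, stain_params).values, nuclei
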