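"""Bead-stack PSF calibration: frame averaging, background subtraction,
bead extraction, and selection of the target depth planes.

Mirrors the one-time instrument calibration: a dilute monolayer of 1 µm
fluorescent beads is imaged at 31 depths at 10 µm intervals, five frames
per depth are averaged, background is subtracted, and the 21 depths
covering the target DOF are kept to fine-tune the reconstruction networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .optics import PSFStack

__all__ = ["BeadStack", "MeasuredPSF", "average_frames", "subtract_background",
           "extract_psf", "select_depths"]

DEFAULT_REPEATS = 5  # frames averaged per depth


@dataclass
class BeadStack:
    """Raw bead frames indexed (depth, repeat, channel, y, x)."""

    frames: np.ndarray
    depth_grid: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.frames.ndim != 5:
            raise ValueError("frames must be (depth, repeat, channel, y, x)")
        if self.frames.shape[0] != self.depth_grid.size:
            raise ValueError("depth axis does not match depth grid")
        if self.frames.shape[1] < 1:
            raise ValueError("need >= 1 repeat per depth")
        if self.depth_grid.size > 1:
            steps = np.diff(self.depth_grid)
            if not np.allclose(steps, steps[0]):
                raise ValueError("depth spacing must be uniform")
        if self.frames.min() < -1e-9:
            raise ValueError("bead frames must be non-negative")
        self.frames = np.clip(self.frames, 0.0, None)

    @property
    def n_depths(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[2]


@dataclass
class MeasuredPSF:
    """Background-subtracted, unit-sum PSF patches per (channel, depth)."""

    values: np.ndarray       # (channel, depth, patch, patch)
    depth_grid: np.ndarray
    bead_positions: np.ndarray  # (channel, depth, 2) int pixel (y, x)

    def to_psfstack(self, wavelengths=(473.0, 640.0), pixel_pitch: float = 0.3) -> PSFStack:
        return PSFStack(values=self.values, depth_grid=self.depth_grid,
                        wavelengths=tuple(wavelengths), pixel_pitch=pixel_pitch)


def average_frames(stack: BeadStack) -> BeadStack:
    """Temporal mean over the repeat axis; returns a stack with repeats = 1.

    Averaging n i.i.d.-noise frames reduces the noise variance by 1/n.
    """
    mean = stack.frames.mean(axis=1, keepdims=True)
    return BeadStack(frames=mean, depth_grid=stack.depth_grid.copy())


def subtract_background(frame: np.ndarray, method: str = "constant",
                        percentile: float = 5.0) -> np.ndarray:
    """Remove a background estimate; negatives clamp to 0.

    ``constant``: subtract the image-wide ``percentile`` value (default 5th
    percentile, robust to sparse bright beads).  ``percentile``: subtract a
    local percentile background computed in coarse blocks.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if method == "constant":
        bg = np.percentile(frame, percentile)
    elif method == "percentile":
        block = max(frame.shape[0] // 8, 8)
        bg = ndi.percentile_filter(frame, percentile, size=block)
        bg = ndi.uniform_filter(bg, size=block // 2)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(frame - bg, 0.0, None)


def _detect_beads(img: np.ndarray, threshold_sigmas: float = 5.0,
                  merge_radius: int = 16) -> list[dict]:
    """Detect bead images as bright connected components.

    The frame is lightly smoothed, thresholded at mean + k·σ, and labeled;
    fragments closer than ``merge_radius`` (side lobes of one defocused or
    wavefront-coded PSF) are merged into a single bead.  Returns beads
    sorted by integrated brightness, each with the location of its
    brightest pixel.
    """
    sm = ndi.gaussian_filter(img, 2.0)
    thr = sm.mean() + threshold_sigmas * sm.std()
    mask = ndi.binary_dilation(sm > thr, iterations=3)
    labels, n = ndi.label(mask)
    if n == 0:
        return []
    comps = []
    for lab in range(1, n + 1):
        sel = labels == lab
        peak = np.unravel_index(np.argmax(np.where(sel, sm, -np.inf)), sm.shape)
        comps.append({"peak": peak, "flux": float(img[sel].sum())})
    comps.sort(key=lambda c: -c["flux"])
    beads: list[dict] = []
    for c in comps:
        for b in beads:
            if np.hypot(c["peak"][0] - b["peak"][0],
                        c["peak"][1] - b["peak"][1]) < merge_radius:
                b["flux"] += c["flux"]
                break
        else:
            beads.append(dict(c))
    beads.sort(key=lambda c: -c["flux"])
    return beads


def extract_psf(stack: BeadStack, patch: int = 64,
                threshold_sigmas: float = 5.0) -> MeasuredPSF:
    """Locate the brightest isolated bead per (channel, depth) and crop it.

    The candidate peak must be at least ``patch`` px away from any other
    detected bead (isolation rejection) and a full patch away from the
    frame edge.  Patches are clamped non-negative and normalized to unit
    sum.  Raises per-depth if no acceptable bead is found.
    """
    averaged = average_frames(stack)
    n_d, _, n_c, h, w = averaged.frames.shape
    values = np.empty((n_c, n_d, patch, patch))
    positions = np.empty((n_c, n_d, 2), dtype=int)
    half = patch // 2
    for ch in range(n_c):
        for di in range(n_d):
            img = subtract_background(averaged.frames[di, 0, ch])
            beads = _detect_beads(img, threshold_sigmas, merge_radius=patch // 4)
            if not beads:
                raise ValueError(
                    f"no bead above detection threshold at depth index {di}, "
                    f"channel {ch}")
            chosen = None
            for bi, bead in enumerate(beads):
                cy, cx = bead["peak"]
                others = [b["peak"] for j, b in enumerate(beads) if j != bi]
                if others and min(np.hypot(cy - oy, cx - ox)
                                  for oy, ox in others) < patch:
                    continue  # another bead inside the crop window
                if not (half <= cy < h - half and half <= cx < w - half):
                    continue
                chosen = (int(cy), int(cx))
                break
            if chosen is None:
                raise ValueError(
                    f"no isolated bead at depth index {di}, channel {ch} "
                    f"(isolation window {patch} px)")
            cy, cx = chosen
            p = img[cy - half:cy + half, cx - half:cx + half]
            tot = p.sum()
            if tot <= 0:
                raise ValueError(f"zero-energy bead patch at depth index {di}")
            values[ch, di] = p / tot
            positions[ch, di] = (cy, cx)
    return MeasuredPSF(values=values, depth_grid=averaged.depth_grid.copy(),
                       bead_positions=positions)


def select_depths(measured: MeasuredPSF, target_grid: np.ndarray,
                  wavelengths=(473.0, 640.0), pixel_pitch: float = 0.3) -> PSFStack:
    """Keep the measured slices whose depths match the target DOF grid.

    Typical use: 31 measured depths at 10 µm spacing -> the 21 central
    planes covering a 200 µm DOF.  A target depth absent from the measured
    grid raises, naming the unmatched depths.
    """
    target_grid = np.asarray(target_grid, dtype=float)
    indices, missing = [], []
    for z in target_grid:
        d = np.abs(measured.depth_grid - z)
        if d.min() > 1e-6:
            missing.append(float(z))
        else:
            indices.append(int(np.argmin(d)))
    if missing:
        raise ValueError(f"target depths not present in measured grid (µm): {missing}")
    return PSFStack(values=measured.values[:, indices], depth_grid=target_grid,
                    wavelengths=tuple(wavelengths), pixel_pitch=pixel_pitch)
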