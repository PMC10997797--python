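"""Configuration loading, stack I/O and format conventions.

Array stacks travel as multi-page 32-bit float TIFF, page order
channel-major then depth, with a JSON sidecar (same path, ``.json``
suffix) carrying the depth grid, wavelengths and pixel pitch.  RGB images
export to 8-bit PNG with the x255 convention.  Pixel indexing is
half-open, origin top-left, row-major (y, x) throughout the package.

Run configurations are YAML/JSON trees with one section per stage; unknown
keys are rejected and every loaded configuration carries a canonical
content hash so runs are reproducible from (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .beer_lambert import StainParams
from .cyclegan import GANConfig
from .optics import N_ZERNIKE, OpticalConfig, PhaseMask, PSFStack
from .recon import ReconNetConfig

__all__ = ["RunConfig", "load_config", "write_stack", "read_stack",
           "save_psfstack", "load_psfstack", "write_rgb_png", "read_rgb_png",
           "save_mask", "load_mask"]

SIDECAR_VERSION = 1


# --------------------------------------------------------------------------- #
# stacks
# --------------------------------------------------------------------------- #

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, values: np.ndarray, metadata: dict) -> None:
    """Write a (channel, depth, y, x) stack as float32 TIFF plus sidecar."""
    path = Path(path)
    values = np.asarray(values)
    if values.ndim != 4:
        raise ValueError("stack must be (channel, depth, y, x)")
    pages = values.reshape(-1, *values.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {"version": SIDECAR_VERSION,
            "shape": list(values.shape),
            **{k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in metadata.items()}}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack and its sidecar; raises cleanly on a missing sidecar."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # truncated/corrupt file: no partial object
        raise OSError(f"cannot read stack {path}: {exc}") from exc
    shape = tuple(meta["shape"])
    pages = np.asarray(pages, dtype=np.float64)
    if pages.size != np.prod(shape):
        raise OSError(f"stack {path} is truncated or corrupt: "
                      f"{pages.size} values, sidecar declares {shape}")
    return pages.reshape(shape), meta


def save_psfstack(path, psfs: PSFStack) -> None:
    write_stack(path, psfs.values,
                {"depth_grid": psfs.depth_grid,
                 "wavelengths": list(psfs.wavelengths),
                 "pixel_pitch": psfs.pixel_pitch})


def load_psfstack(path) -> PSFStack:
    values, meta = read_stack(path)
    return PSFStack(values=values, depth_grid=np.asarray(meta["depth_grid"]),
                    wavelengths=tuple(meta["wavelengths"]),
                    pixel_pitch=float(meta["pixel_pitch"]))


def write_rgb_png(path, rgb) -> None:
    """Export an RGBImage ([0,1] floats) as 8-bit PNG, x255 convention."""
    import imageio.v3 as iio
    iio.imwrite(Path(path), rgb.to_uint8())


def read_rgb_png(path) -> np.ndarray:
    """Read an RGB PNG back to a (3, H, W) float array in [0,1]."""
    import imageio.v3 as iio
    arr = np.asarray(iio.imread(Path(path)), dtype=np.float64) / 255.0
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path} is not an RGB image")
    return arr[:, :, :3].transpose(2, 0, 1)


# --------------------------------------------------------------------------- #
# phase-mask exchange
# --------------------------------------------------------------------------- #

def save_mask(path, mask: PhaseMask, grid: int = 128) -> None:
    """JSON with 55 named Zernike coefficients plus grid/material metadata."""
    payload = {
        "ordering": "osa-ansi",
        "units": "um",
        "grid": grid,
        "cauchy": list(mask.cauchy),
        "coefficients": {f"Z{j}": float(c) for j, c in enumerate(mask.zernike_coeffs)},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def export_height_map(path, mask: PhaseMask, grid: int = 128) -> None:
    """Write the mask height map (µm) as a single-page float32 TIFF."""
    tifffile.imwrite(Path(path), mask.height_map(grid).astype(np.float32))


def load_mask(path) -> PhaseMask:
    payload = json.loads(Path(path).read_text())
    coeffs = np.zeros(N_ZERNIKE)
    for name, val in payload["coefficients"].items():
        j = int(name[1:])
        coeffs[j] = float(val)
    return PhaseMask(zernike_coeffs=coeffs, cauchy=tuple(payload.get("cauchy", (1.4580, 0.00354))))


# --------------------------------------------------------------------------- #
# run configuration
# --------------------------------------------------------------------------- #

_SECTIONS = {
    "optics": OpticalConfig,
    "recon": ReconNetConfig,
    "gan": GANConfig,
    "stain": None,      # free-form: beta (2x3) + k
    "seed": None,
}


def _check_keys(tree: dict) -> None:
    unknown = [k for k in tree if k not in _SECTIONS]
    if unknown:
        raise ValueError(f"unknown configuration section(s): {unknown}")
    for section, cls in _SECTIONS.items():
        if cls is None or section not in tree:
            continue
        allowed = {f.name for f in fields(cls)}
        bad = [k for k in tree[section] if k not in allowed]
        if bad:
            raise ValueError(f"unknown key(s) in [{section}]: {bad}")


def _canonical_hash(tree: dict) -> str:
    blob = json.dumps(tree, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Validated configuration tree with a content hash for provenance."""

    tree: dict
    hash: str

    @property
    def seed(self) -> int:
        return int(self.tree.get("seed", 0))

    def optics(self) -> OpticalConfig:
        kw = dict(self.tree.get("optics", {}))
        if "wavelengths" in kw:
            kw["wavelengths"] = tuple(kw["wavelengths"])
        return OpticalConfig(**kw)

    def recon(self) -> ReconNetConfig:
        return ReconNetConfig(**self.tree.get("recon", {}))

    def gan(self) -> GANConfig:
        return GANConfig(**self.tree.get("gan", {}))

    def stain(self) -> StainParams:
        section = self.tree.get("stain")
        return StainParams.from_dict(section) if section else StainParams()


def load_config(path) -> RunConfig:
    """Load, validate, default and hash a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = yaml.safe_load(path.read_text()) or {}
    if not isinstance(tree, dict):
        raise ValueError(f"{path} does not contain a mapping")
    _check_keys(tree)
    cfg = RunConfig(tree=tree, hash=_canonical_hash(tree))
    # force validation of every provided section now, not at first use
    cfg.optics(), cfg.recon(), cfg.gan(), cfg.stain()
    return cfg
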