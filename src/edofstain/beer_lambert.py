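"""Beer-Lambert virtual H&E rendering of two-channel fluorescence images.

Each RGB channel M transmits T_M = exp(−Σ_i β_{M,i} I_i k), where I_i are
the dye intensity images (nuclear channel plays the hematoxylin role,
cytoplasmic channel the eosin role), β_{M,i} the channel-integrated
attenuations, and k a global scaling constant.  The transform is pointwise:
it introduces no spatial mixing, so in- and out-of-focus structure is
preserved exactly.

The default β matrix follows the published channel-integrated attenuation
values for hematoxylin and eosin from the virtual-transillumination
literature; it is configuration, not a calibrated constant, and can be
overridden per rendering or via a YAML stain file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import RGBImage, TwoChannelImage

__all__ = ["StainParams", "bl_transmission", "bl_render"]

# rows: dye (hematoxylin-role, eosin-role); columns: RGB
_DEFAULT_BETA = np.array([
    [0.860, 1.000, 0.300],   # hematoxylin: strong red/green attenuation -> blue-purple nuclei
    [0.050, 0.840, 0.544],   # eosin: mostly green/blue attenuation -> pink cytoplasm
])

DEFAULT_K = 2.5  # global scaling, chosen for images exported to the [0, 255] range


@dataclass
class StainParams:
    """Per-dye, per-RGB-channel attenuation matrix and global scaling."""

    beta: np.ndarray = field(default_factory=lambda: _DEFAULT_BETA.copy())
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[1] != 3:
            raise ValueError("beta must be (n_dyes, 3)")
        if np.any(self.beta < 0):
            raise ValueError("beta must be non-negative")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "StainParams":
        return cls(beta=np.asarray(d["beta"], dtype=float), k=float(d.get("k", DEFAULT_K)))

    def to_dict(self) -> dict:
        return {"beta": self.beta.tolist(), "k": float(self.k)}


def bl_transmission(dye_intensities, params: StainParams, channel: int) -> float:
    """Transmission of one RGB channel for given per-dye intensities.

    T_M = exp(−Σ_i β_{M,i} I_i k); multiplicative in dyes, 1 at zero dye.
    """
    inten = np.asarray(dye_intensities, dtype=float)
    if np.any(inten < 0):
        raise ValueError("dye intensities must be >= 0")
    if inten.shape[0] != params.beta.shape[0]:
        raise ValueError("one intensity per dye required")
    return float(np.exp(-(params.beta[:, channel] * inten * params.k).sum()))


def bl_render(img, params: StainParams | None = None) -> RGBImage:
    """Render a two-channel fluorescence image to RGB via the Beer-Lambert map.

    Accepts a TwoChannelImage or a (n_dyes, H, W) array in [0,1]; returns
    an RGBImage in [0,1] (x255 on 8-bit export).  Strictly decreasing in
    each dye intensity wherever the corresponding β is positive; all-zero
    input renders pure white.
    """
    params = params or StainParams()
    arr = img.values if isinstance(img, TwoChannelImage) else np.asarray(img, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n_dyes, H, W) input")
    if np.any(arr < 0):
        raise ValueError("dye intensities must be >= 0")
    if arr.shape[0] != params.beta.shape[0]:
        raise ValueError(
            f"{arr.shape[0]} dye planes but beta has {params.beta.shape[0]} rows")
    # optical density per RGB channel: OD_M = Σ_i β_{M,i} I_i k
    od = np.einsum("im,ihw->mhw", params.beta, arr) * params.k
    return RGBImage(values=np.exp(-od))
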