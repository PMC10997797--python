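"""Lightweight image containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TwoChannelImage", "RGBImage"]


@dataclass
class TwoChannelImage:
    """Co-registered nuclear (DAPI-like) and cytoplasmic (Rhodamine-B-like)
    intensity planes, values in [0,1], layout (2, H, W)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 2:
            raise ValueError("TwoChannelImage must be (2, H, W)")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def nuclear(self) -> np.ndarray:
        return self.values[0]

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.values[1]


@dataclass
class RGBImage:
    """Three-channel image in [0,1], layout (3, H, W); exported x255 to 8-bit."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 3:
            raise ValueError("RGBImage must be (3, H, W)")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("values must lie in [0, 1]")

    def to_uint8(self) -> np.ndarray:
        """(H, W, 3) uint8 using the x255 export convention, round-half-even."""
        scaled = np.rint(self.values * 255.0)  # numpy rint rounds half to even
        return np.clip(scaled, 0, 255).astype(np.uint8).transpose(1, 2, 0)
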