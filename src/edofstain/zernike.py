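"""Zernike polynomial basis on the unit disk (OSA/ANSI single-index ordering).

The phase-mask height map is parameterized by the first 55 Zernike modes,
i.e. all complete radial orders n = 0..9.  Modes are orthonormal with respect
to the continuous inner product (1/pi) * integral over the unit disk.
"""

from __future__ import annotations

from math import factorial, sqrt

import numpy as np

__all__ = ["osa_index_to_nm", "zernike_mode", "zernike_basis", "unit_disk_grid"]


def osa_index_to_nm(j: int) -> tuple[int, int]:
    """Map the OSA/ANSI single index j >= 0 to (radial order n, azimuthal m)."""
    if j < 0:
        raise ValueError(f"OSA index must be >= 0, got {j}")
    n = 0
    while (n + 1) * (n + 2) // 2 <= j:
        n += 1
    m = 2 * j - n * (n + 2)
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike_mode(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate orthonormal Zernike mode j on polar coordinates (rho, theta).

    Values outside the unit disk (rho > 1) are set to zero.
    """
    n, m = osa_index_to_nm(j)
    norm = sqrt(2.0 * (n + 1)) if m != 0 else sqrt(n + 1.0)
    r = _radial_poly(n, m, np.clip(rho, 0.0, 1.0))
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(theta)
    out = norm * r * ang
    out[rho > 1.0] = 0.0
    return out


def unit_disk_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Square grid of n x n samples spanning [-1, 1]^2; returns (rho, theta, mask)."""
    c = (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0)
    x, y = np.meshgrid(c, c)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return rho, theta, rho <= 1.0


def zernike_basis(n_modes: int, grid: int) -> np.ndarray:
    """Stack of ``n_modes`` Zernike modes sampled on a ``grid`` x ``grid`` square.

    Parameters
    ----------
    n_modes:
        Number of modes, OSA/ANSI order starting from piston (j = 0).
    grid:
        Samples across the disk diameter.  Must resolve the highest radial
        order: we require grid >= 4 * n_max + 4 so that the fastest radial
        oscillation is sampled above Nyquist.

    Returns
    -------
    ndarray of shape (n_modes, grid, grid), zero outside the unit disk;
    the first mode is constant inside the aperture.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    n_max, _ = osa_index_to_nm(n_modes - 1)
    if grid < 4 * n_max + 4:
        raise ValueError(
            f"grid={grid} too coarse for radial order {n_max}; need >= {4 * n_max + 4}"
        )
    rho, theta, _ = unit_disk_grid(grid)
    return np.stack([zernike_mode(j, rho, theta) for j in range(n_modes)])
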