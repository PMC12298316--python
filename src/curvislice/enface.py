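"""En face image extraction: curved slicing and flat/average baselines.

A curved slice samples the volume along a fitted morphology surface
``F_m(dz) = f(x, y) + dz`` instead of a flat plane, so a thin layer that
follows the sample's curvature is captured in a single image even when a flat
plane would cut through several layers.  The traditional baselines — a flat
horizontal slice or a mean/max projection over a depth band — are provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .surface import PolySurface, evaluate_surface
from .volume import IntensityVolume

__all__ = ["EnFaceImage", "curved_slice", "flat_enface", "enhance_for_display", "ncc"]


@dataclass
class EnFaceImage:
    """2D en face image indexed ``(x, y)`` with a validity mask.

    ``valid_mask`` is False where the requested depth fell outside the volume
    (those pixels are filled with 0, never clamped to the edge voxel).
    Exported images are transposed to (ny rows, nx cols).
    """

    data: np.ndarray
    dz: float = 0.0
    method: str = "curved"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("en face image must be 2D")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.data.shape:
            raise ValueError("valid_mask shape must match data shape")


def curved_slice(
    vol: IntensityVolume,
    s: PolySurface,
    dz: float = 0.0,
    interp: Literal["nearest", "linear"] = "linear",
) -> EnFaceImage:
    """Sample the volume at depth ``f(x, y) + dz`` for every lateral position."""
    xs = np.arange(vol.nx, dtype=float)[:, None]
    ys = np.arange(vol.ny, dtype=float)[None, :]
    zq = evaluate_surface(s, xs, ys) + dz
    nz = vol.nz
    valid = (zq >= 0) & (zq <= nz - 1)
    cols = np.broadcast_to(np.arange(vol.ny)[None, :], zq.shape)
    rows = np.broadcast_to(np.arange(vol.nx)[:, None], zq.shape)
    if interp == "nearest":
        zi = np.clip(np.rint(zq).astype(int), 0, nz - 1)
        img = vol.data[rows, cols, zi]
    elif interp == "linear":
        z0 = np.clip(np.floor(zq).astype(int), 0, nz - 1)
        z1 = np.clip(z0 + 1, 0, nz - 1)
        frac = np.clip(zq - z0, 0.0, 1.0)
        img = (1 - frac) * vol.data[rows, cols, z0] + frac * vol.data[rows, cols, z1]
    else:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    img = np.where(valid, img, 0.0)
    return EnFaceImage(img, dz=dz, method="curved", valid_mask=valid)


def flat_enface(
    vol: IntensityVolume,
    z_lo: int,
    z_hi: int,
    stat: Literal["mean", "max"] = "mean",
) -> EnFaceImage:
    """Per-pixel mean or max over the inclusive depth band ``[z_lo, z_hi]``."""
    if not 0 <= z_lo <= z_hi < vol.nz:
        raise ValueError(f"depth band [{z_lo}, {z_hi}] out of range for nz={vol.nz}")
    band = vol.data[:, :, z_lo : z_hi + 1]
    if stat == "mean":
        img = band.mean(axis=2)
    elif stat == "max":
        img = band.max(axis=2)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return EnFaceImage(img, dz=float(z_lo), method="average" if z_lo != z_hi else "flat")


def enhance_for_display(img: EnFaceImage, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch to an 8-bit image (display only, deterministic)."""
    if not 0 <= p_lo < p_hi <= 100:
        raise ValueError("need 0 <= p_lo < p_hi <= 100")
    vals = img.data[img.valid_mask]
    lo, hi = np.percentile(vals, [p_lo, p_hi]) if vals.size else (0.0, 0.0)
    if hi <= lo:
        warnings.warn("constant image; display copy is all zero", stacklevel=2)
        return np.zeros(img.data.shape, dtype=np.uint8)
    stretched = np.clip((img.data - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(stretched * 255).astype(np.uint8)


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized (Pearson) cross-correlation of two same-shaped images."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if mask is not None:
        keep = np.asarray(mask, bool).ravel()
        a, b = a[keep], b[keep]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)
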