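"""Foreground extraction by Otsu's adaptive threshold.

Otsu's method picks the histogram cut that maximizes the between-class
variance ``w0 * w1 * (mu0 - mu1)**2`` between background and foreground.  OCT
magnitude histograms are heavy-tailed, so by default each B-scan is
log-compressed (``20*log10(v + eps)``, i.e. dB) before histogramming; Otsu on
raw magnitude tends to collapse onto the speckle tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .volume import IntensityVolume

__all__ = [
    "OtsuResult",
    "ForegroundPoints",
    "otsu_threshold",
    "binarize_volume",
    "extract_points",
    "log_compress",
]

log = logging.getLogger(__name__)

#: guard added before taking log10 so zero-magnitude voxels stay finite
LOG_EPS = 1e-12


@dataclass
class OtsuResult:
    """Threshold ``T`` plus the between-class variance scanned over all cuts.

    ``candidates[i]`` is the bin edge of the i-th candidate cut and
    ``interclass_variance_curve[i]`` its between-class variance; ``threshold``
    is the candidate with maximal variance (ties broken toward the lower cut).
    Pixels strictly above ``threshold`` are foreground.
    """

    threshold: float
    interclass_variance_curve: np.ndarray
    candidates: np.ndarray


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Otsu's threshold of a 2D image via an ``n_bins`` histogram scan."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("constant image: no foreground/background split exists")

    hist, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    # candidate cut t splits bins [0, t) | [t, n_bins); threshold = edges[t]
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
    var = np.nan_to_num(var, nan=0.0)
    best = int(np.argmax(var))  # first occurrence -> lower threshold on ties
    return OtsuResult(float(edges[best + 1]), var, edges[1:-1].copy())


def log_compress(data: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    """Magnitude to dB: ``20*log10(v + eps)``."""
    return 20.0 * np.log10(np.asarray(data, dtype=float) + eps)


def binarize_volume(
    vol: IntensityVolume,
    per_slice: bool = True,
    log_transform: bool = True,
    n_bins: int = 256,
) -> np.ndarray:
    """Boolean foreground mask of a volume, thresholded per B-scan by default.

    With ``per_slice`` each (x, z) B-scan gets its own Otsu threshold; otherwise
    a single global threshold is used.  A constant slice yields an all-background
    mask with a logged warning rather than an error.
    """
    data = log_compress(vol.data) if log_transform else vol.data
    mask = np.zeros(data.shape, dtype=bool)
    if per_slice:
        for y in range(vol.ny):
            sl = data[:, y, :]
            try:
                res = otsu_threshold(sl, n_bins=n_bins)
            except ValueError:
                log.warning("slice y=%d is constant; marking all background", y)
                continue
            mask[:, y, :] = sl > res.threshold
    else:
        try:
            res = otsu_threshold(data.reshape(vol.nx, -1), n_bins=n_bins)
        except ValueError:
            log.warning("volume is constant; mask is all background")
            return mask
        mask[:] = data > res.threshold
    return mask


@dataclass
class ForegroundPoints:
    """Foreground voxel coordinates: integer array of shape (N, 3), columns x, y, z."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (N, 3), got {self.coords.shape}")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def subsample(self, max_points: int, seed: int = 0) -> "ForegroundPoints":
        """Seeded uniform subsample to at most ``max_points`` (raster order kept)."""
        if max_points < 1:
            raise ValueError("max_points must be >= 1")
        if self.n <= max_points:
            return self
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(self.n, size=max_points, replace=False))
        return ForegroundPoints(self.coords[idx])

    def save_tsv(self, path) -> None:
        np.savetxt(path, self.coords, fmt="%d", delimiter="\t", header="x\ty\tz", comments="")

    @classmethod
    def load_tsv(cls, path) -> "ForegroundPoints":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=np.int64)
        return cls(np.atleast_2d(arr))


def extract_points(mask: np.ndarray) -> ForegroundPoints:
    """All true-voxel coordinates in deterministic raster order (y, then x, then z)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    idx = np.argwhere(np.transpose(mask, (1, 0, 2)))  # rows ordered by (y, x, z)
    if idx.shape[0] == 0:
        raise ValueError("empty foreground mask")
    return ForegroundPoints(idx[:, [1, 0, 2]])
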