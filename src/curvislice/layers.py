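"""Boundary-layer detection along the depth offset axis.

Shifting a fitted surface by ``dz`` and scoring how closely the foreground
cloud hugs it gives the boundary score

    gamma(dz) = (1/N) * sum_i 1 / (|f(x_i, y_i) - z_i + dz| + 1)

which lies in (0, 1], equals 1 only when every point sits exactly on the
shifted surface, and peaks whenever the surface crosses a layer boundary.
Each peak's score magnitude approximates the fraction of foreground points
belonging to that layer, which drives the outlier cut: keep the closest
``keep_fraction`` of points and refit, discarding the other layers' voxels
as outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .foreground import ForegroundPoints
from .surface import PolySurface, build_design, evaluate_surface, fit_surface

__all__ = [
    "BoundaryScoreProfile",
    "ScorePeak",
    "boundary_score",
    "score_profile",
    "select_layer",
]


def _residuals(points: ForegroundPoints, s: PolySurface) -> np.ndarray:
    """f(x_i, y_i) - z_i (before any extra dz shift)."""
    return evaluate_surface(s, points.x, points.y) - points.z


def boundary_score(points: ForegroundPoints, s: PolySurface, dz: float = 0.0) -> float:
    """Mean inverse (distance + 1) of the points to the surface shifted by ``dz``."""
    if points.n < 1:
        raise ValueError("boundary score needs at least one point")
    r = _residuals(points, s)
    return float(np.mean(1.0 / (np.abs(r + dz) + 1.0)))


@dataclass(frozen=True)
class ScorePeak:
    dz: float
    gamma: float
    inlier_fraction: float


@dataclass
class BoundaryScoreProfile:
    """gamma(dz) sampled on a grid, with detected local maxima."""

    dz_grid: np.ndarray
    gamma: np.ndarray
    peaks: list[ScorePeak]

    def best_peak(self) -> ScorePeak:
        """Highest-score peak; ties broken toward the smaller ``|dz|``."""
        if not self.peaks:
            raise ValueError("no peaks detected in boundary-score profile")
        return max(self.peaks, key=lambda p: (p.gamma, -abs(p.dz)))

    def save_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.dz_grid, self.gamma]),
            delimiter="\t",
            header="dz\tgamma",
            comments="",
        )


def score_profile(
    points: ForegroundPoints,
    s: PolySurface,
    dz_min: float,
    dz_max: float,
    step: float = 1.0,
    prominence_fraction: float = 0.1,
    refine: bool = False,
) -> BoundaryScoreProfile:
    """Evaluate gamma on the inclusive grid ``dz_min : dz_max : step`` and find peaks.

    Peaks are local maxima whose prominence exceeds ``prominence_fraction`` of
    the profile's full range.  Each peak's ``inlier_fraction`` is its share of
    the summed peak scores, a monotone proxy for the fraction of points in
    that layer.  With ``refine`` each peak position is interpolated to
    sub-grid precision by a parabola through the peak sample and its two
    neighbours.
    """
    if not dz_min < dz_max:
        raise ValueError("dz_min must be < dz_max")
    if step <= 0:
        raise ValueError("step must be > 0")
    n_steps = int(math.floor((dz_max - dz_min) / step + 1e-9))
    grid = dz_min + step * np.arange(n_steps + 1)
    r = _residuals(points, s)
    gamma = np.mean(1.0 / (np.abs(r[None, :] + grid[:, None]) + 1.0), axis=1)

    span = float(gamma.max() - gamma.min())
    peaks = []
    if span > 0:
        idx, _ = find_peaks(gamma, prominence=prominence_fraction * span)
        total = float(gamma[idx].sum()) if idx.size else 0.0
        for i in idx:
            dz_pk, g_pk = float(grid[i]), float(gamma[i])
            if refine and 0 < i < gamma.size - 1:
                y0, y1, y2 = gamma[i - 1], gamma[i], gamma[i + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    delta = 0.5 * (y0 - y2) / denom
                    dz_pk += float(delta) * step
                    g_pk = float(y1 - 0.25 * (y0 - y2) * delta)
            peaks.append(ScorePeak(dz_pk, g_pk, float(gamma[i] / total)))
    return BoundaryScoreProfile(grid, gamma, peaks)


def select_layer(
    points: ForegroundPoints,
    s: PolySurface,
    dz_peak: float,
    keep_fraction: float = 0.3,
    alpha: float | None = None,
) -> tuple[ForegroundPoints, PolySurface]:
    """Keep the points closest to the shifted surface and refit.

    Points are ranked by ``|f(x_i, y_i) - z_i + dz_peak|`` ascending (ties keep
    raster order) and the closest ``ceil(keep_fraction * N)`` survive; the rest
    are outliers from other layers.  The refit reuses the parent surface's
    degree and normalization, gets the next instance label, and has ``dz = 0``
    relative to its own fit.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    r = np.abs(_residuals(points, s) + dz_peak)
    order = np.argsort(r, kind="stable")
    n_keep = math.ceil(keep_fraction * points.n)
    kept = np.sort(order[:n_keep])  # restore raster order
    inliers = ForegroundPoints(points.coords[kept])
    design = build_design(
        inliers,
        k=s.degree,
        normalize=False if s.transform.x_scale == 1.0 and s.transform.x_off == 0.0 else True,
        extents=(
            s.transform.x_off - s.transform.x_scale,
            s.transform.x_off + s.transform.x_scale,
            s.transform.y_off - s.transform.y_scale,
            s.transform.y_off + s.transform.y_scale,
        ),
    )
    refit = fit_surface(design, alpha, label=s.label + 1)
    return inliers, refit
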