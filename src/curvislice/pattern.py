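"""Spatial-frequency pattern analysis and layer-thickness measurement.

A periodic print pattern confined to a thin depth band shows up, in the 2D
Fourier transform of a curved en face slice, as a pair of symmetric sideband
spots next to the DC peak.  Scanning the slice offset ``dz`` and tracking the
sideband strength (above the high-frequency noise floor) yields a per-offset
"pattern signal" that rises and falls as the slicing surface sweeps through
the patterned band.  A Gaussian fit to that signal gives the band's extent in
depth voxels, and projecting through the local surface tilt converts it to a
physical thickness:

    r = (Mz/Mx * df/dx, Mz/My * df/dy, 1)^T      (gradient-plane vector)
    L = n_medium * Mz * l_z * (e_z . r_hat)       (tilt-corrected thickness)

where ``l_z`` is the layer count in voxels taken from the Gaussian's 1/e^2
point (``A/e^2`` occurs at ``|dz - mu| = 2*sigma``, so the half-width reading
is ``l_z = 2*sigma``).

The automated candidate-slice workflow mirrors the printed-label analysis:
max-pool the spectrum, find the offset with the largest P2/P100 intensity
ratio (P1 is DC, P2 the sideband, P100 the noise floor), split pooled cells
into dominant/recessive locations at that offset, then score every offset as
(max near dominant) - (max near recessive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.optimize import curve_fit

from .enface import EnFaceImage, curved_slice
from .surface import PolySurface, surface_gradient
from .volume import IntensityVolume, VoxelScale

__all__ = [
    "PatternSignal",
    "CandidateSelection",
    "GaussianFit",
    "ThicknessResult",
    "region_fft",
    "maxpool_reduce",
    "rank_ratio",
    "select_candidate",
    "pattern_signal",
    "fit_gaussian_clip",
    "thickness",
]

DEFAULT_REGION = 256
DEFAULT_KERNEL = 8
DEFAULT_N_DOMINANT = 23
DEFAULT_RADIUS = 1
DEFAULT_N_MEDIUM = 1.557  # refractive index of plain paper


def region_fft(img: EnFaceImage, center_size: int, window: bool = True) -> np.ndarray:
    """DC-centered 2D DFT magnitude of the image's central square region.

    ``window`` applies a separable 2D Hann taper before the transform so that
    edge discontinuities and broad intensity structure do not leak energy
    along the spectral axes and masquerade as sidebands; disable it for exact
    Parseval accounting.
    """
    nx, ny = img.data.shape
    if center_size > min(nx, ny):
        raise ValueError(f"center_size {center_size} exceeds image extent {(nx, ny)}")
    if center_size < 1:
        raise ValueError("center_size must be >= 1")
    x0 = (nx - center_size) // 2
    y0 = (ny - center_size) // 2
    region = img.data[x0 : x0 + center_size, y0 : y0 + center_size]
    mask = img.valid_mask[x0 : x0 + center_size, y0 : y0 + center_size]
    if not mask.all():
        warnings.warn(
            f"{(~mask).sum()} masked pixels in FFT region contribute 0", stacklevel=2
        )
        region = np.where(mask, region, 0.0)
    if window:
        taper = np.hanning(center_size)
        region = region * taper[:, None] * taper[None, :]
    return np.fft.fftshift(np.abs(np.fft.fft2(region)))


def maxpool_reduce(spectrum: np.ndarray, kernel: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping kernel x kernel max pooling with an argmax coordinate map.

    Returns ``(pooled, argmax_coords)`` where ``argmax_coords[i, j]`` holds the
    (row, col) position, in the input array, of the maximum of pooled cell
    ``(i, j)``.  Edge cells may cover a partial block.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    h, w = spectrum.shape
    hc = -(-h // kernel)
    wc = -(-w // kernel)
    padded = np.full((hc * kernel, wc * kernel), -np.inf)
    padded[:h, :w] = spectrum
    blocks = padded.reshape(hc, kernel, wc, kernel).transpose(0, 2, 1, 3).reshape(hc, wc, -1)
    flat_arg = blocks.argmax(axis=2)
    pooled = np.take_along_axis(blocks, flat_arg[:, :, None], axis=2)[:, :, 0]
    rows = flat_arg // kernel + kernel * np.arange(hc)[:, None]
    cols = flat_arg % kernel + kernel * np.arange(wc)[None, :]
    coords = np.stack([rows, cols], axis=-1)
    return pooled, coords


def rank_ratio(pooled: np.ndarray, i: int, j: int) -> float:
    """Ratio of the i-th to the j-th largest intensity (1-indexed, stable ties)."""
    flat = np.asarray(pooled, dtype=float).ravel()
    if i < 1 or j < 1 or i > flat.size or j > flat.size:
        raise ValueError(f"ranks ({i}, {j}) invalid for {flat.size} entries")
    order = np.argsort(-flat, kind="stable")
    p_i = flat[order[i - 1]]
    p_j = flat[order[j - 1]]
    if p_j == 0:
        raise ZeroDivisionError(f"P{j} is zero; rank ratio undefined")
    return float(p_i / p_j)


@dataclass
class CandidateSelection:
    """Candidate offset and the dominant/recessive pooled-cell split made there."""

    dz_m: int
    dz_grid: np.ndarray
    ratio_per_dz: np.ndarray
    dominant_locations: np.ndarray  # (n_dominant, 2) pooled-cell indices
    recessive_locations: np.ndarray
    dc_cell: tuple[int, int]
    sharp: bool  # False when the ratio curve has no clear maximum (max/min < 2)

    @property
    def n_dominant(self) -> int:
        return self.dominant_locations.shape[0]


def _pool_offset(n: int, kernel: int) -> int:
    """Circular shift that centers the DC bin (index n//2) within its pooled cell."""
    return (kernel // 2 - (n // 2) % kernel) % kernel


def pooled_dc_cell(center_size: int, kernel: int) -> tuple[int, int]:
    """Pooled-cell index holding DC under the aligned pooling grid."""
    off = _pool_offset(center_size, kernel)
    idx = (center_size // 2 + off) // kernel
    return (idx, idx)


def _pooled_spectrum(
    vol: IntensityVolume,
    s: PolySurface,
    dz: float,
    center_size: int,
    kernel: int,
    interp: str = "linear",
) -> np.ndarray:
    img = curved_slice(vol, s, dz, interp=interp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # masked edge pixels are expected mid-scan
        spec = region_fft(img, center_size)
    # align the pooling grid on the DC bin so a peak's taper mainlobe stays in
    # one cell instead of straddling a cell boundary
    off = _pool_offset(center_size, kernel)
    pooled, _ = maxpool_reduce(np.roll(spec, (off, off), axis=(0, 1)), kernel)
    return pooled


def select_candidate(
    vol: IntensityVolume,
    s: PolySurface,
    dz_range: Sequence[int],
    center_size: int = DEFAULT_REGION,
    kernel: int = DEFAULT_KERNEL,
    n_dominant: int = DEFAULT_N_DOMINANT,
    interp: str = "linear",
) -> CandidateSelection:
    """Find the offset with the largest P2/P100 ratio and split its pooled cells.

    Ties in the ratio are broken toward the smaller ``|dz|``.  The ``n_dominant``
    largest pooled intensities at the candidate offset become the dominant
    locations; every other pooled cell is recessive.
    """
    dz_grid = np.asarray(list(dz_range), dtype=int)
    if dz_grid.size == 0:
        raise ValueError("dz_range must be nonempty")
    ratios = np.empty(dz_grid.size)
    pooled_at = {}
    for idx, dz in enumerate(dz_grid):
        pooled = _pooled_spectrum(vol, s, int(dz), center_size, kernel, interp)
        pooled_at[int(dz)] = pooled
        ratios[idx] = rank_ratio(pooled, 2, 100)
    best = max(range(dz_grid.size), key=lambda k: (ratios[k], -abs(int(dz_grid[k]))))
    dz_m = int(dz_grid[best])

    pooled = pooled_at[dz_m]
    flat_order = np.argsort(-pooled.ravel(), kind="stable")
    all_cells = np.column_stack(np.unravel_index(flat_order, pooled.shape))
    dominant = all_cells[:n_dominant]
    recessive = all_cells[n_dominant:]
    dc_cell = pooled_dc_cell(center_size, kernel)
    span = ratios.max() / max(ratios.min(), np.finfo(float).tiny)
    return CandidateSelection(
        dz_m, dz_grid, ratios, dominant, recessive, dc_cell, bool(span >= 2.0)
    )


@dataclass
class PatternSignal:
    """Sideband / noise / signal intensities per depth offset."""

    dz_grid: np.ndarray
    sideband: np.ndarray
    noise: np.ndarray

    @property
    def signal(self) -> np.ndarray:
        return self.sideband - self.noise

    def save_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.dz_grid, self.sideband, self.noise, self.signal]),
            delimiter="\t",
            header="dz\tsideband\tnoise\tsignal",
            comments="",
        )


def _neighborhood_mask(shape, cells: np.ndarray, radius: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if cells.size:
        mask[cells[:, 0], cells[:, 1]] = True
    if radius > 0:
        size = 2 * radius + 1
        mask = binary_dilation(mask, structure=np.ones((size, size), dtype=bool))
    return mask


def pattern_signal(
    vol: IntensityVolume,
    s: PolySurface,
    selection: CandidateSelection,
    dz_range: Sequence[int] | None = None,
    center_size: int = DEFAULT_REGION,
    kernel: int = DEFAULT_KERNEL,
    radius: int = DEFAULT_RADIUS,
    interp: str = "linear",
) -> PatternSignal:
    """Per-offset sideband minus noise, using the candidate slice's locations.

    Sideband: the largest pooled intensity within Chebyshev radius ``radius`` of
    any dominant location.  Noise: the largest pooled intensity near the
    recessive locations.  The DC neighborhood is excluded from both searches
    (it is neither pattern nor noise), and dominant neighborhoods are excluded
    from the noise search so low-frequency structure cannot masquerade as the
    noise floor.
    """
    dz_grid = selection.dz_grid if dz_range is None else np.asarray(list(dz_range), int)
    side = np.empty(dz_grid.size)
    noise = np.empty(dz_grid.size)
    dom_mask = rec_mask = None
    for idx, dz in enumerate(dz_grid):
        pooled = _pooled_spectrum(vol, s, int(dz), center_size, kernel, interp)
        if dom_mask is None:
            dc = _neighborhood_mask(
                pooled.shape, np.array([selection.dc_cell]), radius
            )
            dom_mask = _neighborhood_mask(pooled.shape, selection.dominant_locations, radius)
            rec_mask = _neighborhood_mask(pooled.shape, selection.recessive_locations, radius)
            rec_mask &= ~dom_mask
            dom_mask &= ~dc
            rec_mask &= ~dc
        side[idx] = pooled[dom_mask].max() if dom_mask.any() else 0.0
        noise[idx] = pooled[rec_mask].max() if rec_mask.any() else 0.0
    return PatternSignal(dz_grid.astype(float), side, noise)


@dataclass
class GaussianFit:
    amplitude: float
    center: float
    sigma: float
    converged: bool

    def __call__(self, x):
        return self.amplitude * np.exp(-((np.asarray(x, float) - self.center) ** 2) / (2 * self.sigma**2))

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "center": self.center,
            "sigma": self.sigma,
            "converged": self.converged,
        }


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def _fit_gauss(x: np.ndarray, y: np.ndarray) -> GaussianFit:
    a0 = float(y.max())
    if a0 <= 0:
        raise ValueError("pattern signal has no positive samples to fit")
    mu0 = float(x[np.argmax(y)])
    pos = np.clip(y, 0, None)
    denom = pos.sum()
    sigma0 = float(np.sqrt(np.sum(pos * (x - mu0) ** 2) / denom)) if denom > 0 else 1.0
    sigma0 = max(sigma0, 0.5)
    span = float(x.max() - x.min()) or 1.0
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=(a0, mu0, sigma0),
            bounds=([0.0, x.min() - span, 1e-3], [np.inf, x.max() + span, 10 * span]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, sigma = map(float, popt)
    if sigma <= 0:
        raise ValueError(f"Gaussian fit produced non-positive width {sigma}")
    return GaussianFit(a, mu, sigma, True)


def fit_gaussian_clip(
    sig: PatternSignal, width_mode: Literal["half", "full"] = "half"
) -> tuple[GaussianFit, PatternSignal, GaussianFit, float]:
    """Two-stage Gaussian fit with a right-side 1/e^2 clip.

    Fits ``A*exp(-(dz-mu)^2 / (2*sigma^2))`` to the pattern signal, clips the
    samples beyond ``mu + 2*sigma`` of the initial fit (deep slices carry
    multiple-scattering tails), refits, and reads the layer count off the final
    width: ``l_z = 2*sigma`` ("half", peak to the 1/e^2 point) or ``4*sigma``
    ("full").
    """
    x = np.asarray(sig.dz_grid, float)
    y = np.asarray(sig.signal, float)
    if np.count_nonzero(y > 0) < 4:
        raise ValueError("need at least 4 positive signal samples for a Gaussian fit")
    initial = _fit_gauss(x, y)
    keep = x <= initial.center + 2 * initial.sigma
    if keep.sum() < 4:
        keep = np.ones_like(keep)
    clipped = PatternSignal(x[keep], sig.sideband[keep], sig.noise[keep])
    final = _fit_gauss(clipped.dz_grid, clipped.signal)
    if width_mode == "half":
        l_z = 2.0 * final.sigma
    elif width_mode == "full":
        l_z = 4.0 * final.sigma
    else:
        raise ValueError(f"unknown width_mode {width_mode!r}")
    return initial, clipped, final, float(l_z)


@dataclass
class ThicknessResult:
    """Tilt-corrected physical thickness and its geometric ingredients."""

    l_z: float  # layer count, depth voxels
    r: np.ndarray  # gradient-plane vector (dimensionless)
    unit_projection: float  # e_z . r_hat
    n_medium: float
    thickness_um: float

    def to_dict(self) -> dict:
        return {
            "l_z": self.l_z,
            "r": list(map(float, self.r)),
            "unit_projection": self.unit_projection,
            "n_medium": self.n_medium,
            "thickness_um": self.thickness_um,
        }


def thickness(
    l_z: float,
    s: PolySurface,
    x0: float,
    y0: float,
    scale: VoxelScale,
    n_medium: float = DEFAULT_N_MEDIUM,
) -> ThicknessResult:
    """Physical layer thickness ``L = n * Mz * l_z * (e_z . r_hat)`` in micrometres.

    The gradient-plane vector at ``(x0, y0)`` is
    ``r = (Mz/Mx * df/dx, Mz/My * df/dy, 1)``; its unit form's z-component,
    ``1/|r|``, shortens the axial voxel count to the true thickness measured
    perpendicular to the tilted layer.
    """
    if l_z <= 0:
        raise ValueError("l_z must be > 0")
    if n_medium < 1:
        raise ValueError("n_medium must be >= 1")
    gx, gy = surface_gradient(s, x0, y0)
    r = np.array([scale.mz / scale.mx * float(gx), scale.mz / scale.my * float(gy), 1.0])
    proj = 1.0 / float(np.linalg.norm(r))
    L = n_medium * scale.mz * l_z * proj
    return ThicknessResult(float(l_z), r, proj, float(n_medium), float(L))
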