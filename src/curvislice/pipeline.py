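"""End-to-end automated workflows and their configuration.

``run_auto_thickness`` chains the whole ink-thickness measurement: binarize
the volume, fit the morphology surface, locate the boundary via the
boundary-score profile, reject outliers and refit, scan slice offsets for the
candidate pattern slice (largest P2/P100 ratio), build the pattern signal,
double Gaussian fit with the 1/e^2 right-side clip, and convert the fitted
width to a tilt-corrected physical thickness.  Every intermediate quantity
lands in a JSON-serializable report with a provenance block, so a run is
reproducible from its report alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .enface import EnFaceImage, curved_slice, enhance_for_display, flat_enface
from .foreground import binarize_volume, extract_points
from .layers import score_profile, select_layer
from .pattern import (
    fit_gaussian_clip,
    pattern_signal,
    select_candidate,
    thickness,
)
from .surface import fit_points
from .volume import IntensityVolume

__all__ = ["PipelineConfig", "run_auto_thickness", "run_enface_export"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the automated workflows.

    Defaults follow the reference instrument configuration; every value can be
    overridden from YAML or CLI flags.  ``validate()`` runs before any stage.
    """

    degree: int = 3
    alpha: float = 0.1
    per_slice: bool = True
    log_transform: bool = True
    n_bins: int = 256
    max_points: int | None = 200_000
    dz_scan: tuple = (-32.0, 32.0)  # boundary-score scan range, voxels
    dz_step: float = 1.0
    target_layer: str | int = "strongest"  # or index into peaks sorted by dz
    keep_fraction: float = 0.3
    dz_range: tuple = (-20, 19)  # candidate/pattern offset range, voxels
    region_size: int = 256
    pool_kernel: int = 8
    n_dominant: int = 23
    radius: int = 1
    interp: str = "linear"
    width_mode: str = "half"
    n_medium: float = 1.557
    seed: int = 0

    def validate(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.dz_scan[0] >= self.dz_scan[1] or self.dz_step <= 0:
            raise ValueError("invalid boundary-score scan range")
        if len(tuple(self.dz_range)) != 2 or self.dz_range[0] > self.dz_range[1]:
            raise ValueError("invalid dz_range")
        if self.region_size < 1 or self.pool_kernel < 1:
            raise ValueError("region_size and pool_kernel must be >= 1")
        if self.n_dominant < 1 or self.radius < 0:
            raise ValueError("n_dominant must be >= 1 and radius >= 0")
        if self.interp not in ("linear", "nearest"):
            raise ValueError("interp must be 'linear' or 'nearest'")
        if self.width_mode not in ("half", "full"):
            raise ValueError("width_mode must be 'half' or 'full'")
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dz_scan"] = list(self.dz_scan)
        d["dz_range"] = list(self.dz_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("dz_scan", "dz_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _provenance(config: PipelineConfig) -> dict:
    return {
        "curvislice_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
    }


def _fit_target_surface(vol: IntensityVolume, config: PipelineConfig, report: dict):
    """Binarize -> fit -> boundary profile -> outlier cut -> refit."""
    mask = binarize_volume(
        vol, per_slice=config.per_slice, log_transform=config.log_transform, n_bins=config.n_bins
    )
    points = extract_points(mask)
    if config.max_points is not None:
        points = points.subsample(config.max_points, seed=config.seed)
    report["n_foreground_points"] = points.n

    extents = (0.0, vol.nx - 1.0, 0.0, vol.ny - 1.0)
    initial = fit_points(
        points, k=config.degree, alpha=config.alpha, extents=extents, label=1
    )
    profile = score_profile(
        points, initial, config.dz_scan[0], config.dz_scan[1], config.dz_step
    )
    report["gamma_profile"] = {
        "dz": profile.dz_grid.tolist(),
        "gamma": profile.gamma.tolist(),
        "peaks": [dataclasses.asdict(p) for p in profile.peaks],
    }
    if config.target_layer == "strongest":
        peak = profile.best_peak()
    else:
        idx = int(config.target_layer)
        if not 0 <= idx < len(profile.peaks):
            raise ValueError(
                f"target_layer index {idx} out of range ({len(profile.peaks)} peaks)"
            )
        peak = profile.peaks[idx]
    report["selected_peak"] = dataclasses.asdict(peak)
    inliers, refit = select_layer(
        points, initial, peak.dz, config.keep_fraction, alpha=config.alpha
    )
    report["n_inliers"] = inliers.n
    report["surface"] = refit.to_dict()
    return refit


def run_auto_thickness(vol: IntensityVolume, config: PipelineConfig) -> dict:
    """Automated layer-thickness measurement; returns the full report dict.

    The report carries the candidate offset ``dz_m``, the P2/P100 ratio curve,
    the pattern signal, both Gaussian fits, the layer count ``l_z`` and the
    physical thickness ``thickness_um``, plus a provenance block.
    """
    config.validate()
    report: dict = {"provenance": _provenance(config)}
    stage = "segment/fit"
    try:
        surface = _fit_target_surface(vol, config, report)
        stage = "candidate-selection"
        dz_lo, dz_hi = int(config.dz_range[0]), int(config.dz_range[1])
        dz_range = range(dz_lo, dz_hi + 1)
        selection = select_candidate(
            vol,
            surface,
            dz_range,
            center_size=config.region_size,
            kernel=config.pool_kernel,
            n_dominant=config.n_dominant,
            interp=config.interp,
        )
        report["dz_m"] = selection.dz_m
        report["ratio_per_dz"] = {
            "dz": selection.dz_grid.tolist(),
            "ratio": selection.ratio_per_dz.tolist(),
        }
        report["candidate_sharp"] = selection.sharp
        stage = "pattern-signal"
        sig = pattern_signal(
            vol,
            surface,
            selection,
            center_size=config.region_size,
            kernel=config.pool_kernel,
            radius=config.radius,
            interp=config.interp,
        )
        report["pattern_signal"] = {
            "dz": sig.dz_grid.tolist(),
            "sideband": sig.sideband.tolist(),
            "noise": sig.noise.tolist(),
            "signal": sig.signal.tolist(),
        }
        stage = "gaussian-fit"
        initial, clipped, final, l_z = fit_gaussian_clip(sig, width_mode=config.width_mode)
        report["gaussian_initial"] = initial.to_dict()
        report["gaussian_final"] = final.to_dict()
        report["n_clipped_samples"] = int(sig.dz_grid.size - clipped.dz_grid.size)
        stage = "thickness"
        x0, y0 = (vol.nx - 1) / 2.0, (vol.ny - 1) / 2.0
        result = thickness(l_z, surface, x0, y0, vol.scale, config.n_medium)
        report["l_z"] = result.l_z
        report["unit_projection"] = result.unit_projection
        report["thickness_um"] = result.thickness_um
        report["r_vector"] = list(map(float, result.r))
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        raise RuntimeError(f"auto-thickness failed at stage '{stage}': {exc}") from exc
    return report


def run_enface_export(
    vol: IntensityVolume,
    config: PipelineConfig,
    dz_list,
    out_dir=None,
    baseline_band: tuple | None = None,
) -> dict:
    """Curved slices at each requested offset plus a flat/average baseline.

    Returns ``{"curved": {dz: EnFaceImage}, "baseline": EnFaceImage,
    "surface": PolySurface, "report": dict}``; if ``out_dir`` is given, 8-bit
    display copies are written as PNGs with deterministic names
    (``enface_curved_dz{+d}.png``, ``enface_average_z{lo}-{hi}.png``).
    """
    config.validate()
    report: dict = {"provenance": _provenance(config)}
    surface = _fit_target_surface(vol, config, report)
    curved = {float(dz): curved_slice(vol, surface, float(dz), interp=config.interp) for dz in dz_list}
    if baseline_band is None:
        z_centers = surface(np.array([0, vol.nx - 1]), np.array([0, vol.ny - 1]))
        lo = int(max(0, np.floor(z_centers.min() - 10)))
        hi = int(min(vol.nz - 1, np.ceil(z_centers.max() + 10)))
    else:
        lo, hi = int(baseline_band[0]), int(baseline_band[1])
    baseline = flat_enface(vol, lo, hi, stat="mean")
    if out_dir is not None:
        import os

        import imageio.v3 as iio

        os.makedirs(out_dir, exist_ok=True)
        for dz, img in curved.items():
            name = f"enface_curved_dz{dz:+g}.png"
            iio.imwrite(os.path.join(out_dir, name), enhance_for_display(img).T)
        iio.imwrite(
            os.path.join(out_dir, f"enface_average_z{lo}-{hi}.png"),
            enhance_for_display(baseline).T,
        )
    return {"curved": curved, "baseline": baseline, "surface": surface, "report": report}
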