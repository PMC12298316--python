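"""Synthetic OCT-like phantom volumes with known ground truth.

Every stage of the curved-slicing pipeline is testable against these phantoms
without any instrument data: one or two bright boundary bands draped over
polynomial height maps, an optional spatially periodic "print" pattern
confined to a depth band riding a named layer, and speckle-like background
noise.  The generator emits every quantity downstream assertions need (height
maps, boundary voxel masks, the pattern image, the band's physical thickness)
so tests never have to re-derive truth.

Model choices, briefly:

* **Bands** are deposited with partial-voxel (anti-aliased) weights, so
  sub-voxel band thicknesses and surface positions are meaningful.
* **Background noise** is additive gamma-distributed speckle with shape
  parameter ``shape`` (mean ``background``): shape 1 is fully developed
  exponential-magnitude speckle, larger shapes emulate the reduced contrast of
  multi-scan-averaged volumes.  The default shape of 4 represents a 4-scan
  average, the normal acquisition mode for the volumes this package targets.
  A small Gaussian readout term is added and the volume clipped at zero.
* **Diffusive layers** get a smooth multiplicative reflectivity field
  (``reflectivity_sigma`` > 0), which is what makes flat projections of a
  rough bright layer drown out deeper low-contrast structure.
* **Sparse layers** (``coverage`` < 1) keep only the given area fraction of
  the band, as connected blobs — residue-like debris.

All randomness flows through one ``numpy.random.default_rng(seed)``; a spec
reproduces its volume bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .surface import AffineXY, PolySurface, poly_exponents
from .volume import IntensityVolume, VoxelScale

__all__ = [
    "true_surface",
    "LayerSpec",
    "PatternSpec",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_two_layer_phantom",
    "make_tape_phantom",
    "make_label_phantom",
]


@dataclass
class LayerSpec:
    """One boundary band: polynomial height map + intensity + axial thickness.

    ``coeffs`` maps exponent pairs ``"a,b"`` to coefficients of the height map
    ``f(x, y) = sum C_ab u^a v^b`` in normalized lateral coordinates
    ``u, v in [-1, 1]`` (so coefficients are in depth voxels regardless of the
    lateral grid size).
    """

    coeffs: dict
    intensity: float
    thickness: float = 3.0
    reflectivity_sigma: float = 0.0
    reflectivity_corr: float = 6.0
    coverage: float = 1.0

    def height_map(self, nx: int, ny: int) -> np.ndarray:
        u = np.linspace(-1.0, 1.0, nx)[:, None]
        v = np.linspace(-1.0, 1.0, ny)[None, :]
        f = np.zeros((nx, ny))
        for key, c in self.coeffs.items():
            a, b = (int(s) for s in str(key).split(","))
            f = f + float(c) * u**a * v**b
        return f

    def gradient_at_center(self, nx: int, ny: int) -> tuple[float, float]:
        """Analytic (df/dx, df/dy) in voxel units at the lateral center."""
        gx = gy = 0.0
        for key, c in self.coeffs.items():
            a, b = (int(s) for s in str(key).split(","))
            # u = v = 0 at the center: only monomials linear in one coordinate survive
            if a == 1 and b == 0:
                gx += float(c)
            if a == 0 and b == 1:
                gy += float(c)
        return gx * 2.0 / (nx - 1), gy * 2.0 / (ny - 1)


def true_surface(layer: "LayerSpec", dims: tuple) -> PolySurface:
    """Ground-truth ``PolySurface`` for a phantom layer.

    Phantom height maps live on normalized lateral coordinates
    ``u, v in [-1, 1]``; the matching affine transform reproduces them
    exactly, so downstream code can treat the truth like any fitted surface.
    """
    nx, ny, _ = dims
    pairs = {tuple(int(s) for s in str(key).split(",")): float(c) for key, c in layer.coeffs.items()}
    degree = max(a + b for a, b in pairs)
    exps = poly_exponents(degree)
    coeffs = np.zeros(len(exps))
    for i, ab in enumerate(exps):
        coeffs[i] = pairs.get(ab, 0.0)
    tr = AffineXY((nx - 1) / 2.0, (nx - 1) / 2.0, (ny - 1) / 2.0, (ny - 1) / 2.0)
    return PolySurface(degree, coeffs, 0.0, 1, tr)


@dataclass
class PatternSpec:
    """Sinusoidal print pattern confined to a depth band relative to one layer."""

    frequency: float  # cycles per voxel along the pattern direction
    orientation_deg: float
    amplitude: float
    layer: int  # index into PhantomSpec.layers
    band: tuple  # (lo, hi) depth offsets in voxels relative to the layer surface
    phase: float = 0.0
    profile: str = "box"  # axial amplitude profile: "box" (hard edges) or
    # "gauss" (Gaussian whose peak-to-1/e^2 distance is (hi-lo)/1, i.e.
    # sigma = (hi-lo)/2 centered on the band midpoint) - the smooth profile an
    # imaging system with finite axial response actually records

    def image(self, nx: int, ny: int) -> np.ndarray:
        """Pattern image in [0, 1]."""
        x = np.arange(nx)[:, None]
        y = np.arange(ny)[None, :]
        th = math.radians(self.orientation_deg)
        arg = 2 * math.pi * self.frequency * (x * math.cos(th) + y * math.sin(th))
        return 0.5 * (1.0 + np.cos(arg + self.phase)) * np.ones((nx, ny))


@dataclass
class NoiseSpec:
    background: float = 1.0  # mean of the additive speckle floor
    shape: float = 4.0  # gamma shape; 1 = fully developed (exponential) speckle
    readout: float = 0.3  # additive Gaussian readout sigma
    structure_shape: float | None = None  # gamma shape of multiplicative speckle
    # on the deposited structure (mean 1, contrast 1/sqrt(shape)); None = off,
    # emulating a heavily averaged acquisition


@dataclass
class PhantomSpec:
    dims: tuple  # (nx, ny, nz)
    layers: list
    pattern: PatternSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    scale: VoxelScale = field(default_factory=VoxelScale.default)
    n_medium: float = 1.0

    def to_dict(self) -> dict:
        d = {
            "dims": list(self.dims),
            "layers": [
                {
                    "coeffs": {str(k): float(v) for k, v in l.coeffs.items()},
                    "intensity": l.intensity,
                    "thickness": l.thickness,
                    "reflectivity_sigma": l.reflectivity_sigma,
                    "reflectivity_corr": l.reflectivity_corr,
                    "coverage": l.coverage,
                }
                for l in self.layers
            ],
            "pattern": None,
            "noise": {
                "background": self.noise.background,
                "shape": self.noise.shape,
                "readout": self.noise.readout,
                "structure_shape": self.noise.structure_shape,
            },
            "seed": self.seed,
            "scale": self.scale.to_dict(),
            "n_medium": self.n_medium,
        }
        if self.pattern is not None:
            d["pattern"] = {
                "frequency": self.pattern.frequency,
                "orientation_deg": self.pattern.orientation_deg,
                "amplitude": self.pattern.amplitude,
                "layer": self.pattern.layer,
                "band": list(self.pattern.band),
                "phase": self.pattern.phase,
                "profile": self.pattern.profile,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        pattern = None
        if d.get("pattern") is not None:
            p = d["pattern"]
            pattern = PatternSpec(
                float(p["frequency"]),
                float(p["orientation_deg"]),
                float(p["amplitude"]),
                int(p["layer"]),
                tuple(float(b) for b in p["band"]),
                float(p.get("phase", 0.0)),
                str(p.get("profile", "box")),
            )
        return cls(
            dims=tuple(int(v) for v in d["dims"]),
            layers=[
                LayerSpec(
                    coeffs=dict(l["coeffs"]),
                    intensity=float(l["intensity"]),
                    thickness=float(l["thickness"]),
                    reflectivity_sigma=float(l.get("reflectivity_sigma", 0.0)),
                    reflectivity_corr=float(l.get("reflectivity_corr", 6.0)),
                    coverage=float(l.get("coverage", 1.0)),
                )
                for l in d["layers"]
            ],
            pattern=pattern,
            noise=NoiseSpec(**d.get("noise", {})),
            seed=int(d.get("seed", 0)),
            scale=VoxelScale.from_dict(d["scale"]) if "scale" in d else VoxelScale.default(),
            n_medium=float(d.get("n_medium", 1.0)),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def load_json(cls, path) -> "PhantomSpec":
        with open(path) as f:
            return cls.from_dict(json.load(f))


@dataclass
class PhantomTruth:
    """Everything downstream assertions need, emitted by the generator."""

    height_maps: list  # per layer, (nx, ny) arrays in voxels
    boundary_masks: list  # per layer, boolean (nx, ny, nz) volumes
    pattern_image: np.ndarray | None
    pattern_band: tuple | None  # (lo, hi) offsets relative to its layer surface
    pattern_layer: int | None
    true_lz: float | None  # patterned band extent, depth voxels
    true_thickness_um: float | None  # physical thickness along the surface normal
    unit_projection: float | None  # e_z . r_hat at the lateral center
    spec: PhantomSpec


def _band_weights(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fraction of voxel [z-0.5, z+0.5] inside [lo, hi] (broadcast over z)."""
    return np.clip(
        np.minimum(z + 0.5, hi[:, :, None]) - np.maximum(z - 0.5, lo[:, :, None]), 0.0, 1.0
    )


def _smooth_unit_field(rng: np.random.Generator, nx: int, ny: int, corr: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((nx, ny)), corr, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, PhantomTruth]:
    nx, ny, nz = spec.dims
    rng = np.random.default_rng(spec.seed)
    z = np.arange(nz, dtype=float)

    clean = np.zeros((nx, ny, nz))
    height_maps, boundary_masks = [], []
    for layer in spec.layers:
        f = layer.height_map(nx, ny)
        lo, hi = f - layer.thickness / 2.0, f + layer.thickness / 2.0
        if lo.min() < -0.5 or hi.max() > nz - 0.5:
            raise ValueError(
                f"layer band [{lo.min():.1f}, {hi.max():.1f}] leaves the volume (nz={nz})"
            )
        w = _band_weights(z, lo, hi)
        refl = np.ones((nx, ny))
        if layer.reflectivity_sigma > 0:
            refl = np.clip(
                1.0
                + layer.reflectivity_sigma
                * _smooth_unit_field(rng, nx, ny, layer.reflectivity_corr),
                0.05,
                None,
            )
        cov = np.ones((nx, ny), dtype=bool)
        if layer.coverage < 1.0:
            blob = _smooth_unit_field(rng, nx, ny, 2.0)
            cov = blob > np.quantile(blob, 1.0 - layer.coverage)
        clean += layer.intensity * (refl * cov)[:, :, None] * w
        height_maps.append(f)
        boundary_masks.append((w >= 0.5) & cov[:, :, None])

    pattern_image = None
    pattern_band = pattern_layer = true_lz = true_T = proj = None
    if spec.pattern is not None:
        p = spec.pattern
        f = height_maps[p.layer]
        lo, hi = f + p.band[0], f + p.band[1]
        if lo.min() < -0.5 or hi.max() > nz - 0.5:
            raise ValueError("pattern band leaves the volume")
        if p.profile == "gauss":
            c = f + (p.band[0] + p.band[1]) / 2.0
            sigma_p = (p.band[1] - p.band[0]) / 2.0
            w = np.exp(-((z - c[:, :, None]) ** 2) / (2.0 * sigma_p**2))
        elif p.profile == "box":
            w = _band_weights(z, lo, hi)
        else:
            raise ValueError(f"unknown pattern profile {p.profile!r}")
        pattern_image = p.image(nx, ny)
        clean += p.amplitude * pattern_image[:, :, None] * w
        pattern_band = (float(p.band[0]), float(p.band[1]))
        pattern_layer = p.layer
        true_lz = float(p.band[1] - p.band[0])
        gx, gy = spec.layers[p.layer].gradient_at_center(nx, ny)
        r = np.array(
            [spec.scale.mz / spec.scale.mx * gx, spec.scale.mz / spec.scale.my * gy, 1.0]
        )
        proj = float(1.0 / np.linalg.norm(r))
        true_T = float(spec.n_medium * spec.scale.mz * true_lz * proj)

    noisy = clean
    if spec.noise.structure_shape is not None:
        m = spec.noise.structure_shape
        noisy = noisy * rng.gamma(m, 1.0 / m, size=clean.shape)
    if spec.noise.background > 0:
        noisy = noisy + rng.gamma(
            spec.noise.shape, spec.noise.background / spec.noise.shape, size=clean.shape
        )
    if spec.noise.readout > 0:
        # magnitude of a zero-mean readout term: keeps the volume strictly
        # positive, like real detector magnitude data
        noisy = noisy + np.abs(rng.normal(0.0, spec.noise.readout, size=clean.shape))
    vol = IntensityVolume(np.clip(noisy, 0.0, None), spec.scale)
    truth = PhantomTruth(
        height_maps,
        boundary_masks,
        pattern_image,
        pattern_band,
        pattern_layer,
        true_lz,
        true_T,
        proj,
        spec,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Presets


def make_two_layer_phantom(
    separation: float = 11.0,
    seed: int = 0,
    dims: tuple = (128, 64, 128),
    intensity: float = 60.0,
    thickness: float = 3.0,
) -> PhantomSpec:
    """Two parallel gently curved boundary bands ``separation`` voxels apart."""
    base = {"0,0": 50.0, "1,0": 4.0, "2,0": -5.0, "0,2": 3.0, "1,1": 2.0, "3,0": 1.5}
    second = dict(base)
    second["0,0"] = base["0,0"] + separation
    return PhantomSpec(
        dims=dims,
        layers=[
            LayerSpec(base, intensity, thickness),
            LayerSpec(second, intensity, thickness),
        ],
        seed=seed,
    )


def make_tape_phantom(seed: int = 0, dims: tuple = (160, 160, 128)) -> PhantomSpec:
    """Translucent-tape scenario: diffusive top boundary, low-contrast ridge
    pattern at the glue layer 11 voxels deeper, sparse residue debris below.

    The rough bright top layer dominates flat/average en face projections; the
    fingerprint-like ridge pattern only becomes resolvable on a curved slice
    that follows the glue layer.
    """
    top = {"0,0": 45.0, "1,0": 4.0, "2,0": -5.0, "0,2": 3.0, "1,1": 2.0, "3,0": 1.5}
    glue = dict(top)
    glue["0,0"] = top["0,0"] + 11.0
    residue = dict(top)
    residue["0,0"] = top["0,0"] + 17.0
    return PhantomSpec(
        dims=dims,
        layers=[
            LayerSpec(top, 100.0, 3.0, reflectivity_sigma=0.6, reflectivity_corr=6.0),
            LayerSpec(glue, 25.0, 2.0, reflectivity_sigma=0.05),
            LayerSpec(residue, 60.0, 1.0, coverage=0.05),
        ],
        pattern=PatternSpec(0.06, 25.0, 25.0, layer=1, band=(-1.0, 1.0)),
        seed=seed,
    )


def make_label_phantom(
    thickness_um: float = 20.0,
    tilt_deg: float = 10.0,
    azimuth_deg: float = 0.0,
    pattern_offset: float = -6.0,
    seed: int = 0,
    dims: tuple = (160, 128, 192),
    scale: VoxelScale | None = None,
    n_medium: float = 1.0,
) -> PhantomSpec:
    """Thermal-printed-label scenario: a tilted cubic paper boundary with a
    periodic ink band of known physical thickness a few voxels above it.

    ``tilt_deg`` is the physical tilt of the surface and ``azimuth_deg`` the
    in-plane direction of that tilt (used to emulate re-orienting the sample).
    The ink band's z-extent is ``thickness_um / (n_medium * Mz * projection)``
    so the band's physical thickness measured along the surface normal equals
    ``thickness_um`` exactly.
    """
    if scale is None:
        scale = VoxelScale.default()
    nx, ny, nz = dims
    th = math.radians(tilt_deg)
    az = math.radians(azimuth_deg)
    slope_x = math.tan(th) * scale.mx / scale.mz * math.cos(az)  # voxel/voxel
    slope_y = math.tan(th) * scale.my / scale.mz * math.sin(az)
    coeffs = {
        "0,0": nz / 2.0,
        "1,0": slope_x * (nx - 1) / 2.0,
        "0,1": slope_y * (ny - 1) / 2.0,
        "2,0": -6.0,
        "0,2": -4.0,
        "1,1": 3.0,
        "3,0": 2.0,
    }
    r = np.array([scale.mz / scale.mx * slope_x, scale.mz / scale.my * slope_y, 1.0])
    proj = float(1.0 / np.linalg.norm(r))  # = cos(tilt)
    t_vox = thickness_um / (n_medium * scale.mz * proj)
    band = (pattern_offset - t_vox / 2.0, pattern_offset + t_vox / 2.0)
    return PhantomSpec(
        dims=dims,
        layers=[LayerSpec(coeffs, 100.0, 4.0, reflectivity_sigma=0.2, reflectivity_corr=12.0)],
        pattern=PatternSpec(
            0.25, azimuth_deg, 4.0, layer=0, band=band, phase=0.7, profile="gauss"
        ),
        noise=NoiseSpec(background=1.0, shape=8.0, readout=0.3, structure_shape=8.0),
        seed=seed,
        scale=scale,
        n_medium=n_medium,
    )
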