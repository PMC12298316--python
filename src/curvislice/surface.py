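"""Ridge-regularized polynomial surface fitting.

A sample's structural morphology is modelled as a bivariate polynomial height
map ``f(x, y) = sum_{a+b<=k} C_ab x^a y^b`` fitted to the foreground voxel
cloud by Tikhonov-regularized least squares: minimize
``||z - X w||^2 + alpha * ||w||^2`` with the intercept left unpenalized.
The fitted surface extends to a one-parameter family ``F_m(dz) = f(x, y) + dz``
that can be shifted along the depth axis to address layers above or below the
fitted boundary; ``m`` labels individual fitted instances.

Lateral coordinates are affinely normalized to [-1, 1] before the monomial
expansion (raw voxel indices up to ~1e3 raised to the cube make the normal
equations ill-conditioned and change what a fixed ``alpha`` means).  The
transform is recorded on the surface so evaluation and gradients are always in
raw voxel coordinates; ``normalize=False`` reproduces the literal raw-coordinate
design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .foreground import ForegroundPoints

__all__ = [
    "AffineXY",
    "PolyDesign",
    "PolySurface",
    "poly_exponents",
    "build_design",
    "fit_surface",
    "evaluate_surface",
    "surface_gradient",
]

DEFAULT_DEGREE = 3
DEFAULT_ALPHA = 0.1


def poly_exponents(k: int) -> list[tuple[int, int]]:
    """Monomial exponents (a, b) with a + b <= k in lexicographic (a, b) order."""
    if k < 0:
        raise ValueError(f"degree must be >= 0, got {k}")
    return [(a, b) for a in range(k + 1) for b in range(k + 1 - a)]


@dataclass(frozen=True)
class AffineXY:
    """Affine map applied to x/y before monomial expansion: u = (x - off) / scale."""

    x_off: float = 0.0
    x_scale: float = 1.0
    y_off: float = 0.0
    y_scale: float = 1.0

    def forward(self, x, y):
        return (np.asarray(x, float) - self.x_off) / self.x_scale, (
            np.asarray(y, float) - self.y_off
        ) / self.y_scale

    def to_dict(self) -> dict:
        return {
            "x_off": self.x_off,
            "x_scale": self.x_scale,
            "y_off": self.y_off,
            "y_scale": self.y_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineXY":
        return cls(**{k: float(v) for k, v in d.items()})


def _monomials(u: np.ndarray, v: np.ndarray, k: int) -> np.ndarray:
    cols = [u**a * v**b for a, b in poly_exponents(k)]
    return np.column_stack(cols)


@dataclass
class PolyDesign:
    """Design matrix for one ridge surface fit."""

    X: np.ndarray
    z: np.ndarray
    degree: int
    transform: AffineXY
    alpha: float = DEFAULT_ALPHA


@dataclass
class PolySurface:
    """Fitted polynomial height map with depth offset ``dz`` and instance label ``m``."""

    degree: int
    coeffs: np.ndarray  # ordered as poly_exponents(degree)
    dz: float = 0.0
    label: int = 1
    transform: AffineXY = field(default_factory=AffineXY)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        n_expected = len(poly_exponents(self.degree))
        if self.coeffs.shape != (n_expected,):
            raise ValueError(
                f"degree-{self.degree} surface needs {n_expected} coefficients, "
                f"got shape {self.coeffs.shape}"
            )

    def __call__(self, x, y):
        return evaluate_surface(self, x, y)

    def shifted(self, ddz: float) -> "PolySurface":
        return PolySurface(self.degree, self.coeffs.copy(), self.dz + ddz, self.label, self.transform)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coeffs": self.coeffs.tolist(),
            "exponents": poly_exponents(self.degree),
            "dz": self.dz,
            "label": self.label,
            "transform": self.transform.to_dict(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PolySurface":
        return cls(
            int(d["degree"]),
            np.asarray(d["coeffs"], dtype=float),
            float(d.get("dz", 0.0)),
            int(d.get("label", 1)),
            AffineXY.from_dict(d.get("transform", AffineXY().to_dict())),
        )

    @classmethod
    def load_json(cls, path) -> "PolySurface":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def build_design(
    points: ForegroundPoints,
    k: int = DEFAULT_DEGREE,
    normalize: bool = True,
    extents: tuple[float, float, float, float] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> PolyDesign:
    """Monomial design matrix for the point cloud.

    ``extents = (x_min, x_max, y_min, y_max)`` defines the lateral box mapped to
    [-1, 1]^2 when normalizing; it defaults to the point cloud's own bounding
    box.  Pass the volume extents when the surface will be evaluated over a
    full lateral grid.
    """
    exps = poly_exponents(k)  # validates k
    n_coef = len(exps)
    if points.n < n_coef:
        import warnings

        warnings.warn(
            f"only {points.n} points for {n_coef} coefficients; "
            "fit is underdetermined and relies on regularization",
            stacklevel=2,
        )
    if normalize:
        if extents is None:
            x_min, x_max = float(points.x.min()), float(points.x.max())
            y_min, y_max = float(points.y.min()), float(points.y.max())
        else:
            x_min, x_max, y_min, y_max = map(float, extents)
        sx = (x_max - x_min) / 2 or 1.0
        sy = (y_max - y_min) / 2 or 1.0
        tr = AffineXY((x_min + x_max) / 2, sx, (y_min + y_max) / 2, sy)
    else:
        tr = AffineXY()
    u, v = tr.forward(points.x, points.y)
    return PolyDesign(_monomials(u, v, k), points.z.astype(float), k, tr, alpha)


def fit_surface(design: PolyDesign, alpha: float | None = None, label: int = 1) -> PolySurface:
    """Solve the ridge problem; the intercept column is unpenalized.

    With ``alpha = 0`` and a full-rank design this is the ordinary
    least-squares solution.
    """
    if alpha is None:
        alpha = design.alpha
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    X, z = design.X, design.z
    penalty = np.eye(X.shape[1])
    penalty[0, 0] = 0.0  # intercept (a=b=0 is the first lexicographic monomial)
    A = X.T @ X + alpha * penalty
    b = X.T @ z
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are singular (rank-deficient design); "
            "set alpha > 0 to regularize"
        ) from exc
    if alpha == 0:
        # np.linalg.solve may succeed numerically on nearly singular systems;
        # verify the unregularized solve is trustworthy.
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError(
                "design is numerically rank-deficient; set alpha > 0 to regularize"
            )
    return PolySurface(design.degree, w, 0.0, label, design.transform)


def fit_points(
    points: ForegroundPoints,
    k: int = DEFAULT_DEGREE,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
    extents: tuple[float, float, float, float] | None = None,
    label: int = 1,
) -> PolySurface:
    """Convenience: ``fit_surface(build_design(...))``."""
    return fit_surface(build_design(points, k, normalize, extents, alpha), alpha, label)


def evaluate_surface(s: PolySurface, x, y):
    """``f(x, y) + dz`` in raw voxel coordinates (scalars or broadcastable arrays)."""
    u, v = s.transform.forward(x, y)
    u, v = np.broadcast_arrays(u, v)
    out = np.zeros_like(u, dtype=float)
    for (a, b), c in zip(poly_exponents(s.degree), s.coeffs):
        out += c * u**a * v**b
    return out + s.dz


def surface_gradient(s: PolySurface, x0, y0):
    """Analytic ``(df/dx, df/dy)`` in raw voxel coordinates at ``(x0, y0)``."""
    u, v = s.transform.forward(x0, y0)
    u, v = np.broadcast_arrays(u, v)
    gx = np.zeros_like(u, dtype=float)
    gy = np.zeros_like(u, dtype=float)
    for (a, b), c in zip(poly_exponents(s.degree), s.coeffs):
        if a > 0:
            gx += c * a * u ** (a - 1) * v**b
        if b > 0:
            gy += c * b * u**a * v ** (b - 1)
    return gx / s.transform.x_scale, gy / s.transform.y_scale
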