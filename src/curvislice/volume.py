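"""Volume containers and file I/O.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
(or ``(x, y, f)`` for raw spectral cubes), with ``x`` the fast lateral axis,
``y`` the slow lateral axis (one B-scan per ``y`` index) and ``z`` increasing
with depth.  Physical coordinates are ``X = Mx*x``, ``Y = My*y``, ``Z = Mz*z``
with the voxel pitches in micrometres.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelScale",
    "SpectralVolume",
    "IntensityVolume",
    "load_intensity_volume",
    "save_intensity_volume",
    "load_spectral_volume",
]

#: Voxel pitches of the instrument configuration this package was developed
#: against (micrometres per voxel along X, Y, Z).
DEFAULT_SCALE_UM = (4.8828, 19.5312, 4.2068)


@dataclass(frozen=True)
class VoxelScale:
    """Micrometres per voxel along X, Y and depth Z."""

    mx: float
    my: float
    mz: float

    def __post_init__(self) -> None:
        for name in ("mx", "my", "mz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    @classmethod
    def default(cls) -> "VoxelScale":
        return cls(*DEFAULT_SCALE_UM)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelScale":
        return cls(float(d["mx"]), float(d["my"]), float(d["mz"]))


def _check_cube(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"{what} must be a 3D array, got shape {data.shape}")
    if data.size == 0:
        raise ValueError(f"{what} must be non-empty")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite samples")
    if np.any(data < 0):
        raise ValueError(f"{what} contains negative samples")
    return data


@dataclass
class SpectralVolume:
    """Raw interferogram cube indexed ``(x, y, f)`` before reconstruction."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = _check_cube(self.data, "spectral volume")

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nf(self) -> int:
        return self.data.shape[2]


@dataclass
class IntensityVolume:
    """Reconstructed magnitude cube indexed ``(x, y, z)`` with voxel calibration."""

    data: np.ndarray
    scale: VoxelScale

    def __post_init__(self) -> None:
        self.data = _check_cube(self.data, "intensity volume")
        if not isinstance(self.scale, VoxelScale):
            self.scale = VoxelScale.from_dict(dict(self.scale))

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# File I/O
#
# HDF5 layout: dataset "data" with shape (nx, ny, nz|nf) plus attributes
# mx/my/mz.  TIFF layout: one page per B-scan (ny pages), each page is a
# (nz, nx) image so it displays with depth running down.


def save_intensity_volume(vol: IntensityVolume, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=vol.data)
            ds.attrs["mx"] = vol.scale.mx
            ds.attrs["my"] = vol.scale.my
            ds.attrs["mz"] = vol.scale.mz
            ds.attrs["axes"] = "xyz"
    elif path.endswith((".tif", ".tiff")):
        import tifffile

        pages = np.transpose(vol.data, (1, 2, 0)).astype(np.float32)  # (ny, nz, nx)
        tifffile.imwrite(
            path,
            pages,
            photometric="minisblack",
            metadata={"axes": "QYX", "voxel_scale_um": list(vol.scale.to_dict().values())},
        )
    else:
        raise ValueError(f"unsupported volume format: {path}")


def load_intensity_volume(path: str | os.PathLike, scale: VoxelScale | None = None) -> IntensityVolume:
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["data"]
            data = ds[()]
            if scale is None and "mx" in ds.attrs:
                scale = VoxelScale(float(ds.attrs["mx"]), float(ds.attrs["my"]), float(ds.attrs["mz"]))
    elif path.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(path)
        if pages.ndim == 2:  # single B-scan
            pages = pages[None]
        data = np.transpose(pages, (2, 0, 1))  # (nx, ny, nz)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if scale is None:
        scale = VoxelScale.default()
    return IntensityVolume(np.asarray(data, dtype=float), scale)


def load_spectral_volume(path: str | os.PathLike) -> SpectralVolume:
    """Load a raw spectral cube.

    Supported inputs: an HDF5 file with a 3D ``data`` dataset, or a raw binary
    file accompanied by a YAML sidecar ``<path>.yaml`` declaring ``shape``
    (``[nx, ny, nf]``), ``dtype`` (numpy name, e.g. ``uint16``), ``byteorder``
    (``little``/``big``) and optionally ``axis_order`` (a permutation of
    ``"xyf"``, default ``"xyf"``).
    """
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
        return SpectralVolume(np.asarray(data, dtype=float))

    sidecar = path + ".yaml"
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"raw cube {path} needs a YAML sidecar {sidecar}")
    import yaml

    with open(sidecar) as f:
        hdr = yaml.safe_load(f)
    shape = tuple(int(s) for s in hdr["shape"])
    dtype = np.dtype(hdr["dtype"])
    if hdr.get("byteorder", "little") == "big":
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != int(np.prod(shape)):
        raise ValueError(f"raw file holds {raw.size} samples, header implies {np.prod(shape)}")
    data = raw.reshape(shape).astype(float)
    order = hdr.get("axis_order", "xyf")
    if sorted(order) != ["f", "x", "y"]:
        raise ValueError(f"axis_order must be a permutation of 'xyf', got {order!r}")
    data = np.transpose(data, tuple(order.index(ax) for ax in "xyf"))
    return SpectralVolume(data)
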