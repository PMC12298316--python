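"""Spectral-domain reconstruction: raw interferogram cubes to intensity volumes.

Each A-line is an interference spectrum riding on the source spectrum.  The
source is estimated per B-scan plane as the per-frequency median over all
A-lines in that plane, subtracted, windowed with a Hann taper to limit
spectral leakage, and Fourier transformed along the frequency axis.  A real
signal produces a mirrored depth profile, so only the first half of the
transform is kept: ``nf`` frequency samples yield ``nf / 2`` depth voxels.
Repeat scans of the same sample can be averaged voxel-wise, improving SNR by
the square root of the scan count.

No wavelength-to-wavenumber resampling or dispersion compensation is applied;
the transform axis is treated as uniformly sampled.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .volume import IntensityVolume, SpectralVolume, VoxelScale

__all__ = ["estimate_source_spectrum", "reconstruct_volume", "average_volumes"]


def estimate_source_spectrum(vol: SpectralVolume, y_index: int) -> np.ndarray:
    """Per-frequency median over all A-lines of the X-frequency plane at ``y_index``."""
    if not -vol.ny <= y_index < vol.ny:
        raise IndexError(f"y_index {y_index} out of range for ny={vol.ny}")
    return np.median(vol.data[:, y_index, :], axis=0)


def reconstruct_volume(vol: SpectralVolume, scale: VoxelScale) -> IntensityVolume:
    """Source-subtract, Hann-window and Fourier transform every A-line.

    Keeps the magnitude of DFT bins ``0 .. nf/2 - 1`` (the mirror half is
    discarded), so the output depth axis has ``nf / 2`` voxels.
    """
    nf = vol.nf
    if nf % 2 != 0 or nf < 4:
        raise ValueError(f"nf must be even and >= 4, got {nf}")
    window = np.hanning(nf)
    nz = nf // 2
    out = np.empty((vol.nx, vol.ny, nz), dtype=float)
    for y in range(vol.ny):
        plane = vol.data[:, y, :]
        source = np.median(plane, axis=0)
        windowed = (plane - source) * window
        spectrum = np.fft.fft(windowed, axis=1)
        out[:, y, :] = np.abs(spectrum[:, :nz])
    return IntensityVolume(out, scale)


def average_volumes(vols: Sequence[IntensityVolume]) -> IntensityVolume:
    """Voxel-wise arithmetic mean of co-registered magnitude volumes."""
    if len(vols) == 0:
        raise ValueError("need at least one volume to average")
    first = vols[0]
    for v in vols[1:]:
        if v.data.shape != first.data.shape:
            raise ValueError(
                f"volume shape mismatch: {v.data.shape} vs {first.data.shape}"
            )
        if v.scale != first.scale:
            raise ValueError("volumes have differing voxel scales")
    mean = np.mean([v.data for v in vols], axis=0)
    return IntensityVolume(mean, first.scale)
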