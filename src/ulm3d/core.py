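"""Shared domain types and acquisition-parameter arithmetic.

Conventions used throughout the package:

* axes are ``(x, y, z)`` with x, y lateral and z depth (increasing away
  from the probe, dorsal to ventral);
* all continuous positions are in millimetres, voxel indices are 0-based;
* a voxel's world position is its **centre**: ``origin + (i + 0.5) * pitch``;
* binning a point into a voxel is half-open on the upper face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "VoxelGrid",
    "IQSeries",
    "PSFModel",
    "volume_rate",
    "mechanical_index",
    "min_track_duration_ms",
    "max_link_distance",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero to ``decimals`` places (0.35 -> 0.4 at 1 dp).

    Used for every "reported" companion value; banker's rounding would
    report MI(1 MPa, 10 MHz) = 0.316... as 0.3 either way but differs on
    exact halves.
    """
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def volume_rate(prf_hz: float, n_compound: int) -> float:
    """Compounded volume rate in Hz: PRF divided by plane waves per volume."""
    if prf_hz <= 0:
        raise ValueError(f"prf_hz must be positive, got {prf_hz}")
    if n_compound < 1:
        raise ValueError(f"n_compound must be >= 1, got {n_compound}")
    return prf_hz / n_compound


def mechanical_index(
    peak_rarefaction_mpa: float, center_freq_mhz: float
) -> tuple[float, float]:
    """Mechanical index P[MPa]/sqrt(f[MHz]).

    Returns ``(exact, reported)`` where ``reported`` is rounded
    half-away-from-zero to one decimal.
    """
    if peak_rarefaction_mpa <= 0 or center_freq_mhz <= 0:
        raise ValueError("pressure and frequency must be positive")
    mi = peak_rarefaction_mpa / math.sqrt(center_freq_mhz)
    return mi, round_half_away(mi, 1)


def min_track_duration_ms(min_frames: int, volume_rate_hz: float) -> tuple[float, int]:
    """Duration of the shortest accepted track, as (exact ms, rounded ms)."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if volume_rate_hz <= 0:
        raise ValueError("volume_rate_hz must be positive")
    ms = min_frames / volume_rate_hz * 1000.0
    return ms, int(round_half_away(ms, 0))


def max_link_distance(max_speed_mm_s: float, volume_rate_hz: float) -> float:
    """Inter-frame displacement (mm) of a bubble at ``max_speed_mm_s``.

    The tracking gate itself is configured directly as a distance
    (default 0.13 mm); this helper converts a speed into that distance.
    """
    if max_speed_mm_s <= 0 or volume_rate_hz <= 0:
        raise ValueError("speed and rate must be positive")
    return max_speed_mm_s / volume_rate_hz


@dataclass(frozen=True)
class AcquisitionParams:
    """Ultrafast acquisition parameters.

    Defaults are a 12 kHz PRF compounded over 16 tilted plane waves
    (750 volumes/s), 10 MHz transmit at 1 MPa peak rarefaction pressure,
    blocks of 300 volumes processed in SVD sub-blocks of 150.
    """

    prf_hz: float = 12_000.0
    n_compound: int = 16
    center_freq_mhz: float = 10.0
    peak_rarefaction_mpa: float = 1.0
    block_len: int = 300
    subblock_len: int = 150

    def __post_init__(self):
        volume_rate(self.prf_hz, self.n_compound)  # validates
        if self.block_len < 1 or self.subblock_len < 1:
            raise ValueError("block_len and subblock_len must be >= 1")
        if self.block_len % self.subblock_len != 0:
            raise ValueError(
                f"subblock_len ({self.subblock_len}) must divide "
                f"block_len ({self.block_len})"
            )

    @property
    def volume_rate_hz(self) -> float:
        return volume_rate(self.prf_hz, self.n_compound)

    @property
    def mi(self) -> float:
        return mechanical_index(self.peak_rarefaction_mpa, self.center_freq_mhz)[0]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D grid; world position of voxel ``i`` is ``origin + (i+0.5)*pitch``."""

    origin_mm: tuple[float, float, float]
    pitch_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(p <= 0 for p in self.pitch_mm):
            raise ValueError(f"pitch must be strictly positive, got {self.pitch_mm}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape extents must be >= 1, got {self.shape}")
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "pitch_mm", tuple(float(v) for v in self.pitch_mm))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def pitch(self) -> np.ndarray:
        return np.asarray(self.pitch_mm, dtype=float)

    def voxel_center(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel centre(s); index shape (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx + 0.5) * self.pitch

    def voxel_of(self, point_mm) -> np.ndarray:
        """Voxel index containing world point(s); half-open on the upper face."""
        p = np.asarray(point_mm, dtype=float)
        return np.floor((p - self.origin) / self.pitch).astype(np.int64)

    def contains(self, point_mm) -> np.ndarray:
        idx = self.voxel_of(point_mm)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    def world_to_continuous(self, point_mm) -> np.ndarray:
        """Fractional voxel coordinates (voxel centre i maps to i exactly)."""
        p = np.asarray(point_mm, dtype=float)
        return (p - self.origin) / self.pitch - 0.5

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.pitch

    def refined(self, factor: int) -> "VoxelGrid":
        """Grid whose voxel centres include every centre of this grid.

        Pitch is divided by ``factor``; the origin shifts by
        ``pitch/2 - pitch/(2 factor)`` so refined centre ``factor*i``
        coincides with original centre ``i``; shape is ``factor*(n-1)+1``.
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError("factor must be a positive integer")
        factor = int(factor)
        if factor == 1:
            return self
        pitch = self.pitch / factor
        origin = self.origin + self.pitch / 2 - pitch / 2
        shape = tuple(factor * (n - 1) + 1 for n in self.shape)
        return VoxelGrid(tuple(origin), tuple(pitch), shape)


@dataclass
class IQSeries:
    """Complex beamformed IQ volumes indexed ``(x, y, z, t)``."""

    data: np.ndarray
    grid: VoxelGrid
    volume_rate_hz: float
    block_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid {self.grid.shape}"
            )
        if self.data.shape[3] < 1:
            raise ValueError("time extent must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IQ data contains non-finite values")
        if self.volume_rate_hz <= 0:
            raise ValueError("volume_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def magnitude(self, t: int) -> np.ndarray:
        return np.abs(self.data[..., t])


@dataclass(frozen=True)
class PSFModel:
    """Anisotropic 3D Gaussian point-spread model, sigmas in mm."""

    sigma_mm: tuple[float, float, float] = (0.4, 0.4, 0.17)

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma_mm):
            raise ValueError("all sigmas must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return np.asarray(self.sigma_mm, dtype=float)

    def amplitude(self, offsets_mm: np.ndarray) -> np.ndarray:
        """Gaussian amplitude at displacement(s) from the scatterer centre."""
        d = np.asarray(offsets_mm, dtype=float)
        return np.exp(-0.5 * np.sum((d / self.sigma) ** 2, axis=-1))


# Default grids: acquisition pitch before interpolation, and the paper-scale
# post-interpolation pitch used by the phantom (0.1 x 0.1 x 0.04 mm).
DEFAULT_ACQ_PITCH_MM = (0.197, 0.197, 0.0739)
DEFAULT_PHANTOM_GRID = VoxelGrid(
    origin_mm=(0.0, 0.0, 0.0), pitch_mm=(0.1, 0.1, 0.04), shape=(64, 64, 64)
)
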