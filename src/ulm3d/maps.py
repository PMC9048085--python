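"""Super-resolved volumetric density and velocity maps from bubble tracks.

Tracks are first resampled along their arc length at a fine step (20 um by
default) so a fast bubble does not leave gaps on a fine grid.  Density
counts distinct voxel traversals per track; velocity maps average the
chosen quantity per track within each voxel and then across tracks, so a
slow bubble dwelling in a voxel carries the same weight as a fast one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import VoxelGrid
from .tracking import Track

__all__ = [
    "VolumetricMap",
    "interpolate_track",
    "accumulate_density",
    "accumulate_velocity",
    "mip",
]

MapKind = Literal["density", "velocity_x", "velocity_y", "velocity_z", "velocity_amplitude"]


@dataclass
class VolumetricMap:
    grid: VoxelGrid
    kind: str
    values: np.ndarray
    count: np.ndarray
    n_dropped: int = 0  # points falling outside the grid

    @property
    def empty_mask(self) -> np.ndarray:
        return self.count == 0


def interpolate_track(track: Track, step_mm: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resampling of a track at ``step_mm``.

    Returns ``(positions, velocities)``; positions sampled every
    ``step_mm`` along the polyline (endpoints included), velocities
    linearly interpolated between the bracketing original samples.
    """
    if track.n_samples < 2:
        raise ValueError("track needs at least 2 samples")
    p = track.positions_mm
    v = track.velocities_mm_s
    if v is None:
        raise ValueError("track has no velocities; call compute_velocities first")
    seg_len = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    if total == 0:
        return p[:1].copy(), v[:1].copy()
    samples = np.arange(0.0, total, step_mm)
    samples = np.append(samples, total)
    pos = np.column_stack([np.interp(samples, s, p[:, a]) for a in range(3)])
    vel = np.column_stack([np.interp(samples, s, v[:, a]) for a in range(3)])
    return pos, vel


def _select_quantity(vel: np.ndarray, kind: str) -> np.ndarray:
    if kind == "velocity_amplitude":
        return np.linalg.norm(vel, axis=1)
    axis = {"velocity_x": 0, "velocity_y": 1, "velocity_z": 2}.get(kind)
    if axis is None:
        raise ValueError(f"unknown velocity map kind: {kind}")
    return vel[:, axis]


def accumulate_density(
    tracks: list[Track],
    grid: VoxelGrid,
    step_mm: float = 0.02,
    *,
    dedup_traversal: bool = True,
) -> VolumetricMap:
    """Bubble-count density map.

    With ``dedup_traversal`` (default) consecutive resampled points of one
    track falling in the same voxel count once per traversal; re-entering
    a voxel later counts again.  With it off, every resampled point
    counts (pure-sample mode).
    """
    counts = np.zeros(grid.shape, dtype=np.int64)
    shape = np.asarray(grid.shape)
    dropped = 0
    for tr in tracks:
        pos, _ = interpolate_track(tr, step_mm)
        idx = grid.voxel_of(pos)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        dropped += int((~inside).sum())
        idx = idx[inside]
        if len(idx) == 0:
            continue
        if dedup_traversal:
            keep = np.ones(len(idx), dtype=bool)
            keep[1:] = np.any(idx[1:] != idx[:-1], axis=1)
            idx = idx[keep]
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return VolumetricMap(grid, "density", counts, counts.copy(), dropped)


def accumulate_velocity(
    tracks: list[Track],
    grid: VoxelGrid,
    kind: MapKind = "velocity_amplitude",
    step_mm: float = 0.02,
) -> VolumetricMap:
    """Velocity map: per voxel, the mean over tracks of each track's own
    mean of the selected quantity inside that voxel.

    ``count`` holds the number of distinct contributing tracks; voxels
    with count 0 are empty (NaN), not zero.
    """
    sums = np.zeros(grid.shape, dtype=float)
    n_tracks = np.zeros(grid.shape, dtype=np.int64)
    shape = np.asarray(grid.shape)
    dropped = 0
    for tr in tracks:
        pos, vel = interpolate_track(tr, step_mm)
        q = _select_quantity(vel, kind)
        idx = grid.voxel_of(pos)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        dropped += int((~inside).sum())
        idx, q = idx[inside], q[inside]
        if len(idx) == 0:
            continue
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.shape)
        uniq, inv = np.unique(flat, return_inverse=True)
        per_voxel = np.zeros(len(uniq))
        per_count = np.zeros(len(uniq))
        np.add.at(per_voxel, inv, q)
        np.add.at(per_count, inv, 1.0)
        track_mean = per_voxel / per_count  # this track's mean in each voxel
        ux, uy, uz = np.unravel_index(uniq, grid.shape)
        sums[ux, uy, uz] += track_mean
        n_tracks[ux, uy, uz] += 1
    values = np.full(grid.shape, np.nan)
    filled = n_tracks > 0
    values[filled] = sums[filled] / n_tracks[filled]
    return VolumetricMap(grid, kind, values, n_tracks, dropped)


def mip(vmap: VolumetricMap, axis: int) -> np.ndarray:
    """Maximum-intensity projection along one axis (NaN-safe)."""
    data = vmap.values
    if np.issubdtype(data.dtype, np.floating):
        with np.errstate(all="ignore"):
            out = np.nanmax(np.where(np.isnan(data), -np.inf, data), axis=axis)
        out[out == -np.inf] = np.nan
        return out
    return data.max(axis=axis)
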