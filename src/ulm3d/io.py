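"""File formats: NIfTI / TIFF volumes with JSON sidecars, CSV tables for
localizations and tracks, JSON for transforms, trees and configs.

Complex IQ is persisted as a two-channel real NIfTI (real, imag stacked on
a trailing axis) with a sidecar flag, because downstream viewers honour
complex NIfTI inconsistently.  All voxel pitches and rates round-trip at
full float precision through the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import IQSeries, VoxelGrid
from .localization import MBLocalization
from .maps import VolumetricMap
from .phantom import GroundTruth, Segment, VascularTree
from .tracking import RigidTransform, Track

__all__ = [
    "write_iq_nifti",
    "read_iq_nifti",
    "write_iq_tiff",
    "read_iq_tiff",
    "write_map_nifti",
    "read_map_nifti",
    "write_localizations_csv",
    "read_localizations_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_transforms_json",
    "read_transforms_json",
    "write_tree_json",
    "read_tree_json",
    "write_ground_truth_csv",
    "read_affine_json",
    "write_affine_json",
]

LOC_COLUMNS = ["block", "t", "x_mm", "y_mm", "z_mm", "magnitude", "ncc"]
TRACK_COLUMNS = ["track_id", "t", "x_mm", "y_mm", "z_mm", "vx", "vy", "vz"]


def _grid_affine(grid: VoxelGrid) -> np.ndarray:
    """NIfTI affine mapping voxel index -> world mm (voxel-centre convention)."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.pitch)
    aff[:3, 3] = grid.origin + grid.pitch / 2
    return aff


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix("").with_suffix(".json") if p.suffix == ".gz" else p.parent / (p.stem + ".json")


def _write_sidecar(path, grid: VoxelGrid, volume_rate_hz: float, block_id: int, is_complex: bool):
    meta = {
        "origin_mm": list(grid.origin_mm),
        "pitch_mm": list(grid.pitch_mm),
        "shape": list(grid.shape),
        "volume_rate_hz": volume_rate_hz,
        "block_id": block_id,
        "complex_two_channel": is_complex,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _read_sidecar(path) -> dict:
    return json.loads(_sidecar_path(path).read_text())


def write_iq_nifti(iq: IQSeries, path) -> None:
    """Complex IQ as a 5D float32 NIfTI (x, y, z, t, [real, imag]) + sidecar."""
    stacked = np.stack([iq.data.real, iq.data.imag], axis=-1).astype(np.float32)
    img = nib.Nifti1Image(stacked, _grid_affine(iq.grid))
    img.header.set_zooms(tuple(iq.grid.pitch) + (1.0 / iq.volume_rate_hz, 1.0))
    nib.save(img, str(path))
    _write_sidecar(path, iq.grid, iq.volume_rate_hz, iq.block_id, True)


def read_iq_nifti(path) -> IQSeries:
    img = nib.load(str(path))
    meta = _read_sidecar(path)
    arr = np.asarray(img.dataobj, dtype=np.float32)
    if not meta.get("complex_two_channel"):
        raise ValueError("sidecar does not flag a two-channel complex volume")
    if arr.ndim != 5 or arr.shape[-1] != 2:
        raise ValueError(f"expected (x, y, z, t, 2) data, got shape {arr.shape}")
    grid = VoxelGrid(tuple(meta["origin_mm"]), tuple(meta["pitch_mm"]), tuple(meta["shape"]))
    if tuple(arr.shape[:3]) != grid.shape:
        raise ValueError("volume shape does not match sidecar grid")
    data = arr[..., 0].astype(np.complex64) + 1j * arr[..., 1].astype(np.complex64)
    return IQSeries(data, grid, meta["volume_rate_hz"], meta["block_id"])


def write_iq_tiff(iq: IQSeries, path) -> None:
    """Complex IQ as a multi-page TIFF ([real, imag], t, z, y, x) + sidecar."""
    stacked = np.stack([iq.data.real, iq.data.imag], axis=0).astype(np.float32)
    tifffile.imwrite(str(path), np.transpose(stacked, (0, 4, 3, 2, 1)))
    _write_sidecar(path, iq.grid, iq.volume_rate_hz, iq.block_id, True)


def read_iq_tiff(path) -> IQSeries:
    meta = _read_sidecar(path)
    arr = tifffile.imread(str(path))
    grid = VoxelGrid(tuple(meta["origin_mm"]), tuple(meta["pitch_mm"]), tuple(meta["shape"]))
    arr = np.transpose(arr, (0, 4, 3, 2, 1))
    data = arr[0].astype(np.complex64) + 1j * arr[1].astype(np.complex64)
    return IQSeries(data, grid, meta["volume_rate_hz"], meta["block_id"])


def write_map_nifti(vmap: VolumetricMap, path) -> None:
    img = nib.Nifti1Image(vmap.values.astype(np.float32), _grid_affine(vmap.grid))
    img.header.set_zooms(tuple(vmap.grid.pitch))
    nib.save(img, str(path))
    meta = {
        "origin_mm": list(vmap.grid.origin_mm),
        "pitch_mm": list(vmap.grid.pitch_mm),
        "shape": list(vmap.grid.shape),
        "kind": vmap.kind,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_map_nifti(path) -> VolumetricMap:
    img = nib.load(str(path))
    meta = _read_sidecar(path)
    grid = VoxelGrid(tuple(meta["origin_mm"]), tuple(meta["pitch_mm"]), tuple(meta["shape"]))
    values = np.asarray(img.dataobj, dtype=float)
    count = (~np.isnan(values)).astype(np.int64) if meta["kind"] != "density" else values.astype(np.int64)
    return VolumetricMap(grid, meta["kind"], values, count)


def write_localizations_csv(locs: list[MBLocalization], path) -> None:
    df = pd.DataFrame(
        [
            {
                "block": l.block_id,
                "t": l.t_index,
                "x_mm": l.position_mm[0],
                "y_mm": l.position_mm[1],
                "z_mm": l.position_mm[2],
                "magnitude": l.magnitude,
                "ncc": l.ncc,
            }
            for l in locs
        ],
        columns=LOC_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_localizations_csv(path) -> list[MBLocalization]:
    df = pd.read_csv(path)
    missing = set(LOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"localization CSV missing columns: {sorted(missing)}")
    return [
        MBLocalization(
            position_mm=np.array([r.x_mm, r.y_mm, r.z_mm]),
            t_index=int(r.t),
            block_id=int(r.block),
            magnitude=float(r.magnitude),
            ncc=float(r.ncc),
        )
        for r in df.itertuples()
    ]


def write_tracks_csv(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        v = tr.velocities_mm_s
        for k in range(tr.n_samples):
            rows.append(
                {
                    "track_id": tr.id,
                    "t": int(tr.t_indices[k]),
                    "x_mm": tr.positions_mm[k, 0],
                    "y_mm": tr.positions_mm[k, 1],
                    "z_mm": tr.positions_mm[k, 2],
                    "vx": v[k, 0] if v is not None else np.nan,
                    "vy": v[k, 1] if v is not None else np.nan,
                    "vz": v[k, 2] if v is not None else np.nan,
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False, float_format="%.9g")


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t")
        tracks.append(
            Track(
                id=int(tid),
                t_indices=g["t"].to_numpy(dtype=int),
                positions_mm=g[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                velocities_mm_s=g[["vx", "vy", "vz"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_transforms_json(transforms: list[RigidTransform], path) -> None:
    payload = [
        {"rotation": t.rotation.tolist(), "translation_mm": t.translation_mm.tolist()}
        for t in transforms
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transforms_json(path) -> list[RigidTransform]:
    payload = json.loads(Path(path).read_text())
    return [
        RigidTransform(np.asarray(t["rotation"]), np.asarray(t["translation_mm"]))
        for t in payload
    ]


def write_tree_json(tree: VascularTree, path) -> None:
    payload = {
        "gamma": tree.gamma,
        "segments": [
            {
                "id": s.id,
                "start_mm": s.start_mm.tolist(),
                "end_mm": s.end_mm.tolist(),
                "radius_mm": s.radius_mm,
                "parent_id": s.parent_id,
                "flow_mm3_s": s.flow_mm3_s,
            }
            for s in tree.segments
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_tree_json(path) -> VascularTree:
    payload = json.loads(Path(path).read_text())
    segs = [
        Segment(
            id=s["id"],
            start_mm=np.asarray(s["start_mm"]),
            end_mm=np.asarray(s["end_mm"]),
            radius_mm=s["radius_mm"],
            parent_id=s["parent_id"],
            flow_mm3_s=s["flow_mm3_s"],
        )
        for s in payload["segments"]
    ]
    return VascularTree(segments=segs, gamma=payload["gamma"])


def write_ground_truth_csv(gt: GroundTruth, path) -> None:
    rows = []
    for b in gt.bubbles:
        for k in range(len(b.t_indices)):
            rows.append(
                {
                    "id": b.id,
                    "t": int(b.t_indices[k]),
                    "x": b.positions_mm[k, 0],
                    "y": b.positions_mm[k, 1],
                    "z": b.positions_mm[k, 2],
                    "vx": b.velocities_mm_s[k, 0],
                    "vy": b.velocities_mm_s[k, 1],
                    "vz": b.velocities_mm_s[k, 2],
                    "segment": int(b.segment_ids[k]),
                }
            )
    pd.DataFrame(rows, columns=["id", "t", "x", "y", "z", "vx", "vy", "vz", "segment"]).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_affine_json(affine: np.ndarray, path) -> None:
    a = np.asarray(affine, dtype=float)
    if a.shape not in ((3, 4), (4, 4)):
        raise ValueError("affine must be 3x4 or 4x4")
    Path(path).write_text(json.dumps({"affine": a[:3].tolist()}, indent=2))


def read_affine_json(path) -> np.ndarray:
    a = np.asarray(json.loads(Path(path).read_text())["affine"], dtype=float)
    if a.shape != (3, 4):
        raise ValueError("affine JSON must hold a 3x4 matrix")
    return a
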