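"""End-to-end pipeline: phantom -> SVD filter -> localize -> track ->
motion-correct -> maps -> quantify, with a JSON-serializable configuration
and a per-stage report.

One master seed drives every stage; per-stage streams are derived
deterministically from it, so a fixed seed reproduces the run byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as ulmio
from .clutterfilter import SVDFilterConfig, svd_filter
from .core import PSFModel, VoxelGrid
from .localization import DetectionConfig, localize_series
from .maps import accumulate_density, accumulate_velocity
from .phantom import (
    ClutterModel,
    assign_flows,
    generate_tree,
    render_iq,
    simulate_bubbles,
)
from .quantify import (
    centerline_velocity,
    fit_power_law,
    skeletonize_with_radius,
    smooth_binarize,
)
from .tracking import ICPConfig, TrackingConfig, build_tracks, compute_velocities, motion_correct

__all__ = ["PhantomConfig", "PipelineConfig", "run_all", "derive_seed"]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class PhantomConfig:
    depth: int = 2
    root_radius_mm: float = 0.06
    gamma: float = 3.0
    asymmetry: float = 1.0
    root_v_max_mm_s: float = 50.0
    seeding_rate_hz: float = 30.0
    n_blocks: int = 2
    block_len: int = 150
    volume_rate_hz: float = 750.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_pitch_mm: tuple[float, float, float] = (0.1, 0.1, 0.04)
    grid_origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    clutter_db: float = 30.0
    noise_db: float = -40.0
    drift_um_per_min: float = 20.0
    spatial_corr_mm: float = 0.5

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_origin_mm, self.grid_pitch_mm, self.grid_shape)

    @property
    def duration_s(self) -> float:
        return self.n_blocks * self.block_len / self.volume_rate_hz


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    psf_sigma_mm: tuple[float, float, float] = (0.4, 0.4, 0.17)
    svd: SVDFilterConfig = field(default_factory=SVDFilterConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    icp: ICPConfig = field(default_factory=ICPConfig)
    mocorr_group_len: int = 20
    map_pitch_mm: float = 0.02

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "phantom": PhantomConfig,
            "svd": SVDFilterConfig,
            "detection": DetectionConfig,
            "tracking": TrackingConfig,
            "icp": ICPConfig,
        }
        kwargs = {}
        for key, kcls in sub.items():
            if key in d:
                kwargs[key] = _from_dict(kcls, d.pop(key))
        base = _from_dict(cls, d)
        return dataclasses.replace(base, **kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_all(cfg: PipelineConfig, out_dir) -> dict:
    """Run the whole chain on a freshly generated phantom; write artifacts
    and return the report dictionary (also saved as report.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "versions": _versions(),
        "stages": {},
    }
    pc = cfg.phantom
    psf = PSFModel(cfg.psf_sigma_mm)

    # --- phantom ---
    grid = pc.grid
    box = (grid.origin + 0.35, grid.origin + grid.extent_mm - 0.35)
    tree = generate_tree(
        pc.depth,
        pc.root_radius_mm,
        pc.gamma,
        pc.asymmetry,
        seed=derive_seed(cfg.seed, "tree"),
        root_start_mm=grid.origin + grid.extent_mm * np.array([0.5, 0.5, 0.0]) + np.array([0, 0, 0.4]),
        bounding_box=box,
    )
    inlet = pc.root_v_max_mm_s / 2.0 * np.pi * pc.root_radius_mm**2
    assign_flows(tree, inlet)
    gt = simulate_bubbles(
        tree,
        pc.seeding_rate_hz,
        pc.duration_s,
        pc.volume_rate_hz,
        seed=derive_seed(cfg.seed, "bubbles"),
    )
    clutter = ClutterModel(pc.clutter_db, pc.spatial_corr_mm, pc.noise_db, pc.drift_um_per_min)
    blocks = render_iq(gt, grid, psf, clutter, seed=derive_seed(cfg.seed, "render"), block_len=pc.block_len)
    ulmio.write_tree_json(tree, out / "tree.json")
    ulmio.write_ground_truth_csv(gt, out / "ground_truth.csv")
    report["stages"]["phantom"] = {
        "n_segments": len(tree.segments),
        "n_bubbles": len(gt.bubbles),
        "n_blocks": len(blocks),
        "n_frames": gt.n_frames,
    }

    # --- filter + localize (per block) ---
    locs = []
    for blk in blocks:
        filtered = svd_filter(blk, cfg.svd)
        locs.extend(localize_series(filtered, psf, cfg.detection))
    ulmio.write_localizations_csv(locs, out / "localizations.csv")
    report["stages"]["localization"] = {"n_localizations": len(locs)}

    # --- motion correction (needs >= 2 groups; otherwise pass-through) ---
    n_groups = int(np.ceil(len(blocks) / cfg.mocorr_group_len))
    if n_groups >= 2:
        locs, transforms = motion_correct(locs, cfg.mocorr_group_len, cfg.icp)
        ulmio.write_transforms_json(transforms, out / "transforms.json")
        report["stages"]["motion_correction"] = {
            "n_groups": len(transforms),
            "translations_mm": [t.translation_mm.tolist() for t in transforms],
        }
    else:
        report["stages"]["motion_correction"] = {"n_groups": n_groups, "skipped": True}

    # --- tracking ---
    tracks = build_tracks(locs, cfg.tracking)
    for tr in tracks:
        compute_velocities(tr, pc.volume_rate_hz)
    ulmio.write_tracks_csv(tracks, out / "tracks.csv")
    speeds = (
        np.concatenate([np.linalg.norm(t.velocities_mm_s, axis=1) for t in tracks])
        if tracks
        else np.empty(0)
    )
    report["stages"]["tracking"] = {
        "n_tracks": len(tracks),
        "max_speed_mm_s": float(speeds.max()) if len(speeds) else None,
    }

    # --- maps on a grid tight around the vasculature ---
    lo, hi = tree.bounding_box()
    margin = 0.1
    pitch = cfg.map_pitch_mm
    mshape = tuple(int(np.ceil((h - l + 2 * margin) / pitch)) for l, h in zip(lo, hi))
    mgrid = VoxelGrid(tuple(lo - margin), (pitch,) * 3, mshape)
    density = accumulate_density(tracks, mgrid)
    velocity = accumulate_velocity(tracks, mgrid, "velocity_amplitude")
    ulmio.write_map_nifti(density, out / "density.nii")
    ulmio.write_map_nifti(velocity, out / "velocity.nii")
    report["stages"]["maps"] = {
        "grid_shape": list(mshape),
        "total_count": int(density.values.sum()),
    }

    # --- quantification ---
    quant: dict = {}
    if tracks:
        mask = smooth_binarize(density, threshold=0.5)
        graph = skeletonize_with_radius(mask, mgrid)
        if graph.points:
            centerline_velocity(graph, velocity)
            table = graph.segment_table()
            quant["n_centerline_points"] = len(graph.points)
            quant["n_segments"] = len(table)
            pairs = [
                (r["radius_mm"], r["flow_mm3_s"])
                for r in table
                if np.isfinite(r["flow_mm3_s"]) and r["n_points"] >= 3
            ]
            if len(pairs) >= 3:
                try:
                    fit = fit_power_law(pairs)
                    quant["power_law_exponent"] = fit.exponent
                    quant["power_law_r2"] = fit.r_squared
                except ValueError:
                    pass
            import pandas as pd

            pd.DataFrame(table).to_csv(out / "segments.csv", index=False)
    report["stages"]["quantify"] = quant

    report["elapsed_s"] = time.time() - t_start
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _versions() -> dict:
    import nibabel
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "skimage": skimage.__version__,
        "nibabel": nibabel.__version__,
    }
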