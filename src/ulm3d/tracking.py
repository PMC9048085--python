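"""Frame-to-frame bubble linking, track assembly, Lagrangian velocities,
and ICP-based inter-block motion correction.

Linking solves an optimal one-to-one assignment (Kuhn-Munkres) on squared
Euclidean distance with a hard gate: pairs farther apart than the gate
distance are non-assignable.  Among matchings respecting the gate, the
result has maximum cardinality and, among those, minimum total squared
distance.  Tracks are grown greedily frame by frame (unmatched detections
open new tracks, unextended tracks close) and tracks shorter than the
minimum frame count are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .localization import MBLocalization

__all__ = [
    "TrackingConfig",
    "Track",
    "RigidTransform",
    "ICPConfig",
    "link_frames",
    "build_tracks",
    "compute_velocities",
    "icp_register",
    "motion_correct",
]


@dataclass(frozen=True)
class TrackingConfig:
    max_link_mm: float = 0.13
    min_frames: int = 4

    def __post_init__(self):
        if self.max_link_mm <= 0:
            raise ValueError("max_link_mm must be positive")
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")


@dataclass
class Track:
    id: int
    t_indices: np.ndarray  # (n,) consecutive frame indices
    positions_mm: np.ndarray  # (n, 3)
    velocities_mm_s: np.ndarray | None = None  # (n, 3)
    block_id: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.t_indices)


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation_mm

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation_mm)


def link_frames(
    frame_i: np.ndarray, frame_j: np.ndarray, cfg: TrackingConfig
) -> list[tuple[int, int]]:
    """Optimal gated one-to-one matching between two frames of positions.

    Returns index pairs ``(i, j)``; pairs whose Euclidean distance exceeds
    ``cfg.max_link_mm`` never appear.  Implemented by Kuhn-Munkres on the
    squared-distance matrix with a large finite penalty on gated-out
    entries, which yields the maximum-cardinality minimum-cost matching.
    """
    a = np.asarray(frame_i, dtype=float).reshape(-1, 3)
    b = np.asarray(frame_j, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return []
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    gate2 = cfg.max_link_mm**2
    feasible = d2 <= gate2
    if not feasible.any():
        return []
    # penalty larger than the total cost of any all-feasible matching, so
    # the solver first maximizes the number of within-gate links
    big = gate2 * (min(len(a), len(b)) + 1) * 10.0
    cost = np.where(feasible, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


def build_tracks(
    locs: list[MBLocalization], cfg: TrackingConfig | None = None
) -> list[Track]:
    """Assemble localizations into tracks by looping the linker over frames.

    Matched detections extend tracks, unmatched ones start new tracks,
    unextended tracks close; tracks with fewer than ``cfg.min_frames``
    samples are then discarded.  Tracks never cross block boundaries.
    """
    if cfg is None:
        cfg = TrackingConfig()
    tracks: list[Track] = []
    next_id = 0
    for block_id in sorted({l.block_id for l in locs}):
        block_locs = [l for l in locs if l.block_id == block_id]
        by_frame: dict[int, list[MBLocalization]] = {}
        for l in block_locs:
            by_frame.setdefault(l.t_index, []).append(l)
        frames = sorted(by_frame)
        active: list[list[MBLocalization]] = []  # open tracks (sample lists)
        closed: list[list[MBLocalization]] = []
        prev_t: int | None = None
        for t in frames:
            dets = by_frame[t]
            if prev_t is None or t != prev_t + 1 or not active:
                closed.extend(active)
                active = [[d] for d in dets]
            else:
                tails = np.array([tr[-1].position_mm for tr in active])
                heads = np.array([d.position_mm for d in dets])
                pairs = link_frames(tails, heads, cfg)
                matched_tracks = {i for i, _ in pairs}
                matched_dets = {j for _, j in pairs}
                new_active = []
                for i, j in sorted(pairs):
                    active[i].append(dets[j])
                    new_active.append(active[i])
                for i, tr in enumerate(active):
                    if i not in matched_tracks:
                        closed.append(tr)
                for j, d in enumerate(dets):
                    if j not in matched_dets:
                        new_active.append([d])
                active = new_active
            prev_t = t
        closed.extend(active)
        for samples in closed:
            if len(samples) < cfg.min_frames:
                continue
            tracks.append(
                Track(
                    id=next_id,
                    t_indices=np.array([s.t_index for s in samples]),
                    positions_mm=np.array([s.position_mm for s in samples]),
                    block_id=block_id,
                )
            )
            next_id += 1
    return tracks


def compute_velocities(track: Track, volume_rate_hz: float) -> Track:
    """Lagrangian velocities: forward differences, backward at the last sample."""
    if track.n_samples < 2:
        raise ValueError("velocity needs at least 2 samples")
    p = track.positions_mm
    v = np.empty_like(p)
    v[:-1] = (p[1:] - p[:-1]) * volume_rate_hz
    v[-1] = (p[-1] - p[-2]) * volume_rate_hz
    track.velocities_mm_s = v
    return track


@dataclass(frozen=True)
class ICPConfig:
    max_corr_mm: float = 0.1  # correspondence rejection radius
    max_iter: int = 100  # correspondence churn near the optimum makes the
    # final 0.1 um approach slow; 50 iterations is occasionally not enough
    tol_mm: float = 1e-4  # convergence when the update moves points < 0.1 um
    max_points: int = 50_000


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform src -> dst (cross-covariance SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cd - r @ cs)


def icp_register(
    source: np.ndarray,
    reference: np.ndarray,
    cfg: ICPConfig | None = None,
    seed: int = 0,
    init: RigidTransform | None = None,
) -> tuple[RigidTransform, bool]:
    """Point-to-point ICP aligning ``source`` onto ``reference``.

    Correspondences are nearest neighbours within ``cfg.max_corr_mm``;
    each iteration applies the closed-form rigid update; convergence when
    the update displaces points by less than ``cfg.tol_mm``.  Returns the
    transform and a convergence flag (identity + False on failure).
    """
    if cfg is None:
        cfg = ICPConfig()
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    if len(src) > cfg.max_points:
        src = src[rng.choice(len(src), cfg.max_points, replace=False)]
    if len(ref) > cfg.max_points:
        ref = ref[rng.choice(len(ref), cfg.max_points, replace=False)]
    tree = cKDTree(ref)
    transform = init if init is not None else RigidTransform.identity()
    moved = transform.apply(src)
    for _ in range(cfg.max_iter):
        dist, nn = tree.query(moved, distance_upper_bound=cfg.max_corr_mm)
        mask = np.isfinite(dist)
        if mask.sum() < 3:
            return RigidTransform.identity(), False
        update = _kabsch(moved[mask], ref[nn[mask]])
        new_moved = update.apply(moved)
        transform = update.compose(transform)
        step = np.max(np.linalg.norm(new_moved - moved, axis=1))
        moved = new_moved
        if step < cfg.tol_mm:
            return transform, True
    warnings.warn("ICP did not converge within max_iter; returning identity")
    return RigidTransform.identity(), False


def motion_correct(
    locs: list[MBLocalization],
    group_len: int = 20,
    icp_cfg: ICPConfig | None = None,
) -> tuple[list[MBLocalization], list[RigidTransform]]:
    """Register each group of ``group_len`` blocks onto the first group.

    Block-wise MB position clouds are pooled into groups; each later
    group's cloud is aligned to the first group's by ICP and the
    estimated rigid transform is applied to its localizations.
    Returns corrected localizations and the per-group transforms
    (identity for the reference group).
    """
    block_ids = sorted({l.block_id for l in locs})
    if not block_ids:
        return [], []
    groups = [block_ids[i : i + group_len] for i in range(0, len(block_ids), group_len)]
    if len(groups) < 2:
        return list(locs), [RigidTransform.identity()] * len(groups)
    by_group: list[list[MBLocalization]] = []
    for g in groups:
        gset = set(g)
        by_group.append([l for l in locs if l.block_id in gset])
    for g in by_group:
        if len(g) < 10:
            raise ValueError("each group needs at least 10 localizations")
    ref_cloud = np.array([l.position_mm for l in by_group[0]])
    transforms = [RigidTransform.identity()]
    corrected: list[MBLocalization] = list(by_group[0])
    prev_tf = RigidTransform.identity()
    for gi in range(1, len(by_group)):
        cloud = np.array([l.position_mm for l in by_group[gi]])
        # cumulative drift can exceed the correspondence radius; warm-start
        # each group from the previous group's transform so only the small
        # group-to-group increment must be found from correspondences
        tf, _converged = icp_register(cloud, ref_cloud, icp_cfg, seed=gi, init=prev_tf)
        prev_tf = tf
        moved = tf.apply(cloud)
        for l, p in zip(by_group[gi], moved):
            corrected.append(
                MBLocalization(
                    position_mm=p,
                    t_index=l.t_index,
                    block_id=l.block_id,
                    magnitude=l.magnitude,
                    ncc=l.ncc,
                )
            )
        transforms.append(tf)
    return corrected, transforms
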