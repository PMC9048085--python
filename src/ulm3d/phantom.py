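"""Ground-truthed synthetic phantom: Murray-law vascular trees, Poiseuille
bubble transport, and rendered complex IQ volumes with clutter, noise and
slow rigid drift.

The phantom replaces an in vivo acquisition with a scene whose every
quantity is known exactly: vessel geometry and radii obey a generalized
Murray bifurcation law ``r_parent^gamma = sum r_child^gamma``, flow is
conserved at every node and splits proportionally to ``r^gamma``, and each
microbubble is advected along its vessel at the local Poiseuille speed
``v(rho) = V_max (1 - (rho/R)^2)`` for a radial offset ``rho`` drawn
uniform-in-area.  Rendering sums an anisotropic Gaussian echo per bubble on
top of a strong static clutter field plus complex white noise, with an
optional cumulative rigid drift between acquisition blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import IQSeries, PSFModel, VoxelGrid

__all__ = [
    "Segment",
    "VascularTree",
    "BubbleTrajectory",
    "GroundTruth",
    "ClutterModel",
    "generate_tree",
    "single_segment_tree",
    "assign_flows",
    "simulate_bubbles",
    "render_iq",
]


@dataclass
class Segment:
    """One straight vessel segment between two bifurcation points."""

    id: int
    start_mm: np.ndarray
    end_mm: np.ndarray
    radius_mm: float
    parent_id: int | None = None
    flow_mm3_s: float | None = None

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.end_mm - self.start_mm))

    @property
    def axis(self) -> np.ndarray:
        d = self.end_mm - self.start_mm
        return d / np.linalg.norm(d)

    @property
    def v_max_mm_s(self) -> float:
        """Poiseuille centreline velocity 2Q/(pi R^2); mean velocity is half."""
        if self.flow_mm3_s is None:
            raise ValueError("flows not assigned; call assign_flows first")
        return 2.0 * self.flow_mm3_s / (math.pi * self.radius_mm**2)


@dataclass
class VascularTree:
    segments: list[Segment]
    gamma: float

    def children_of(self, seg_id: int) -> list[Segment]:
        return [s for s in self.segments if s.parent_id == seg_id]

    @property
    def root(self) -> Segment:
        (root,) = [s for s in self.segments if s.parent_id is None]
        return root

    @property
    def leaves(self) -> list[Segment]:
        parent_ids = {s.parent_id for s in self.segments}
        return [s for s in self.segments if s.id not in parent_ids]

    def murray_residuals(self) -> list[float]:
        """|r_p^gamma - sum r_c^gamma| at every bifurcation."""
        out = []
        for s in self.segments:
            kids = self.children_of(s.id)
            if kids:
                out.append(
                    abs(s.radius_mm**self.gamma - sum(k.radius_mm**self.gamma for k in kids))
                )
        return out

    def flow_residuals(self) -> list[float]:
        out = []
        for s in self.segments:
            kids = self.children_of(s.id)
            if kids:
                out.append(abs(s.flow_mm3_s - sum(k.flow_mm3_s for k in kids)))
        return out

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.concatenate(
            [[s.start_mm, s.end_mm] for s in self.segments], axis=0
        )
        r = max(s.radius_mm for s in self.segments)
        return pts.min(axis=0) - r, pts.max(axis=0) + r


@dataclass
class BubbleTrajectory:
    id: int
    t_indices: np.ndarray  # (n,) int, consecutive
    positions_mm: np.ndarray  # (n, 3)
    velocities_mm_s: np.ndarray  # (n, 3)
    segment_ids: np.ndarray  # (n,) int


@dataclass
class GroundTruth:
    bubbles: list[BubbleTrajectory]
    tree: VascularTree
    volume_rate_hz: float
    n_frames: int
    drift_mm: np.ndarray | None = None  # (n_blocks, 3) translation per block

    def frame_positions(self, t: int) -> np.ndarray:
        """True (n, 3) positions of all bubbles present in frame ``t``."""
        pts = []
        for b in self.bubbles:
            m = b.t_indices == t
            if m.any():
                pts.append(b.positions_mm[m])
        return np.concatenate(pts, axis=0) if pts else np.empty((0, 3))


@dataclass(frozen=True)
class ClutterModel:
    """Static tissue clutter + noise + drift parameters.

    ``amplitude_ratio_db`` sets the RMS of the clutter field relative to a
    unit bubble peak (positive: clutter stronger, as in tissue).
    ``noise_db`` sets the white-noise standard deviation relative to the
    same unit peak.  Drift is a slow rigid translation accumulating
    between acquisition blocks (head drift is about 20 um/min).
    """

    amplitude_ratio_db: float = 30.0
    spatial_corr_mm: float = 0.5
    noise_db: float = -40.0
    drift_um_per_min: float = 20.0


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors perpendicular to ``axis``."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _cone_direction(parent_axis: np.ndarray, max_angle_rad: float, rng) -> np.ndarray:
    """Random unit vector within a cone of half-angle ``max_angle_rad``."""
    cos_min = math.cos(max_angle_rad)
    c = rng.uniform(cos_min, 1.0)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    e1, e2 = _orthonormal_frame(parent_axis)
    return c * parent_axis + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def generate_tree(
    depth: int,
    root_radius_mm: float = 0.1,
    gamma: float = 3.0,
    asymmetry: float = 1.0,
    seed: int = 0,
    *,
    length_over_radius: float = 10.0,
    cone_half_angle_deg: float = 35.0,
    root_start_mm=(3.2, 3.2, 0.3),
    root_direction=(0.0, 0.0, 1.0),
    bounding_box: tuple | None = None,
    max_retries: int = 50,
) -> VascularTree:
    """Seeded binary vascular tree obeying the generalized Murray law.

    ``depth`` is the number of bifurcation generations below the root
    (``depth=0`` gives a single root segment).  At each bifurcation the
    two child radii are in the ratio ``asymmetry`` (1 = symmetric) and
    satisfy ``r_parent^gamma = r1^gamma + r2^gamma`` exactly.  Segment
    length is ``length_over_radius * radius``; child directions are drawn
    inside a cone around the parent axis.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if root_radius_mm <= 0 or gamma <= 0:
        raise ValueError("root_radius_mm and gamma must be positive")
    if not (0.0 < asymmetry <= 1.0):
        raise ValueError("asymmetry must be in (0, 1]")

    rng = np.random.default_rng(seed)
    root_start = np.asarray(root_start_mm, dtype=float)
    root_dir = np.asarray(root_direction, dtype=float)
    root_dir = root_dir / np.linalg.norm(root_dir)
    cone = math.radians(cone_half_angle_deg)

    def in_box(p: np.ndarray) -> bool:
        if bounding_box is None:
            return True
        lo, hi = (np.asarray(b, dtype=float) for b in bounding_box)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    segments: list[Segment] = []
    root = Segment(
        id=0,
        start_mm=root_start,
        end_mm=root_start + root_dir * length_over_radius * root_radius_mm,
        radius_mm=root_radius_mm,
        parent_id=None,
    )
    if not (in_box(root.start_mm) and in_box(root.end_mm)):
        raise RuntimeError("root segment escapes the bounding box")
    segments.append(root)

    # Murray split: r2 = asymmetry * r1 and r1^g + r2^g = rp^g
    frontier = [root]
    next_id = 1
    for _ in range(depth):
        new_frontier = []
        for parent in frontier:
            r1 = parent.radius_mm / (1.0 + asymmetry**gamma) ** (1.0 / gamma)
            r2 = asymmetry * r1
            for r_child in (r1, r2):
                end = None
                for _try in range(max_retries):
                    d = _cone_direction(parent.axis, cone, rng)
                    cand = parent.end_mm + d * length_over_radius * r_child
                    if in_box(cand):
                        end = cand
                        break
                if end is None:
                    raise RuntimeError(
                        "tree escaped bounding box after max retries"
                    )
                child = Segment(
                    id=next_id,
                    start_mm=parent.end_mm.copy(),
                    end_mm=end,
                    radius_mm=r_child,
                    parent_id=parent.id,
                )
                segments.append(child)
                new_frontier.append(child)
                next_id += 1
        frontier = new_frontier
    return VascularTree(segments=segments, gamma=gamma)


def single_segment_tree(
    start_mm, end_mm, radius_mm: float, v_max_mm_s: float, gamma: float = 3.0
) -> VascularTree:
    """A one-vessel 'tree' with flow set from a target centreline velocity.

    Convenience for straight-tube fixtures; ``Q = (v_max/2) pi R^2``.
    """
    seg = Segment(
        id=0,
        start_mm=np.asarray(start_mm, dtype=float),
        end_mm=np.asarray(end_mm, dtype=float),
        radius_mm=float(radius_mm),
        parent_id=None,
        flow_mm3_s=v_max_mm_s / 2.0 * math.pi * radius_mm**2,
    )
    return VascularTree(segments=[seg], gamma=gamma)


def assign_flows(tree: VascularTree, inlet_flow_mm3_s: float) -> VascularTree:
    """Propagate the inlet flow through the tree, splitting ~ r^gamma at nodes."""
    if inlet_flow_mm3_s <= 0:
        raise ValueError("inlet_flow must be positive")
    tree.root.flow_mm3_s = float(inlet_flow_mm3_s)
    stack = [tree.root]
    while stack:
        parent = stack.pop()
        kids = tree.children_of(parent.id)
        if not kids:
            continue
        weights = np.array([k.radius_mm**tree.gamma for k in kids])
        weights = weights / weights.sum()
        for k, w in zip(kids, weights):
            k.flow_mm3_s = parent.flow_mm3_s * float(w)
            stack.append(k)
    return tree


def _advect_bubble(
    tree: VascularTree, t_enter_s: float, frame_times: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Advect one bubble from the root inlet to a leaf outlet.

    Per segment traversal: a fresh radial offset ``rho = R sqrt(u)``
    (uniform in cross-sectional area) and azimuth fix the bubble's lateral
    position; it moves at the constant Poiseuille speed
    ``v = V_max (1 - (rho/R)^2)`` for that traversal.  At a bifurcation the
    child is chosen with probability proportional to its flow.
    Returns (t_indices, positions, velocities, segment_ids) at frame times.
    """
    events = []  # (segment, t_in, t_out, offset_vec, speed)
    seg = tree.root
    t = t_enter_s
    while True:
        u = rng.uniform()
        rho = seg.radius_mm * math.sqrt(u)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        e1, e2 = _orthonormal_frame(seg.axis)
        offset = rho * (math.cos(theta) * e1 + math.sin(theta) * e2)
        v = seg.v_max_mm_s * (1.0 - (rho / seg.radius_mm) ** 2)
        if v <= 0:  # exactly at the wall (u == 1); treat as stuck -> drop
            break
        t_out = t + seg.length_mm / v
        events.append((seg, t, t_out, offset, v))
        kids = tree.children_of(seg.id)
        if not kids:
            break
        flows = np.array([k.flow_mm3_s for k in kids])
        seg = kids[rng.choice(len(kids), p=flows / flows.sum())]
        t = t_out

    ts, ps, vs, sids = [], [], [], []
    for seg, t_in, t_out, offset, v in events:
        m = (frame_times >= t_in) & (frame_times < t_out)
        if not m.any():
            continue
        ft = frame_times[m]
        s = (ft - t_in) * v  # arc length along the segment
        pos = seg.start_mm[None, :] + s[:, None] * seg.axis[None, :] + offset[None, :]
        ts.append(np.nonzero(m)[0])
        ps.append(pos)
        vs.append(np.repeat((v * seg.axis)[None, :], len(ft), axis=0))
        sids.append(np.full(len(ft), seg.id, dtype=np.int64))
    if not ts:
        return (np.empty(0, np.int64), np.empty((0, 3)), np.empty((0, 3)), np.empty(0, np.int64))
    return (
        np.concatenate(ts),
        np.concatenate(ps),
        np.concatenate(vs),
        np.concatenate(sids),
    )


def simulate_bubbles(
    tree: VascularTree,
    seeding_rate_hz: float,
    duration_s: float,
    volume_rate_hz: float,
    seed: int = 0,
) -> GroundTruth:
    """Poisson-seeded bubbles advected through the tree; exact truth recorded.

    Bubble entry times at the root are Poisson with rate
    ``seeding_rate_hz``; positions and velocities are sampled at every
    frame time ``k / volume_rate_hz`` during each bubble's transit.
    """
    if seeding_rate_hz <= 0 or duration_s <= 0 or volume_rate_hz <= 0:
        raise ValueError("rates and duration must be positive")
    if tree.root.flow_mm3_s is None:
        raise ValueError("tree has no flows; call assign_flows first")

    seed_rng = np.random.default_rng(seed)  # Poisson arrival stream
    path_rng = np.random.default_rng(seed_rng.integers(2**31))  # branch/offset stream

    n_frames = int(round(duration_s * volume_rate_hz))
    frame_times = np.arange(n_frames) / volume_rate_hz

    t = 0.0
    bubbles: list[BubbleTrajectory] = []
    bid = 0
    while True:
        t += seed_rng.exponential(1.0 / seeding_rate_hz)
        if t >= duration_s:
            break
        ti, pos, vel, sid = _advect_bubble(tree, t, frame_times, path_rng)
        if len(ti) == 0:
            continue
        bubbles.append(BubbleTrajectory(bid, ti, pos, vel, sid))
        bid += 1
    return GroundTruth(
        bubbles=bubbles, tree=tree, volume_rate_hz=volume_rate_hz, n_frames=n_frames
    )


def _smooth_complex_field(shape, corr_vox: np.ndarray, rng) -> np.ndarray:
    """Unit-RMS spatially-smooth complex field (static clutter template)."""
    f = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f.real, corr_vox) + 1j * ndimage.gaussian_filter(
        f.imag, corr_vox
    )
    rms = np.sqrt(np.mean(np.abs(f) ** 2))
    return f / rms


def render_frame(
    positions_mm: np.ndarray,
    amplitudes: np.ndarray,
    grid: VoxelGrid,
    psf: PSFModel,
    *,
    cutoff_sigmas: float = 4.0,
) -> np.ndarray:
    """Sum of anisotropic Gaussian echoes on the grid (complex, no noise)."""
    vol = np.zeros(grid.shape, dtype=np.complex128)
    if len(positions_mm) == 0:
        return vol
    half = np.maximum(1, np.ceil(cutoff_sigmas * psf.sigma / grid.pitch).astype(int))
    centers = [
        grid.origin[a] + (np.arange(grid.shape[a]) + 0.5) * grid.pitch[a]
        for a in range(3)
    ]
    for p, amp in zip(positions_mm, amplitudes):
        c = grid.world_to_continuous(p)
        lo = np.maximum(0, np.floor(c - half).astype(int))
        hi = np.minimum(np.asarray(grid.shape), np.ceil(c + half).astype(int) + 1)
        if np.any(lo >= hi):
            continue
        gx = np.exp(-0.5 * ((centers[0][lo[0]:hi[0]] - p[0]) / psf.sigma[0]) ** 2)
        gy = np.exp(-0.5 * ((centers[1][lo[1]:hi[1]] - p[1]) / psf.sigma[1]) ** 2)
        gz = np.exp(-0.5 * ((centers[2][lo[2]:hi[2]] - p[2]) / psf.sigma[2]) ** 2)
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return vol


def render_iq(
    gt: GroundTruth,
    grid: VoxelGrid,
    psf: PSFModel,
    clutter: ClutterModel | None = None,
    seed: int = 0,
    *,
    block_len: int = 150,
) -> list[IQSeries]:
    """Render the ground truth into blocks of complex IQ volumes.

    Each frame is the sum of one anisotropic Gaussian echo per bubble
    (unit peak, random phase fixed over the bubble's lifetime), a static
    smooth clutter field (constant within a block), and complex white
    noise.  A rigid drift translation accumulates from block to block at
    ``clutter.drift_um_per_min`` and is applied to the whole scene
    (bubbles and clutter alike); the per-block drift is recorded in
    ``gt.drift_mm``.
    """
    if clutter is None:
        clutter = ClutterModel()
    lo, hi = gt.tree.bounding_box()
    glo = grid.origin
    ghi = grid.origin + grid.extent_mm
    if np.any(lo < glo - 1e-9) or np.any(hi > ghi + 1e-9):
        raise ValueError(
            f"grid [{glo}, {ghi}] does not cover tree bounding box [{lo}, {hi}]"
        )

    # independent substreams so e.g. the clutter field does not depend on
    # how many bubbles were simulated (lets tests render bubble-only /
    # clutter-only scenes that superpose exactly)
    phase_rng, clutter_rng, noise_rng, drift_rng = np.random.default_rng(seed).spawn(4)
    phases = {b.id: np.exp(1j * phase_rng.uniform(0, 2 * math.pi)) for b in gt.bubbles}

    clutter_amp = 10.0 ** (clutter.amplitude_ratio_db / 20.0)
    noise_amp = 10.0 ** (clutter.noise_db / 20.0)
    corr_vox = clutter.spatial_corr_mm / grid.pitch
    base_clutter = (
        clutter_amp * _smooth_complex_field(grid.shape, corr_vox, clutter_rng)
        if clutter.amplitude_ratio_db > -np.inf
        else np.zeros(grid.shape, np.complex128)
    )

    # drift: fixed random direction, cumulative translation per block
    drift_dir = drift_rng.standard_normal(3)
    drift_dir /= np.linalg.norm(drift_dir)
    block_dur_s = block_len / gt.volume_rate_hz
    drift_per_block_mm = clutter.drift_um_per_min / 1000.0 / 60.0 * block_dur_s

    # per-frame bubble samples
    frame_bubbles: dict[int, list[tuple[int, np.ndarray]]] = {}
    for b in gt.bubbles:
        for k, p in zip(b.t_indices, b.positions_mm):
            frame_bubbles.setdefault(int(k), []).append((b.id, p))

    n_blocks = int(math.ceil(gt.n_frames / block_len))
    drifts = np.zeros((n_blocks, 3))
    blocks: list[IQSeries] = []
    for ib in range(n_blocks):
        t0, t1 = ib * block_len, min((ib + 1) * block_len, gt.n_frames)
        shift_mm = drift_dir * drift_per_block_mm * ib
        drifts[ib] = shift_mm
        shift_vox = shift_mm / grid.pitch
        block_clutter = ndimage.shift(
            base_clutter.real, shift_vox, order=1, mode="nearest"
        ) + 1j * ndimage.shift(base_clutter.imag, shift_vox, order=1, mode="nearest")
        data = np.empty(grid.shape + (t1 - t0,), dtype=np.complex64)
        for k in range(t0, t1):
            entries = frame_bubbles.get(k, [])
            pos = np.array([p + shift_mm for _, p in entries]).reshape(-1, 3)
            amps = np.array([phases[bid] for bid, _ in entries])
            frame = render_frame(pos, amps, grid, psf)
            frame += block_clutter
            if noise_amp > 0:
                frame += noise_amp * (
                    noise_rng.standard_normal(grid.shape)
                    + 1j * noise_rng.standard_normal(grid.shape)
                ) / math.sqrt(2.0)
            data[..., k - t0] = frame
        blocks.append(
            IQSeries(data=data, grid=grid, volume_rate_hz=gt.volume_rate_hz, block_id=ib)
        )
    gt.drift_mm = drifts
    return blocks
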