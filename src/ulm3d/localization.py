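"""Per-frame microbubble detection and sub-voxel localization.

Stages per frame, following standard ULM practice: the magnitude volume is
spline-interpolated two-fold per axis, regional maxima (26-connected) are
detected, each maximum's neighbourhood is scored by zero-normalized
cross-correlation (ZNCC) against a Gaussian PSF template, candidates
passing a dual correlation/intensity gate are accepted as bubbles, and a
3D paraboloid ``f = d + a(x-x0)^2 + b(y-y0)^2 + c(z-z0)^2`` is fitted over
a 3x3x3 window to recover the sub-voxel centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.morphology import local_maxima

from .core import IQSeries, PSFModel, VoxelGrid

__all__ = [
    "DetectionConfig",
    "Candidate",
    "ParaboloidFit",
    "MBLocalization",
    "interpolate_volume",
    "gaussian_psf_kernel",
    "detect_candidates",
    "select_bubbles",
    "paraboloid_localize",
    "localize_frame",
    "localize_series",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds; defaults follow common transcranial ULM settings.

    ``ncc_threshold`` (~0.65) gates the PSF correlation; the intensity
    gate (~-20 dB) is relative to ``reference_magnitude`` (by default the
    frame's maximum filtered magnitude).  Kernel and fit window are sized
    on the interpolated grid.
    """

    interp_factor: int = 2
    ncc_kernel_vox: tuple[int, int, int] = (11, 11, 11)
    ncc_threshold: float = 0.65
    intensity_threshold_db: float = -20.0
    fit_window_vox: tuple[int, int, int] = (3, 3, 3)
    # surface the paraboloid is fitted on: the PSF cross-correlation of the
    # volume (matched filter, noise-averaged over the kernel; the fit sits
    # in the vicinity of the maximal correlation) or the raw intensity
    fit_on: str = "correlation"

    def __post_init__(self):
        if self.fit_on not in ("correlation", "intensity"):
            raise ValueError("fit_on must be 'correlation' or 'intensity'")
        if self.interp_factor < 1:
            raise ValueError("interp_factor must be >= 1")
        if any(k % 2 == 0 or k < 1 for k in self.ncc_kernel_vox):
            raise ValueError("ncc kernel sizes must be odd and positive")
        if any(k % 2 == 0 or k < 1 for k in self.fit_window_vox):
            raise ValueError("fit window sizes must be odd and positive")
        if not (-1.0 <= self.ncc_threshold <= 1.0):
            raise ValueError("ncc_threshold must lie in [-1, 1]")
        if self.intensity_threshold_db > 0:
            raise ValueError("intensity_threshold_db must be <= 0 dB")


@dataclass
class Candidate:
    voxel_index: tuple[int, int, int]  # on the interpolated grid
    magnitude: float
    ncc: float


@dataclass
class ParaboloidFit:
    center_mm: np.ndarray
    curvatures: tuple[float, float, float]
    offset: float
    rms_residual: float


@dataclass
class MBLocalization:
    position_mm: np.ndarray
    t_index: int
    block_id: int
    magnitude: float
    ncc: float


def interpolate_volume(
    vol: np.ndarray, grid: VoxelGrid, factor: int
) -> tuple[np.ndarray, VoxelGrid]:
    """Cubic-spline upsampling of a magnitude volume by an integer factor.

    The refined grid's voxel centres include every original centre
    (refined index ``factor*i`` sits exactly on original index ``i``), so
    original samples are reproduced exactly there.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return vol, grid
    fine = grid.refined(factor)
    vol = np.asarray(vol)
    if vol.dtype not in (np.float32, np.float64):
        vol = vol.astype(np.float64)
    # separable not-a-knot cubic splines: reproduce the original samples
    # and any polynomial up to degree 3 exactly, boundaries included
    out = vol
    for axis in range(3):
        n = out.shape[axis]
        cs = CubicSpline(np.arange(n), out, axis=axis, bc_type="not-a-knot")
        out = cs(np.arange(factor * (n - 1) + 1) / factor).astype(vol.dtype)
    return out, fine


def gaussian_psf_kernel(
    psf: PSFModel, pitch_mm, size: tuple[int, int, int]
) -> np.ndarray:
    """Zero-mean, unit-norm Gaussian template on the given voxel pitch."""
    pitch = np.asarray(pitch_mm, dtype=float)
    axes = [
        (np.arange(n) - n // 2) * pitch[a] for a, n in enumerate(size)
    ]
    gx = np.exp(-0.5 * (axes[0] / psf.sigma[0]) ** 2)
    gy = np.exp(-0.5 * (axes[1] / psf.sigma[1]) ** 2)
    gz = np.exp(-0.5 * (axes[2] / psf.sigma[2]) ** 2)
    k = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    k = k - k.mean()
    return k / np.linalg.norm(k)


def _matched_filter(vol: np.ndarray, psf: PSFModel, pitch_mm, size) -> np.ndarray:
    """Separable cross-correlation of the volume with the Gaussian PSF."""
    pitch = np.asarray(pitch_mm, dtype=float)
    out = np.asarray(vol)
    for axis, n in enumerate(size):
        ax = (np.arange(n) - n // 2) * pitch[axis]
        g = np.exp(-0.5 * (ax / psf.sigma[axis]) ** 2)
        g = (g / g.sum()).astype(out.dtype, copy=False)
        out = ndimage.correlate1d(out, g, axis=axis, mode="nearest")
    return out


def _suppress_duplicates(
    cands: list[Candidate], radius_vox: tuple[int, int, int]
) -> list[Candidate]:
    """Greedy non-max suppression: within a kernel-half-sized box around a
    stronger candidate, weaker ones are duplicates of the same bubble."""
    kept: list[Candidate] = []
    for c in sorted(cands, key=lambda c: (-c.magnitude, c.voxel_index)):
        if any(
            all(abs(c.voxel_index[a] - k.voxel_index[a]) <= radius_vox[a] for a in range(3))
            for k in kept
        ):
            continue
        kept.append(c)
    return kept


def _zncc(patch: np.ndarray, kernel: np.ndarray) -> float:
    p = patch - patch.mean()
    norm = np.linalg.norm(p)
    if norm == 0:
        return 0.0
    return float(np.sum(p / norm * kernel))


def detect_candidates(
    vol: np.ndarray,
    cfg: DetectionConfig,
    psf: PSFModel,
    pitch_mm,
    *,
    min_magnitude: float = 0.0,
) -> list[Candidate]:
    """Regional maxima (26-connectivity) scored by ZNCC against the PSF.

    A plateau of equal-valued voxels surrounded by lower values yields a
    single candidate at its centroid voxel (rounded toward the lower
    index).  Maxima whose kernel-sized neighbourhood would cross the
    volume border are dropped (they cannot be scored or fitted reliably).
    ``min_magnitude`` skips maxima that the downstream intensity gate
    would reject anyway, so noise maxima are not ZNCC-scored.
    """
    vol = np.asarray(vol)
    if np.any(vol < 0):
        raise ValueError("expected a non-negative magnitude volume")
    size = cfg.ncc_kernel_vox
    if any(vol.shape[a] < size[a] for a in range(3)):
        raise ValueError(
            f"volume shape {vol.shape} smaller than ncc kernel {size}"
        )
    kernel = gaussian_psf_kernel(psf, pitch_mm, size)
    half = tuple(s // 2 for s in size)

    maxima = local_maxima(vol, connectivity=3)
    if min_magnitude > 0:
        # a regional-max plateau has a single value, so gating by value
        # keeps or drops whole components and labeling stays exact
        maxima &= vol >= min_magnitude
    labels, n_comp = ndimage.label(maxima, structure=np.ones((3, 3, 3), dtype=int))
    cands: list[Candidate] = []
    if n_comp == 0:
        return cands
    centroids = ndimage.center_of_mass(maxima, labels, range(1, n_comp + 1))
    for c in centroids:
        idx = tuple(int(math.floor(v + 1e-9)) for v in c)  # toward lower index
        if any(
            idx[a] - half[a] < 0 or idx[a] + half[a] >= vol.shape[a] for a in range(3)
        ):
            continue
        patch = vol[
            idx[0] - half[0] : idx[0] + half[0] + 1,
            idx[1] - half[1] : idx[1] + half[1] + 1,
            idx[2] - half[2] : idx[2] + half[2] + 1,
        ]
        cands.append(Candidate(idx, float(vol[idx]), _zncc(patch, kernel)))
    return cands


def select_bubbles(
    cands: list[Candidate], cfg: DetectionConfig, reference_magnitude: float
) -> list[Candidate]:
    """Dual gate: PSF correlation above threshold AND intensity above the
    dB gate relative to ``reference_magnitude``."""
    if reference_magnitude <= 0:
        raise ValueError("reference_magnitude must be positive")
    out = []
    for c in cands:
        if c.ncc <= cfg.ncc_threshold:
            continue
        if c.magnitude <= 0:
            continue
        if 20.0 * math.log10(c.magnitude / reference_magnitude) <= cfg.intensity_threshold_db:
            continue
        out.append(c)
    return out


def paraboloid_localize(
    vol: np.ndarray,
    grid: VoxelGrid,
    candidate: Candidate,
    cfg: DetectionConfig,
) -> ParaboloidFit | None:
    """Least-squares paraboloid fit over the window around a candidate.

    The model ``d + a(x-x0)^2 + b(y-y0)^2 + c(z-z0)^2`` is solved in its
    expanded cross-term-free basis {1, x, y, z, x^2, y^2, z^2}; the
    sub-voxel centre follows as ``x0 = -beta_x / (2a)``.  Returns ``None``
    (rejection) for border candidates, non-negative curvature, a centre
    displaced more than one voxel, or a singular design.
    """
    vol = np.asarray(vol, dtype=float)
    half = tuple(s // 2 for s in cfg.fit_window_vox)
    idx = candidate.voxel_index
    if any(idx[a] - half[a] < 0 or idx[a] + half[a] >= vol.shape[a] for a in range(3)):
        return None
    window = vol[
        idx[0] - half[0] : idx[0] + half[0] + 1,
        idx[1] - half[1] : idx[1] + half[1] + 1,
        idx[2] - half[2] : idx[2] + half[2] + 1,
    ]
    xs, ys, zs = np.meshgrid(
        *[np.arange(-h, h + 1, dtype=float) for h in half], indexing="ij"
    )
    design = np.column_stack(
        [
            np.ones(window.size),
            xs.ravel(),
            ys.ravel(),
            zs.ravel(),
            xs.ravel() ** 2,
            ys.ravel() ** 2,
            zs.ravel() ** 2,
        ]
    )
    coef, _, rank, _ = np.linalg.lstsq(design, window.ravel(), rcond=None)
    if rank < design.shape[1]:
        return None
    _, bx, by, bz, a, b, c = coef
    if a >= 0 or b >= 0 or c >= 0:
        return None
    offset_vox = np.array([-bx / (2 * a), -by / (2 * b), -bz / (2 * c)])
    if np.any(np.abs(offset_vox) > 1.0):
        return None
    resid = window.ravel() - design @ coef
    center_vox = np.asarray(idx, dtype=float) + offset_vox
    center_mm = grid.voxel_center(center_vox - 0.0)  # fractional index -> world
    # peak level at the vertex: d' + sum beta*x0 + curv*x0^2
    peak = float(
        coef[0]
        + bx * offset_vox[0] + by * offset_vox[1] + bz * offset_vox[2]
        + a * offset_vox[0] ** 2 + b * offset_vox[1] ** 2 + c * offset_vox[2] ** 2
    )
    return ParaboloidFit(
        center_mm=center_mm,
        curvatures=(float(a), float(b), float(c)),
        offset=peak,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _recenter_on(vol: np.ndarray, cand: Candidate, radius: int = 2) -> Candidate:
    """Move a candidate to the local argmax of ``vol`` within ``radius``
    voxels (an intensity maximum can sit a voxel or two off the smoothed
    correlation peak under noise)."""
    idx = np.asarray(cand.voxel_index)
    lo = np.maximum(0, idx - radius)
    hi = np.minimum(np.asarray(vol.shape), idx + radius + 1)
    sub = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    new = lo + np.asarray(np.unravel_index(np.argmax(sub), sub.shape))
    return Candidate(tuple(int(v) for v in new), cand.magnitude, cand.ncc)


def localize_frame(
    mag: np.ndarray,
    grid: VoxelGrid,
    psf: PSFModel,
    cfg: DetectionConfig,
    *,
    t_index: int = 0,
    block_id: int = 0,
    reference_magnitude: float | None = None,
) -> list[MBLocalization]:
    """Full localization chain on one magnitude volume."""
    fine_vol, fine_grid = interpolate_volume(mag, grid, cfg.interp_factor)
    fine_vol = np.clip(fine_vol, 0.0, None)  # spline overshoot guard
    ref = reference_magnitude if reference_magnitude is not None else float(fine_vol.max())
    if ref <= 0:
        return []
    floor = ref * 10.0 ** (cfg.intensity_threshold_db / 20.0)
    cands = detect_candidates(
        fine_vol, cfg, psf, fine_grid.pitch_mm, min_magnitude=floor
    )
    accepted = select_bubbles(cands, cfg, ref)
    accepted = _suppress_duplicates(
        accepted, tuple(s // 2 for s in cfg.ncc_kernel_vox)
    )
    if cfg.fit_on == "correlation":
        fit_vol = _matched_filter(fine_vol, psf, fine_grid.pitch_mm, cfg.ncc_kernel_vox)
    else:
        fit_vol = fine_vol
    out: list[MBLocalization] = []
    for cand in accepted:
        if cfg.fit_on == "correlation":
            cand = _recenter_on(fit_vol, cand, radius=2)
        fit = paraboloid_localize(fit_vol, fine_grid, cand, cfg)
        if fit is None:
            continue
        out.append(
            MBLocalization(
                position_mm=fit.center_mm,
                t_index=t_index,
                block_id=block_id,
                magnitude=cand.magnitude,
                ncc=cand.ncc,
            )
        )
    return out


def localize_series(
    iq_filtered: IQSeries,
    psf: PSFModel,
    cfg: DetectionConfig | None = None,
) -> list[MBLocalization]:
    """Localize bubbles in every frame of a clutter-filtered IQ series."""
    if cfg is None:
        cfg = DetectionConfig()
    locs: list[MBLocalization] = []
    for t in range(iq_filtered.n_frames):
        locs.extend(
            localize_frame(
                iq_filtered.magnitude(t),
                iq_filtered.grid,
                psf,
                cfg,
                t_index=t,
                block_id=iq_filtered.block_id,
            )
        )
    return locs
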