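"""SVD spatiotemporal clutter rejection on IQ sub-blocks.

Each sub-block of frames is reshaped into a Casorati matrix
(voxels x time), decomposed by singular value decomposition, and the
leading singular components — which capture static and slowly varying
tissue — are zeroed before reconstruction.  Defaults follow ultrafast
ULM practice: 150-frame sub-blocks, first 15 singular vectors removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import IQSeries

__all__ = ["SVDFilterConfig", "svd_filter"]


@dataclass(frozen=True)
class SVDFilterConfig:
    subblock_len: int = 150
    n_remove: int = 15
    # optional high-order cutoff (noise floor); disabled by default
    n_remove_high: int = 0

    def __post_init__(self):
        if not (0 <= self.n_remove < self.subblock_len):
            raise ValueError(
                f"need 0 <= n_remove ({self.n_remove}) < subblock_len "
                f"({self.subblock_len})"
            )
        if self.n_remove_high < 0:
            raise ValueError("n_remove_high must be >= 0")


def _filter_casorati(x: np.ndarray, n_remove: int, n_remove_high: int) -> np.ndarray:
    """Zero the ``n_remove`` largest singular values of (voxels x time) x.

    Since time is the short axis, the temporal singular vectors are the
    eigenvectors of the small Hermitian Gram matrix ``X^H X`` (t x t);
    zeroing singular values is then the projection
    ``X (I - V_k V_k^H)``, avoiding the full tall-matrix SVD.
    """
    if n_remove == 0 and n_remove_high == 0:
        return x.copy()
    gram = x.conj().T @ x
    _, vecs = linalg.eigh(gram.astype(np.complex128))  # eigenvalues ascending
    out = x.copy()
    t = gram.shape[0]
    if n_remove > 0:
        vk = vecs[:, t - n_remove :].astype(x.dtype)
        out -= (x @ vk) @ vk.conj().T
    if n_remove_high > 0:
        vlow = vecs[:, :n_remove_high].astype(x.dtype)
        out -= (x @ vlow) @ vlow.conj().T
    return out


def _subblock_slices(n_frames: int, subblock_len: int) -> list[tuple[slice, int]]:
    """Non-overlapping sub-blocks; a trailing remainder shorter than half a
    sub-block is merged into the previous one, a longer remainder stands
    alone with n_remove rescaled by its relative length."""
    out: list[tuple[slice, int]] = []
    start = 0
    while n_frames - start >= subblock_len:
        out.append((slice(start, start + subblock_len), subblock_len))
        start += subblock_len
    rem = n_frames - start
    if rem > 0:
        if out and rem < subblock_len / 2:
            last_slice, _ = out[-1]
            out[-1] = (slice(last_slice.start, n_frames), n_frames - last_slice.start)
        else:
            out.append((slice(start, n_frames), rem))
    return out


def svd_filter(iq: IQSeries, cfg: SVDFilterConfig | None = None) -> IQSeries:
    """Remove low-order spatiotemporal (clutter) components from an IQ series.

    The output has the same shape and metadata; its energy never exceeds
    the input's, and the removed plus retained parts sum exactly to the
    input (the filter is a linear projection per sub-block).
    """
    if cfg is None:
        cfg = SVDFilterConfig()
    n_frames = iq.n_frames
    if n_frames < cfg.subblock_len:
        raise ValueError(
            f"series has {n_frames} frames < subblock_len {cfg.subblock_len}"
        )
    n_vox = int(np.prod(iq.grid.shape))
    flat = iq.data.reshape(n_vox, n_frames)
    out = np.empty_like(flat)
    for sl, length in _subblock_slices(n_frames, cfg.subblock_len):
        n_rm = cfg.n_remove
        if length != cfg.subblock_len:
            n_rm = int(round(cfg.n_remove * length / cfg.subblock_len))
            n_rm = min(n_rm, max(length - 1, 0))
        out[:, sl] = _filter_casorati(flat[:, sl], n_rm, cfg.n_remove_high)
    return IQSeries(
        data=out.reshape(iq.data.shape),
        grid=iq.grid,
        volume_rate_hz=iq.volume_rate_hz,
        block_id=iq.block_id,
    )
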