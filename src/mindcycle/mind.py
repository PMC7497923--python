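"""Modality-independent neighborhood descriptor (MIND) and content loss.

MIND encodes each voxel by how similar its patch is to the patches at the
offsets of a search region R:

    MIND(I, x, r) = (1/n) * exp(-D(I, x, r) / V(I, x)),   r in R

where D is the summed squared difference between the patch at x and the
patch at x + r, and V is a local variance estimate (the mean of D over a
small neighborhood N of x) that makes the response contrast-invariant.
Because the descriptor only measures *self*-similarity within one image,
descriptors of a CT and an MR of the same anatomy are directly comparable,
and their mean absolute difference serves as the content loss driving
multimodal registration.

Conventions (documented in the methods note):

- patches and the search region are in-plane by default (5x5 patch, 7x7
  region minus the zero offset), matching thick-slice acquisitions; a 3D
  mode is available via ``mode_2d=False``;
- the normalization constant is realized per voxel as division by the
  maximum response over R, so every response lies in (0, 1] with max 1;
- V averages D over the 4-connected in-plane offsets and is floored at
  ``epsilon_scale * (intensity range)^2``;
- all out-of-grid reads replicate the edge: a sample position is clamped
  to the grid, and the r-offset is applied to the clamped position and
  clamped again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .volume_io import Volume

__all__ = [
    "MindConfig",
    "MINDDescriptor",
    "patch_distance",
    "variance_estimate",
    "mind_descriptor",
    "mind_tensor",
    "content_loss",
]


@dataclass(frozen=True)
class MindConfig:
    patch_size: int = 5
    region_size: int = 7
    mode_2d: bool = True
    epsilon_scale: float = 1e-6

    def __post_init__(self):
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 1")
        if self.region_size < 3 or self.region_size % 2 == 0:
            raise ValueError("region_size must be odd and >= 3")
        if self.epsilon_scale <= 0:
            raise ValueError("epsilon_scale must be positive")

    @property
    def patch_offsets(self) -> tuple[tuple[int, int, int], ...]:
        h = (self.patch_size - 1) // 2
        rng = range(-h, h + 1)
        if self.mode_2d:
            return tuple((dx, dy, 0) for dx in rng for dy in rng)
        return tuple((dx, dy, dz) for dx in rng for dy in rng for dz in rng)

    @property
    def search_offsets(self) -> tuple[tuple[int, int, int], ...]:
        h = (self.region_size - 1) // 2
        rng = range(-h, h + 1)
        if self.mode_2d:
            offs = ((dx, dy, 0) for dx in rng for dy in rng)
        else:
            offs = ((dx, dy, dz) for dx in rng for dy in rng for dz in rng)
        return tuple(o for o in offs if o != (0, 0, 0))

    @property
    def variance_offsets(self) -> tuple[tuple[int, int, int], ...]:
        if self.mode_2d:
            return ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))
        return ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1))


@dataclass
class MINDDescriptor:
    """Dense MIND responses: shape (|R|, X, Y, Z), values in (0, 1]."""

    values: np.ndarray
    config: MindConfig

    @property
    def n_offsets(self) -> int:
        return self.values.shape[0]


def _epsilon(data: np.ndarray, cfg: MindConfig) -> float:
    rng = float(data.max() - data.min())
    return max(cfg.epsilon_scale * rng * rng, 1e-12)


def _shift(t: ad.Tensor, offset, axis0: int = 0) -> ad.Tensor:
    """Edge-clamped 3D shift, spatial axes starting at `axis0`."""
    out = t
    for ax, k in enumerate(offset):
        if k:
            out = ad.shift_axis(out, axis0 + ax, int(k))
    return out


def _box_sum(t: ad.Tensor, cfg: MindConfig, axis0: int = 0) -> ad.Tensor:
    """Sum over the patch footprint via separable edge-clamped shifts."""
    h = (cfg.patch_size - 1) // 2
    axes = (0, 1) if cfg.mode_2d else (0, 1, 2)
    out = t
    for ax in axes:
        acc = None
        for d in range(-h, h + 1):
            term = ad.shift_axis(out, axis0 + ax, d) if d else out
            acc = term if acc is None else acc + term
        out = acc
    return out


def _as_array(v) -> np.ndarray:
    if isinstance(v, Volume):
        return v.data
    if isinstance(v, ad.Tensor):
        return v.value
    return np.asarray(v, dtype=np.float64)


def _clip_idx(idx, shape):
    return tuple(int(np.clip(i, 0, n - 1)) for i, n in zip(idx, shape))


def patch_distance(i, x, r, cfg: MindConfig = MindConfig()) -> float:
    """Summed squared patch difference D(I, x, r) (single voxel).

    Reads are edge-clamped: sample positions x+p are clamped to the grid
    and the offset r is applied to the clamped position (and clamped
    again), matching the dense descriptor path exactly.
    """
    data = _as_array(i)
    shape = data.shape
    total = 0.0
    for p in cfg.patch_offsets:
        a = _clip_idx(tuple(xi + pi for xi, pi in zip(x, p)), shape)
        b = _clip_idx(tuple(ai + ri for ai, ri in zip(a, r)), shape)
        d = data[a] - data[b]
        total += d * d
    return float(total)


def variance_estimate(i, x, cfg: MindConfig = MindConfig()) -> float:
    """Local variance V(I, x): mean of D over the variance neighborhood."""
    data = _as_array(i)
    offs = cfg.variance_offsets
    mean_d = sum(patch_distance(data, x, n, cfg) for n in offs) / len(offs)
    return max(mean_d, _epsilon(data, cfg))


def mind_tensor(t: ad.Tensor, cfg: MindConfig = MindConfig(),
                epsilon: float | None = None) -> ad.Tensor:
    """Dense MIND responses as a (|R|, X, Y, Z) tensor (differentiable).

    All search offsets are batched into one stacked tensor so the whole
    descriptor is O(|R| + |P|) shifted-array operations, not per-voxel
    loops; the distance volumes for the variance offsets are reused from
    the stack (they are members of R).
    """
    shape = t.value.shape
    eps = _epsilon(t.value, cfg) if epsilon is None else float(epsilon)
    offsets = cfg.search_offsets
    shifted = ad.stack([_shift(t, r) for r in offsets], axis=0)
    diff = shifted - t.reshape((1,) + shape)
    d_all = _box_sum(diff * diff, cfg, axis0=1)
    var_rows = [offsets.index(n) for n in cfg.variance_offsets]
    n_vox = int(np.prod(shape))
    row_idx = (np.asarray(var_rows)[:, None] * n_vox
               + np.arange(n_vox)[None, :]).reshape((len(var_rows),) + shape)
    v = ad.take(d_all, row_idx, out_shape=row_idx.shape).mean(axis=0)
    v = ad.clip(v, eps, np.inf)  # variance floor
    responses = ad.exp(-(d_all / v.reshape((1,) + shape)))
    peak = ad.maximum_along(responses, axis=0)
    return responses / peak.reshape((1,) + shape)


def mind_descriptor(i, cfg: MindConfig = MindConfig()) -> MINDDescriptor:
    """Dense MIND descriptor of a volume (numpy result)."""
    data = _as_array(i)
    min_extent = cfg.region_size if not cfg.mode_2d else 1
    if data.shape[2] < min_extent or min(data.shape[:2]) < cfg.region_size:
        raise ValueError("volume smaller than the search-region footprint")
    vals = mind_tensor(ad.Tensor(data), cfg).value
    return MINDDescriptor(values=vals, config=cfg)


def content_loss(a, b, cfg: MindConfig = MindConfig()):
    """Mean absolute MIND difference between two images (Lcont).

    Accepts volumes, arrays, or autodiff tensors; returns a float for
    plain inputs and a scalar :class:`~mindcycle.autodiff.Tensor` when
    either input carries gradients, so the loss can drive training.
    Symmetric in its arguments.
    """
    ta = a if isinstance(a, ad.Tensor) else ad.Tensor(_as_array(a))
    tb = b if isinstance(b, ad.Tensor) else ad.Tensor(_as_array(b))
    if ta.value.shape != tb.value.shape:
        raise ValueError(
            f"shape mismatch: {ta.value.shape} vs {tb.value.shape}")
    ma = mind_tensor(ta, cfg)
    mb = mind_tensor(tb, cfg)
    loss = ad.absolute(ma - mb).mean()
    if loss.requires_grad:
        return loss
    return float(loss.value)
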