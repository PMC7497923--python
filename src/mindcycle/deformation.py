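"""Dense displacement fields, differentiable warping, and field diagnostics.

A :class:`DeformationField` stores one displacement 3-vector per voxel, in
voxel units, on the fixed image's grid; the transformation it defines is
``phi(x) = x + f(x)`` so the zero field is the identity.  Warping samples
the moving image at ``phi(x)`` with trilinear interpolation (differentiable
with respect to both the image and the field, for training) or nearest
neighbor (for label masks, which must not be blended).  Out-of-grid sample
positions replicate the edge.

The regularization loss is the literal squared-magnitude penalty on the
displacement grid — the mean over voxels of ``|f(x)|^2`` — which favors
small deformations; a first-difference (gradient) penalty is available via
``regularization_loss(..., penalty="gradient")``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import nibabel as nib
import numpy as np

from . import autodiff as ad
from .volume_io import Volume

__all__ = [
    "DeformationField",
    "warp",
    "warp_tensor",
    "warp_points",
    "regularization_loss",
    "jacobian_folding_fraction",
    "save_field",
    "load_field",
]


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (3, X, Y, Z) in voxel units."""

    displacements: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[0] != 3:
            raise ValueError("displacements must have shape (3, X, Y, Z)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains NaN/Inf")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[1:]

    def to_mm(self) -> np.ndarray:
        """Displacements converted to millimetres per component."""
        s = np.asarray(self.spacing).reshape(3, 1, 1, 1)
        return self.displacements * s

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0, 1.0)) -> "DeformationField":
        return cls(np.zeros((3,) + tuple(shape)), spacing)


@lru_cache(maxsize=64)
def _base_grid(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                indexing="ij"), axis=0)


def warp_tensor(vol: ad.Tensor, field: ad.Tensor) -> ad.Tensor:
    """Trilinear warp ``out(x) = vol(x + field(x))`` (differentiable).

    `vol` has shape (X, Y, Z), `field` (3, X, Y, Z) in voxel units.
    Gradients flow into `vol` through the corner gathers and into `field`
    through the interpolation weights; positions clamped at the boundary
    contribute zero field gradient there (edge replication).
    """
    shape = vol.value.shape
    if field.value.shape != (3,) + shape:
        raise ValueError(
            f"field shape {field.value.shape} does not match volume {shape}")
    base = _base_grid(shape)
    X, Y, Z = shape
    dims = (X, Y, Z)

    n_vox = X * Y * Z
    fracs, floors = [], []
    for ax in range(3):
        comp = ad.take(field, np.arange(ax * n_vox, (ax + 1) * n_vox)
                       .reshape(shape), out_shape=shape)
        pos = comp + base[ax]
        pos = ad.clip(pos, 0.0, dims[ax] - 1.0)
        fl = np.minimum(np.floor(pos.value), max(dims[ax] - 2, 0)).astype(np.int64)
        floors.append(fl)
        fracs.append(pos - fl)

    out = None
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                ix = np.minimum(floors[0] + cx, X - 1)
                iy = np.minimum(floors[1] + cy, Y - 1)
                iz = np.minimum(floors[2] + cz, Z - 1)
                flat = (ix * Y + iy) * Z + iz
                corner = ad.take(vol, flat, out_shape=shape)
                w = (fracs[0] if cx else 1.0 - fracs[0]) \
                    * (fracs[1] if cy else 1.0 - fracs[1]) \
                    * (fracs[2] if cz else 1.0 - fracs[2])
                term = w * corner
                out = term if out is None else out + term
    return out


def _warp_nearest(data: np.ndarray, disp: np.ndarray) -> np.ndarray:
    shape = data.shape
    pos = _base_grid(shape) + disp
    idx = tuple(np.clip(np.round(pos[ax]), 0, shape[ax] - 1).astype(np.int64)
                for ax in range(3))
    return data[idx]


def warp(v: Volume, f: DeformationField, interpolation: str = "trilinear") -> Volume:
    """Warp a volume by a displacement field defined on its grid."""
    if f.grid_shape != v.data.shape:
        raise ValueError(
            f"field grid {f.grid_shape} does not match volume {v.data.shape}")
    if interpolation == "trilinear":
        out = warp_tensor(ad.Tensor(v.data), ad.Tensor(f.displacements)).value
    elif interpolation == "nearest":
        out = _warp_nearest(v.data, f.displacements)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return v.with_data(out)


def warp_labels(labels: np.ndarray, f: DeformationField) -> np.ndarray:
    """Nearest-neighbor warp for integer label grids."""
    if f.grid_shape != labels.shape:
        raise ValueError("field grid does not match label grid")
    return _warp_nearest(labels.astype(np.float64), f.displacements).astype(labels.dtype)


def warp_points(points_mm: np.ndarray, f: DeformationField,
                origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Map physical points through ``phi(x) = x + f(x)``.

    The displacement is interpolated trilinearly at each point (given in
    mm) and added, returning the mapped points in mm.  Points outside the
    field extent raise.
    """
    from scipy.ndimage import map_coordinates

    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    spacing = np.asarray(f.spacing)
    vox = (pts - np.asarray(origin)) / spacing
    shape = np.asarray(f.grid_shape)
    bad = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    if bad.any():
        raise ValueError(f"points outside field extent: {pts[bad].tolist()}")
    coords = np.clip(vox, 0, shape - 1).T
    disp_vox = np.stack([map_coordinates(f.displacements[ax], coords, order=1,
                                         mode="nearest") for ax in range(3)],
                        axis=1)
    return pts + disp_vox * spacing


def regularization_loss(f, penalty: str = "magnitude"):
    """Smoothness/magnitude penalty on a displacement field (Lreg).

    ``magnitude`` (default): mean over voxels of the squared displacement
    magnitude.  ``gradient``: mean squared forward difference of each
    component along each axis.  Accepts a DeformationField, an array, or
    an autodiff tensor (returning a differentiable scalar).
    """
    if isinstance(f, DeformationField):
        t = ad.Tensor(f.displacements)
    elif isinstance(f, ad.Tensor):
        t = f
    else:
        t = ad.Tensor(np.asarray(f, dtype=np.float64))
    n_vox = int(np.prod(t.value.shape[1:]))
    if penalty == "magnitude":
        loss = (t * t).sum() * (1.0 / n_vox)
    elif penalty == "gradient":
        total = None
        for ax in range(1, 4):
            n = t.value.shape[ax]
            if n < 2:
                continue
            sl_hi = [slice(None)] * 4
            sl_lo = [slice(None)] * 4
            sl_hi[ax] = slice(1, n)
            sl_lo[ax] = slice(0, n - 1)
            d = _slice(t, tuple(sl_hi)) - _slice(t, tuple(sl_lo))
            term = (d * d).sum() * (1.0 / n_vox)
            total = term if total is None else total + term
        loss = total
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    if isinstance(loss, ad.Tensor) and loss.requires_grad:
        return loss
    return float(loss.value)


def _slice(t: ad.Tensor, slices) -> ad.Tensor:
    flat = np.arange(t.value.size).reshape(t.value.shape)[slices]
    return ad.take(t, flat, out_shape=flat.shape)


def jacobian_folding_fraction(f: DeformationField) -> float:
    """Fraction of interior voxels where det(Jacobian of x + f(x)) <= 0.

    Central finite differences on the interior; a positive determinant
    everywhere means the discrete transformation preserves orientation
    (no folding).
    """
    disp = f.displacements
    shape = disp.shape[1:]
    if min(shape) < 2:
        raise ValueError("grid must be at least 2 voxels per axis")
    jac = np.empty((3, 3) + shape)
    for i in range(3):
        grads = np.gradient(disp[i], axis=(0, 1, 2))
        for j in range(3):
            jac[i, j] = grads[j] + (1.0 if i == j else 0.0)
    det = (jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
           - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
           + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0]))
    interior = det[tuple(slice(1, -1) if n > 2 else slice(None) for n in shape)]
    if interior.size == 0:
        return 0.0
    return float(np.mean(interior <= 0))


def save_field(f: DeformationField, path) -> None:
    """Serialize as 4D NIfTI: (X, Y, Z, 3), voxel-unit displacements."""
    affine = np.diag(list(f.spacing) + [1.0])
    arr = np.moveaxis(f.displacements, 0, -1)
    img = nib.Nifti1Image(arr, affine)
    img.header["descrip"] = b"displacement field, voxel units, axis order xyz"
    nib.save(img, str(path))


def load_field(path) -> DeformationField:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"not a displacement field file: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DeformationField(np.moveaxis(arr, -1, 0), spacing)
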