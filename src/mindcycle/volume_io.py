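"""Volume container, NIfTI/MetaImage I/O and the preprocessing chain.

Volumes are axis-aligned scalar grids with millimetre voxel spacing; a
voxel index maps to the physical point ``origin + index * spacing`` (no
direction matrix — obliquely acquired data is out of scope).  The
preprocessing chain mirrors the standard pipeline for rigidly pre-aligned
multimodal pairs: resample to a common spacing (typically 1x1x5 mm for
pelvic CT/MR), crop or pad to a fixed grid so redundant air is removed,
then robustly rescale intensities into (-1, 1) for the network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "Volume",
    "ROIMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "resample",
    "crop_or_pad",
    "normalize_intensity",
    "preprocess",
]


class Modality(str, Enum):
    CT = "CT"
    MR = "MR"
    SYNTH_A = "SYNTH_A"
    SYNTH_B = "SYNTH_B"
    UNKNOWN = "UNKNOWN"


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and physical origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.UNKNOWN

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every volume dimension must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN or Inf intensities")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class ROIMask:
    """Integer label grid aligned with a companion :class:`Volume`.

    Label 0 is background; ``label_names`` maps positive labels to organ
    names (e.g. 1 -> bladder, 2 -> rectum).
    """

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _format_from_path(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValueError(f"cannot infer volume format from extension of {path}")


def load_volume(path, fmt: str | None = None,
                modality: Modality = Modality.UNKNOWN) -> Volume:
    """Read a NIfTI or MetaImage volume; spacing/origin come from the header.

    Intensities are passed through unmodified but validated: NaN/Inf voxels
    are rejected at load so they cannot silently propagate into descriptors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = fmt or _format_from_path(path)
    try:
        if fmt == "nifti":
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
            zooms = img.header.get_zooms()[:3]
            if any(z <= 0 for z in zooms):
                raise ValueError(f"non-positive spacing in header of {path}")
            origin = tuple(float(v) for v in img.affine[:3, 3])
            spacing = tuple(float(z) for z in zooms)
        elif fmt == "metaimage":
            img = sitk.ReadImage(str(path))
            # SimpleITK returns (z, y, x); transpose to (x, y, z)
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
            spacing = tuple(float(s) for s in img.GetSpacing())
            origin = tuple(float(o) for o in img.GetOrigin())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (OSError, RuntimeError) as err:
        raise OSError(f"could not read volume {path}: {err}") from err
    return Volume(data=data, spacing=spacing, origin=origin, modality=modality)


def save_volume(v: Volume, path, fmt: str | None = None) -> None:
    """Write a volume so that :func:`load_volume` round-trips it bit-exactly."""
    path = Path(path)
    fmt = fmt or _format_from_path(path)
    if not np.all(np.isfinite(v.data)):
        raise ValueError("refusing to save volume with NaN/Inf intensities")
    if fmt == "nifti":
        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        img = nib.Nifti1Image(v.data, affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, str(path))
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
        img.SetSpacing(v.spacing)
        img.SetOrigin(v.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_mask(path, label_names: dict[int, str] | None = None) -> ROIMask:
    v = load_volume(path)
    return ROIMask(labels=np.round(v.data).astype(np.int32),
                   label_names=label_names or {}, spacing=v.spacing)


def save_mask(m: ROIMask, path) -> None:
    save_volume(Volume(data=m.labels.astype(np.float64), spacing=m.spacing), path)


def resample(v: Volume, target_spacing) -> Volume:
    """Trilinear resample onto `target_spacing`, preserving physical extent.

    Output size is ``round(in_size * in_spacing / out_spacing)`` (at least 1
    per axis), so the physical extent matches the input to within one output
    voxel.  Sample positions outside the input grid replicate the edge.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    in_shape = v.data.shape
    out_shape = tuple(max(1, int(round(n * s_in / s_out)))
                      for n, s_in, s_out in zip(in_shape, v.spacing, target_spacing))
    if out_shape == in_shape and target_spacing == v.spacing:
        return replace(v, data=v.data.copy())
    # physical position of output voxel i is i * s_out; input index = pos / s_in
    coords = np.meshgrid(*[np.arange(n) * s_out / s_in
                           for n, s_out, s_in in zip(out_shape, target_spacing, v.spacing)],
                         indexing="ij")
    out = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    return Volume(data=out, spacing=target_spacing, origin=v.origin,
                  modality=v.modality)


def _foreground_centroid(data: np.ndarray, threshold_pct: float) -> np.ndarray:
    thr = np.percentile(data, threshold_pct * 100.0)
    fg = data > thr
    if not fg.any():
        return (np.asarray(data.shape, dtype=np.float64) - 1) / 2.0
    return np.asarray(ndimage.center_of_mass(fg), dtype=np.float64)


def crop_or_pad(v: Volume, target_size, center_mode: str = "grid_center",
                foreground_threshold_pct: float = 0.05) -> Volume:
    """Crop/pad to an exact grid size, removing redundant air at the borders.

    ``center_mode='foreground_centroid'`` centres the window on the centroid
    of above-threshold voxels (threshold at the 5th intensity percentile by
    default) so bright anatomy stays inside the crop; ``'grid_center'``
    keeps the geometric centre.  Padding fills with the minimum intensity
    (air).
    """
    target_size = tuple(int(n) for n in target_size)
    if any(n <= 0 for n in target_size):
        raise ValueError(f"target size must be positive, got {target_size}")
    if center_mode not in ("foreground_centroid", "grid_center"):
        raise ValueError(f"unknown center_mode {center_mode!r}")
    data = v.data
    if center_mode == "foreground_centroid":
        center = _foreground_centroid(data, foreground_threshold_pct)
    else:
        center = (np.asarray(data.shape, dtype=np.float64) - 1) / 2.0

    air = float(data.min())
    out = np.full(target_size, air, dtype=data.dtype)
    start = np.round(center - (np.asarray(target_size) - 1) / 2.0).astype(int)
    new_origin = list(v.origin)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for ax in range(3):
        lo = start[ax]
        hi = lo + target_size[ax]
        s_lo = max(lo, 0)
        s_hi = min(hi, data.shape[ax])
        if s_lo >= s_hi:  # window entirely outside: emit all-air axis
            s_lo = s_hi = 0
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - lo)
        dst_hi.append(s_lo - lo + (s_hi - s_lo))
        new_origin[ax] = v.origin[ax] + lo * v.spacing[ax]
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return Volume(data=out, spacing=v.spacing, origin=tuple(new_origin),
                  modality=v.modality)


def normalize_intensity(v: Volume, lower_pct: float = 0.01,
                        upper_pct: float = 0.99) -> Volume:
    """Robust percentile rescaling into the closed interval [-1, 1].

    Values at/below the lower percentile map to -1, at/above the upper to
    +1, linear in between.  A constant volume has no percentile range and
    maps to all zeros (with a warning).
    """
    if not (0.0 <= lower_pct < upper_pct <= 1.0):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 1")
    # order statistics (not interpolated percentiles): re-normalizing
    # already-normalized data is then an exact identity
    lo = np.quantile(v.data, lower_pct, method="lower")
    hi = np.quantile(v.data, upper_pct, method="higher")
    if hi - lo <= 0:
        logger.warning("constant intensity volume: normalizing to all zeros")
        warnings.warn("constant intensity volume: normalized to all zeros",
                      stacklevel=2)
        return v.with_data(np.zeros_like(v.data))
    out = np.clip(2.0 * (v.data - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return v.with_data(out)


def preprocess(v: Volume, target_spacing=(1.0, 1.0, 5.0), target_size=None,
               lower_pct: float = 0.01, upper_pct: float = 0.99) -> Volume:
    """Resample -> crop/pad (optional) -> normalize to [-1, 1]."""
    out = resample(v, target_spacing)
    if target_size is not None:
        out = crop_or_pad(out, target_size, center_mode="foreground_centroid")
    return normalize_intensity(out, lower_pct, upper_pct)
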