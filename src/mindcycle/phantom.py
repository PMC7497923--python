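"""Synthetic multimodal phantom pairs with known ground-truth deformation.

Each case emulates a rigidly pre-aligned CT/MR pelvic pair at desk scale:
a shared anatomy (smooth soft-tissue gradient, a bladder-like ellipsoid, a
rectum-like tube, and two high-intensity bone shells), rendered under two
modality transfer maps whose tissue-class intensities are rank-permuted —
so raw intensity similarity fails across modalities while the underlying
structure matches — plus a smooth residual deformation between the pair
and independent per-modality noise.

The anatomy is an analytic function of continuous position, so the
modality-B volume is rendered at inverse-warped sample positions (the
ground-truth displacement inverted by fixed-point iteration).  As a
result, warping the B volume or mask by ``gt_field`` reproduces the
A-side anatomy exactly up to interpolation, masks are rendered
analytically in each space (no resampling error), and corresponding
landmarks satisfy ``p_b = p_a + f(p_a)`` exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .deformation import DeformationField, jacobian_folding_fraction, save_field
from .evaluation import LandmarkSet
from .volume_io import Modality, ROIMask, Volume, normalize_intensity, save_mask, save_volume

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_suite",
           "load_suite"]

LABEL_NAMES = {1: "bladder", 2: "rectum"}


@dataclass(frozen=True)
class PhantomConfig:
    size: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    n_organs: int = 2
    deformation_amplitude: float = 3.0
    deformation_smoothness: float = 8.0
    noise_sd: float = 0.02
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "size", tuple(int(n) for n in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if self.deformation_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if self.deformation_smoothness <= 0:
            raise ValueError("deformation smoothness must be > 0")
        if self.n_organs not in (1, 2):
            raise ValueError("n_organs must be 1 or 2")


@dataclass
class PhantomCase:
    vol_a: Volume
    vol_b: Volume
    mask_a: ROIMask
    mask_b: ROIMask
    gt_field: DeformationField
    landmarks_a: LandmarkSet
    landmarks_b: LandmarkSet
    config: PhantomConfig


class _Anatomy:
    """Analytic tissue-class geometry in voxel coordinates."""

    def __init__(self, cfg: PhantomConfig):
        X, Y, Z = cfg.size
        self.size = cfg.size
        self.n_organs = cfg.n_organs
        self.bladder_center = np.array([0.40 * X, 0.42 * Y, 0.5 * (Z - 1)])
        self.bladder_semi = np.array([0.14 * X, 0.15 * Y, max(0.34 * Z, 1.5)])
        self.rectum_center = np.array([0.72 * X, 0.62 * Y])
        self.rectum_radius = 0.08 * X
        self.bone_centers = [np.array([0.18 * X, 0.70 * Y]),
                             np.array([0.82 * X, 0.70 * Y])]
        self.bone_radius = 0.11 * X
        self.bone_thickness = 0.045 * X

    def labels(self, pts: np.ndarray) -> np.ndarray:
        """Tissue class per point: 0 soft, 1 bladder, 2 rectum, 3 bone."""
        pts = np.asarray(pts, dtype=np.float64)
        out = np.zeros(pts.shape[:-1], dtype=np.int32)
        d_bl = (((pts - self.bladder_center) / self.bladder_semi) ** 2).sum(-1)
        out[d_bl <= 1.0] = 1
        if self.n_organs >= 2:
            d_re = ((pts[..., :2] - self.rectum_center) ** 2).sum(-1)
            out[(d_re <= self.rectum_radius ** 2) & (out == 0)] = 2
        for c in self.bone_centers:
            rr = np.sqrt(((pts[..., :2] - c) ** 2).sum(-1))
            shell = np.abs(rr - self.bone_radius) <= self.bone_thickness
            out[shell & (out == 0)] = 3
        return out

    def render(self, pts: np.ndarray, modality: str) -> np.ndarray:
        """Intensity at continuous points under one modality transfer map.

        Tissue-class base intensities are rank-permuted between the two
        maps (and the soft-tissue gradient reversed), so the pair is
        non-monotonically related across classes.
        """
        X = self.size[0]
        lab = self.labels(pts)
        gx = pts[..., 0] / X
        if modality == "A":
            base = 0.28 + 0.10 * gx
            table = {1: 0.42, 2: 0.55, 3: 1.00}
        else:
            base = 0.62 - 0.10 * gx
            table = {1: 0.95, 2: 0.12, 3: 0.75}
        out = np.where(lab == 0, base, 0.0)
        for k, v in table.items():
            out = np.where(lab == k, v, out)
        return out

    def landmarks(self) -> np.ndarray:
        """Points on the bone shells (voxel coordinates) — bright in both maps."""
        Z = self.size[2]
        zc = 0.5 * (Z - 1)
        pts = []
        for c in self.bone_centers:
            for ang in (0.0, 2.0 * np.pi / 3, 4.0 * np.pi / 3):
                pts.append([c[0] + self.bone_radius * np.cos(ang),
                            c[1] + self.bone_radius * np.sin(ang), zc])
        return np.asarray(pts)


def _smooth_field(cfg: PhantomConfig, rng) -> np.ndarray:
    """Gaussian-smoothed white-noise displacement, scaled to amplitude."""
    X, Y, Z = cfg.size
    s = cfg.deformation_smoothness
    sz = max(1.0, s * cfg.spacing[0] / cfg.spacing[2])
    disp = np.empty((3, X, Y, Z))
    for ax in range(3):
        noise = rng.standard_normal((X, Y, Z))
        disp[ax] = ndimage.gaussian_filter(noise, sigma=(s, s, sz),
                                           mode="reflect")
    mag = np.sqrt((disp ** 2).sum(axis=0))
    peak = mag.max()
    if peak > 0 and cfg.deformation_amplitude > 0:
        disp *= cfg.deformation_amplitude / peak
    else:
        disp[:] = 0.0
    # keep through-plane displacement commensurate in mm with thick slices
    disp[2] *= cfg.spacing[0] / cfg.spacing[2]
    return disp


def _invert_displacement(disp: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point inversion u with (id + u) = (id + f)^{-1} on the grid."""
    shape = disp.shape[1:]
    base = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                indexing="ij"), axis=0)
    u = np.zeros_like(disp)
    for _ in range(n_iter):
        coords = base + u
        sampled = np.stack([ndimage.map_coordinates(disp[ax], coords, order=1,
                                                    mode="nearest")
                            for ax in range(3)])
        u = -sampled
    return u


def _noise(rng, shape, cfg: PhantomConfig) -> np.ndarray:
    """Spatially correlated Gaussian noise (sd in intensity units).

    Reconstructed medical images carry noise that is correlated over a
    voxel or two, not i.i.d.; correlated noise also survives trilinear
    resampling, so descriptors stay comparable between a warped and an
    unwarped rendering.
    """
    n = rng.standard_normal(shape)
    if cfg.noise_sigma > 0:
        n = ndimage.gaussian_filter(n, cfg.noise_sigma)
        sd = n.std()
        if sd > 0:
            n /= sd
    return n * cfg.noise_sd


def generate_case(cfg: PhantomConfig) -> PhantomCase:
    """Deterministically generate one phantom pair from its config/seed."""
    rng = np.random.default_rng(cfg.seed)
    anatomy = _Anatomy(cfg)
    X, Y, Z = cfg.size
    grid = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64)
                                  for n in cfg.size], indexing="ij"), axis=-1)

    disp = _smooth_field(cfg, rng)
    gt_field = DeformationField(disp, spacing=cfg.spacing)
    if cfg.deformation_amplitude > 0 and jacobian_folding_fraction(gt_field) > 0:
        raise ValueError(
            "ground-truth field folds; reduce deformation_amplitude or "
            "increase deformation_smoothness")
    u = _invert_displacement(disp)
    warped_grid = grid + np.moveaxis(u, 0, -1)

    raw_a = anatomy.render(grid, "A")
    raw_b = anatomy.render(warped_grid, "B")
    raw_a = raw_a + _noise(rng, raw_a.shape, cfg)
    raw_b = raw_b + _noise(rng, raw_b.shape, cfg)

    vol_a = normalize_intensity(Volume(raw_a, cfg.spacing,
                                       modality=Modality.SYNTH_A))
    vol_b = normalize_intensity(Volume(raw_b, cfg.spacing,
                                       modality=Modality.SYNTH_B))

    lab_a = anatomy.labels(grid)
    lab_b = anatomy.labels(warped_grid)
    organ = lambda l: np.where(l <= cfg.n_organs, l, 0).astype(np.int32)
    mask_a = ROIMask(organ(lab_a), LABEL_NAMES, cfg.spacing)
    mask_b = ROIMask(organ(lab_b), LABEL_NAMES, cfg.spacing)

    pts_a_vox = anatomy.landmarks()
    spacing = np.asarray(cfg.spacing)
    coords = pts_a_vox.T
    f_at_a = np.stack([ndimage.map_coordinates(disp[ax], coords, order=1,
                                               mode="nearest")
                       for ax in range(3)], axis=1)
    pts_a_mm = pts_a_vox * spacing
    pts_b_mm = (pts_a_vox + f_at_a) * spacing
    landmarks_a = LandmarkSet(pts_a_mm)
    landmarks_b = LandmarkSet(pts_b_mm)

    return PhantomCase(vol_a, vol_b, mask_a, mask_b, gt_field,
                       landmarks_a, landmarks_b, cfg)


def generate_suite(out_dir, n_train: int, n_test: int, base_seed: int = 0,
                   cfg: PhantomConfig = PhantomConfig(),
                   overwrite: bool = False) -> dict:
    """Write n_train + n_test cases (seeds base_seed + i) plus a manifest."""
    if n_train < 0 or n_test < 0:
        raise ValueError("case counts must be >= 0")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {out_dir} is not empty (use overwrite)")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # JSON-native config (tuples become lists) so the manifest on disk
    # compares equal to the returned object
    manifest = {"config": json.loads(json.dumps(asdict(cfg))),
                "base_seed": base_seed, "train": [], "test": []}
    for i in range(n_train + n_test):
        case_cfg = PhantomConfig(**{**asdict(cfg), "seed": base_seed + i})
        case = generate_case(case_cfg)
        name = f"case_{i:03d}"
        cdir = out_dir / name
        cdir.mkdir()
        save_volume(case.vol_a, cdir / "a.nii.gz")
        save_volume(case.vol_b, cdir / "b.nii.gz")
        save_mask(case.mask_a, cdir / "mask_a.nii.gz")
        save_mask(case.mask_b, cdir / "mask_b.nii.gz")
        save_field(case.gt_field, cdir / "gt_field.nii.gz")
        case.landmarks_a.save_csv(cdir / "landmarks_a.csv")
        case.landmarks_b.save_csv(cdir / "landmarks_b.csv")
        split = "train" if i < n_train else "test"
        manifest[split].append({"name": name, "seed": base_seed + i})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_suite(suite_dir, split: str | None = None) -> list[dict]:
    """Load cases written by :func:`generate_suite` back into memory."""
    from .deformation import load_field
    from .volume_io import load_mask, load_volume

    suite_dir = Path(suite_dir)
    try:
        with open(suite_dir / "manifest.json") as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError) as err:
        raise ValueError(f"corrupt or missing manifest in {suite_dir}: {err}")
    names = []
    for sp in ("train", "test"):
        if split in (None, sp):
            names.extend((e["name"], sp) for e in manifest[sp])
    cases = []
    for name, sp in names:
        cdir = suite_dir / name
        label_names = {int(k): v for k, v in LABEL_NAMES.items()}
        cases.append({
            "name": name, "split": sp,
            "vol_a": load_volume(cdir / "a.nii.gz", modality=Modality.SYNTH_A),
            "vol_b": load_volume(cdir / "b.nii.gz", modality=Modality.SYNTH_B),
            "mask_a": load_mask(cdir / "mask_a.nii.gz", label_names),
            "mask_b": load_mask(cdir / "mask_b.nii.gz", label_names),
            "gt_field": load_field(cdir / "gt_field.nii.gz"),
            "landmarks_a": LandmarkSet.load_csv(cdir / "landmarks_a.csv"),
            "landmarks_b": LandmarkSet.load_csv(cdir / "landmarks_b.csv"),
        })
    return cases
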