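"""Shared fixtures and independent oracle implementations.

The oracles here (brute-force MIND, index-shift warps) are deliberately
written as straightforward per-voxel loops, independent of the vectorized
library paths they validate.
"""

import numpy as np
import pytest

from mindcycle import autodiff as ad
from mindcycle.mind import MindConfig, _epsilon
from mindcycle.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.normal(size=(8, 8, 4)))


@pytest.fixture
def smooth_volume():
    """Bandlimited sinusoid phantom: smooth enough for interpolation bounds."""
    x, y, z = np.meshgrid(np.arange(16), np.arange(16), np.arange(8),
                          indexing="ij")
    data = (np.sin(2 * np.pi * x / 32) * np.cos(2 * np.pi * y / 32)
            + 0.5 * np.sin(2 * np.pi * z / 16))
    return Volume(data, spacing=(1.0, 1.0, 5.0))


def brute_force_patch_distance(data, x, r, cfg):
    """Per-voxel loop implementation of the summed squared patch distance."""
    shape = data.shape
    total = 0.0
    for p in cfg.patch_offsets:
        a = tuple(int(np.clip(xi + pi, 0, m - 1))
                  for xi, pi, m in zip(x, p, shape))
        b = tuple(int(np.clip(ai + ri, 0, m - 1))
                  for ai, ri, m in zip(a, r, shape))
        d = data[a] - data[b]
        total += d * d
    return total


def brute_force_variance(data, x, cfg):
    offs = cfg.variance_offsets
    mean_d = sum(brute_force_patch_distance(data, x, n, cfg)
                 for n in offs) / len(offs)
    return max(mean_d, _epsilon(data, cfg))


def brute_force_mind(data, cfg):
    """Per-voxel brute-force MIND descriptor (|R|, X, Y, Z)."""
    shape = data.shape
    R = cfg.search_offsets
    out = np.zeros((len(R),) + shape)
    for ix in range(shape[0]):
        for iy in range(shape[1]):
            for iz in range(shape[2]):
                x = (ix, iy, iz)
                v = brute_force_variance(data, x, cfg)
                resp = np.array([
                    np.exp(-brute_force_patch_distance(data, x, r, cfg) / v)
                    for r in R])
                out[:, ix, iy, iz] = resp / resp.max()
    return out


def shift_with_clamp(data, offset):
    """Index-shift oracle: out[x] = data[clip(x + offset)]."""
    out = data
    for ax, k in enumerate(offset):
        idx = np.clip(np.arange(data.shape[ax]) + k, 0, data.shape[ax] - 1)
        out = np.take(out, idx, axis=ax)
    return out


class ConstantFieldNet:
    """Network stub emitting a fixed uniform displacement."""

    def __init__(self, displacement, shape):
        disp = np.zeros((3,) + tuple(shape))
        for ax, d in enumerate(displacement):
            disp[ax] = d
        self.disp = disp

    def __call__(self, moving, fixed):
        return ad.Tensor(self.disp)


@pytest.fixture
def mind_cfg_small():
    return MindConfig(patch_size=3, region_size=3)
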