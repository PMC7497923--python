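"""Fully convolutional displacement-field regression network.

The network maps a two-channel (moving, fixed) volume pair to a dense
displacement field of the same grid size: an encoder of stride-2 3x3x3
convolutions with ReLU, a stack of residual blocks at the coarsest scale,
and a decoder of nearest-neighbor upsampling + stride-1 3x3x3 convolutions
back to full resolution, finished by a 1x1x1 convolution to 3 channels.

Conventions chosen where the architecture leaves room:

- downsampling strides are in-plane only by default (thick-slice volumes
  have too few slices to halve repeatedly);
- upsampling is resize + convolution rather than transposed convolution,
  avoiding checkerboard artifacts;
- the head is ``max_displacement * tanh(raw)``, bounding the field;
- with ``final_zero_init`` the head starts at zero so the initial
  transform is exactly the identity.

Residual blocks are two 3x3x3 stride-1 convolutions with instance
normalization, ReLU and an identity skip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .deformation import DeformationField
from .volume_io import Volume

__all__ = ["NetworkConfig", "RegistrationNetwork", "build_network",
           "predict_field", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    in_size: tuple[int, int, int] = (32, 32, 8)
    base_channels: int = 32
    n_resnet_blocks: int = 9
    n_scales: int = 3
    final_zero_init: bool = True
    max_displacement: float = 10.0
    stride_z: int = 1
    field_scale: int = 1

    def __post_init__(self):
        object.__setattr__(self, "in_size", tuple(int(n) for n in self.in_size))
        if self.n_resnet_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.n_scales < 1:
            raise ValueError("need at least one scale")
        factor = 2 ** self.n_scales
        if self.in_size[0] % factor or self.in_size[1] % factor:
            raise ValueError(
                f"in-plane size {self.in_size[:2]} not divisible by {factor}")
        if self.stride_z == 2 and self.in_size[2] % factor:
            raise ValueError(
                f"through-plane size {self.in_size[2]} not divisible by {factor}")
        if self.stride_z not in (1, 2):
            raise ValueError("stride_z must be 1 or 2")
        if self.field_scale < 1 or self.field_scale & (self.field_scale - 1):
            raise ValueError("field_scale must be a power of two")
        if self.field_scale > factor:
            raise ValueError("field_scale cannot exceed the total stride")


@lru_cache(maxsize=256)
def _im2col_indices(cin, xp, yp, zp, ox, oy, oz, sx, sy, sz, k):
    """Flat gather indices turning conv3d into a (L, cin*k^3) matmul."""
    gx = np.arange(ox) * sx
    gy = np.arange(oy) * sy
    gz = np.arange(oz) * sz
    start = ((gx[:, None, None] * yp + gy[None, :, None]) * zp
             + gz[None, None, :]).reshape(-1)
    c = np.arange(cin)
    kx, ky, kz = np.meshgrid(np.arange(k), np.arange(k), np.arange(k),
                             indexing="ij")
    offs = (((c[:, None] * xp + kx.reshape(-1)[None, :]) * yp
             + ky.reshape(-1)[None, :]) * zp + kz.reshape(-1)[None, :])
    return start[:, None] + offs.reshape(1, -1)


@lru_cache(maxsize=64)
def _upsample_indices(c, x, y, z, zfac=1):
    """Gather indices for nearest-neighbor 2x in-plane upsampling."""
    ci = np.arange(c)
    xi = np.repeat(np.arange(x), 2)
    yi = np.repeat(np.arange(y), 2)
    zi = np.repeat(np.arange(z), zfac)
    return (((ci[:, None, None, None] * x + xi[None, :, None, None]) * y
             + yi[None, None, :, None]) * z + zi[None, None, None, :])


def _linear_upsample2(t: ad.Tensor, axes) -> ad.Tensor:
    """Differentiable 2x linear upsampling along the given axes.

    Half-sample (align_corners=False) convention with edge replication:
    out[2i] = 0.75 in[i] + 0.25 in[i-1], out[2i+1] = 0.75 in[i] + 0.25 in[i+1].
    """
    for ax in axes:
        even = 0.75 * t + 0.25 * ad.shift_axis(t, ax, -1)
        odd = 0.75 * t + 0.25 * ad.shift_axis(t, ax, 1)
        pair = ad.stack([even, odd], axis=ax + 1)
        shape = list(t.value.shape)
        shape[ax] *= 2
        t = pair.reshape(tuple(shape))
    return t


class Conv3d:
    """3x3x3 (or 1x1x1) convolution, zero padding, arbitrary stride."""

    def __init__(self, cin, cout, rng, kernel=3, stride=(1, 1, 1),
                 zero_init=False):
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.stride = tuple(stride)
        fan_in = cin * kernel ** 3
        if zero_init:
            w = np.zeros((fan_in, cout))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.weight = ad.Tensor(w, requires_grad=True)
        self.bias = ad.Tensor(np.zeros(cout), requires_grad=True)

    @property
    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, t: ad.Tensor) -> ad.Tensor:
        cin, X, Y, Z = t.value.shape
        k = self.kernel
        pad = (k - 1) // 2
        sx, sy, sz = self.stride
        if pad:
            t = ad.pad_zero(t, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
        xp, yp, zp = X + 2 * pad, Y + 2 * pad, Z + 2 * pad
        ox = (xp - k) // sx + 1
        oy = (yp - k) // sy + 1
        oz = (zp - k) // sz + 1
        idx = _im2col_indices(cin, xp, yp, zp, ox, oy, oz, sx, sy, sz, k)
        cols = ad.take(t, idx, out_shape=idx.shape)
        out = ad.matmul(cols, self.weight) + self.bias.reshape((1, self.cout))
        return out.transpose((1, 0)).reshape((self.cout, ox, oy, oz))


class InstanceNorm:
    def __init__(self, channels):
        self.gamma = ad.Tensor(np.ones(channels), requires_grad=True)
        self.beta = ad.Tensor(np.zeros(channels), requires_grad=True)

    @property
    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, t: ad.Tensor, eps: float = 1e-5) -> ad.Tensor:
        mu = t.mean(axis=(1, 2, 3), keepdims=True)
        xc = t - mu
        var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
        norm = xc / (var + eps) ** 0.5
        c = t.value.shape[0]
        return norm * self.gamma.reshape((c, 1, 1, 1)) \
            + self.beta.reshape((c, 1, 1, 1))


class ResnetBlock:
    def __init__(self, channels, rng):
        self.conv1 = Conv3d(channels, channels, rng)
        self.norm1 = InstanceNorm(channels)
        self.conv2 = Conv3d(channels, channels, rng)
        self.norm2 = InstanceNorm(channels)

    @property
    def parameters(self):
        return (self.conv1.parameters + self.norm1.parameters
                + self.conv2.parameters + self.norm2.parameters)

    def __call__(self, t: ad.Tensor) -> ad.Tensor:
        h = ad.relu(self.norm1(self.conv1(t)))
        h = self.norm2(self.conv2(h))
        return t + h


class RegistrationNetwork:
    """Maps a (moving, fixed) pair to a displacement field (voxel units)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        b = config.base_channels
        down_ch = [b * 2 ** i for i in range(config.n_scales)]
        sz = config.stride_z
        self.down = []
        cin = 2
        for c in down_ch:
            self.down.append(Conv3d(cin, c, rng, stride=(2, 2, sz)))
            cin = c
        self.blocks = [ResnetBlock(cin, rng)
                       for _ in range(config.n_resnet_blocks)]
        up_ch = [max(b, c) for c in reversed(down_ch[:-1])] + [b]
        # with field_scale > 1 the decoder stops early and the head emits
        # the field on a coarser grid, linearly upsampled afterwards —
        # each coarse degree of freedom then aggregates the loss gradient
        # of field_scale^2 voxels, which speeds up convergence on smooth
        # deformations at no cost in expressiveness
        n_up = config.n_scales - int(np.log2(config.field_scale))
        self.up = []
        for c in up_ch[:n_up]:
            self.up.append(Conv3d(cin, c, rng))
            cin = c
        self.head = Conv3d(cin, 3, rng, kernel=1,
                           zero_init=config.final_zero_init)

    def parameters(self) -> list[ad.Tensor]:
        params = []
        for layer in self.down + self.blocks + self.up + [self.head]:
            params.extend(layer.parameters)
        return params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def __call__(self, moving: ad.Tensor, fixed: ad.Tensor) -> ad.Tensor:
        """Forward pass on (X, Y, Z) tensors; returns a (3, X, Y, Z) field."""
        shape = moving.value.shape
        if fixed.value.shape != shape:
            raise ValueError("moving and fixed volumes must share a grid")
        if tuple(shape) != self.config.in_size:
            raise ValueError(
                f"input size {shape} does not match config {self.config.in_size}")
        x = ad.stack([moving, fixed], axis=0)
        for conv in self.down:
            x = ad.relu(conv(x))
        for block in self.blocks:
            x = block(x)
        for conv in self.up:
            c, X, Y, Z = x.value.shape
            zfac = 2 if self.config.stride_z == 2 else 1
            x = ad.take(x, _upsample_indices(c, X, Y, Z, zfac),
                        out_shape=(c, 2 * X, 2 * Y, zfac * Z))
            x = ad.relu(conv(x))
        raw = self.head(x)
        field = self.config.max_displacement * ad.tanh(raw)
        fs = self.config.field_scale
        while fs > 1:
            field = _linear_upsample2(field, axes=(1, 2))
            fs //= 2
        return field

    def predict_field(self, moving: Volume, fixed: Volume) -> DeformationField:
        field = self(ad.Tensor(moving.data), ad.Tensor(fixed.data))
        return DeformationField(field.value, spacing=moving.spacing)


def build_network(cfg: NetworkConfig, seed: int) -> RegistrationNetwork:
    """Deterministically construct a network from a config and seed."""
    return RegistrationNetwork(cfg, seed)


def predict_field(net: RegistrationNetwork, moving: Volume,
                  fixed: Volume) -> DeformationField:
    return net.predict_field(moving, fixed)


def save_checkpoint(path, net_a2b: RegistrationNetwork,
                    net_b2a: RegistrationNetwork, meta: dict | None = None):
    """Save both networks' parameters plus config into one .npz file."""
    arrays = {}
    for tag, net in (("a2b", net_a2b), ("b2a", net_b2a)):
        for i, p in enumerate(net.parameters()):
            arrays[f"{tag}_{i}"] = p.value
    cfg = json.dumps({"config": asdict(net_a2b.config), "meta": meta or {}})
    np.savez(path, __meta__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Load a dual-network checkpoint; returns (net_a2b, net_b2a, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["config"].items()})
        nets = []
        for tag in ("a2b", "b2a"):
            net = RegistrationNetwork(cfg, seed=0)
            for i, p in enumerate(net.parameters()):
                p.value = np.array(data[f"{tag}_{i}"], dtype=np.float64)
            nets.append(net)
    return nets[0], nets[1], meta["meta"]
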