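"""Attention and pooling blocks of the segmentation network.

Four composable units:

* :class:`CGRBlock` — multi-kernel context gating with a residual skip. Each
  path runs two same-padding convolutions at one kernel size, squashes the
  result through a sigmoid to get per-pixel gates in (0,1), and multiplies
  the gates with the input; the gated paths are summed and added to the
  residual input.
* :class:`GCABlock` — global context attention. A 1x1 convolution scores
  every position, a spatial softmax turns the scores into a distribution,
  and the attention-weighted sum of the input yields a per-channel context
  vector; a bottleneck transform (1x1 conv -> layer norm -> ReLU -> 1x1
  conv, zero-initialized) is broadcast-added back to every position.
* :class:`MRPBlock` — multipath pooling: non-overlapping max pooling at
  several window sizes, a 1x1 convolution to one channel per path, bilinear
  upsampling back to the input grid, and concatenation with the input
  (output channels = input channels + number of paths).
* :class:`RCAModule` — residual context aggregation for the decoder: a
  pyramid of adaptive average pools (bins 1,2,3,6), 1x1 convolutions
  (zero-initialized), upsampling and summation, added residually to the
  input.

Plus :class:`DecoderBlock` (4x4 transposed conv x2 upsampling, skip
concatenation, two 3x3 conv + BN + ReLU) and :class:`CAGPModule`, the
bottleneck composition CGR -> GCA -> MRP -> 1x1 fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


class ConfigurationError(ValueError):
    pass


@dataclass
class GatingParams:
    """Parameters of a single 1x1 gating convolution (maps C -> C)."""

    weight: np.ndarray  # (C, C)
    bias: np.ndarray    # (C,)

    def validate(self, channels: int) -> None:
        if self.weight.shape != (channels, channels) or self.bias.shape != (channels,):
            raise ConfigurationError(
                f"gating params shaped {self.weight.shape}/{self.bias.shape} "
                f"do not fit {channels} channels")


@dataclass
class BlockConfig:
    """Hyperparameters shared by the bottleneck blocks.

    ``channels`` may be left ``None`` in a model-level config and resolved
    against the encoder's deepest feature width at build time.
    """

    channels: int | None = None
    cgr_kernel_sizes: tuple[int, ...] = (3, 5, 7, 9)
    mrp_pool_sizes: tuple[int, ...] = (2, 3, 5, 7)
    gca_bottleneck_ratio: int = 16
    rca_pyramid_bins: tuple[int, ...] = (1, 2, 3, 6)

    def __post_init__(self):
        for k in self.cgr_kernel_sizes:
            if k <= 0 or k % 2 == 0:
                raise ConfigurationError(
                    f"CGR kernel size {k} invalid: same-padding needs odd sizes")
        for p in self.mrp_pool_sizes:
            if p <= 0:
                raise ConfigurationError(f"MRP pool size {p} must be positive")
        if self.gca_bottleneck_ratio <= 0:
            raise ConfigurationError("bottleneck ratio must be positive")
        if self.channels is not None:
            if self.channels <= 0:
                raise ConfigurationError("channels must be positive")
            if self.channels % self.gca_bottleneck_ratio != 0:
                raise ConfigurationError(
                    f"channels={self.channels} not divisible by "
                    f"bottleneck ratio r={self.gca_bottleneck_ratio}")

    def resolved(self, channels: int) -> "BlockConfig":
        return BlockConfig(channels, self.cgr_kernel_sizes, self.mrp_pool_sizes,
                           self.gca_bottleneck_ratio, self.rca_pyramid_bins)


def context_gate(x: np.ndarray, params: GatingParams) -> np.ndarray:
    """Self-gating: ``x * sigmoid(W*x + a)`` with a per-pixel 1x1 projection.

    Accepts (C,H,W) or (N,C,H,W) arrays; the gate values lie strictly in
    (0,1) so the output magnitude never exceeds the input's.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    c = x.shape[1]
    params.validate(c)
    z = np.einsum("oc,nchw->nohw", params.weight, x) + params.bias[None, :, None, None]
    gate = 1.0 / (1.0 + np.exp(-z))
    out = x * gate
    return out[0] if squeeze else out


class ContextGate(nn.Module):
    """Learnable 1x1 self-gating layer (module form of :func:`context_gate`)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x * nn.sigmoid(self.conv(x))


class CGRBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel_sizes: tuple[int, ...] = (3, 5, 7, 9)):
        super().__init__()
        self.kernel_sizes = tuple(kernel_sizes)
        for i, k in enumerate(self.kernel_sizes):
            if k % 2 == 0:
                raise ConfigurationError(
                    f"CGR kernel size {k} is even; same-padding undefined")
            setattr(self, f"conv{i}a", nn.Conv2d(channels, channels, k, rng))
            setattr(self, f"conv{i}b", nn.Conv2d(channels, channels, k, rng))

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for i in range(len(self.kernel_sizes)):
            a = getattr(self, f"conv{i}a")
            b = getattr(self, f"conv{i}b")
            gate = nn.sigmoid(b(nn.relu(a(x))))
            out = out + x * gate
        return out


class GCABlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator, ratio: int = 16):
        super().__init__()
        if channels % ratio != 0:
            raise ConfigurationError(
                f"channels={channels} not divisible by bottleneck ratio r={ratio}")
        self.score = nn.Conv2d(channels, 1, 1, rng)
        self.squeeze = nn.Conv2d(channels, channels // ratio, 1, rng)
        self.ln = nn.LayerNorm(channels // ratio)
        # zero-init so the block starts as the identity map
        self.expand = nn.Conv2d(channels // ratio, channels, 1, rng, zero_init=True)

    def attention(self, x: Tensor) -> Tensor:
        """Spatial attention map, shape (N,1,H,W), sums to 1 over H*W."""
        n, _, h, w = x.shape
        logits = nn.reshape(self.score(x), (n, 1, h * w))
        return nn.reshape(nn.softmax(logits, axis=2), (n, 1, h, w))

    def context(self, x: Tensor) -> Tensor:
        """Attention-pooled context vector, shape (N,C,1,1)."""
        return (x * self.attention(x)).sum(axis=(2, 3), keepdims=True)

    def forward(self, x: Tensor) -> Tensor:
        ctx = self.context(x)
        return x + self.expand(nn.relu(self.ln(self.squeeze(ctx))))


class MRPBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 pool_sizes: tuple[int, ...] = (2, 3, 5, 7),
                 upsample_mode: str = "bilinear", clip_to_input: bool = False):
        super().__init__()
        self.pool_sizes = tuple(pool_sizes)
        self.upsample_mode = upsample_mode
        # inside the network the deepest map can be smaller than 7x7 (e.g.
        # 64x64 inputs give a 2x2 bottleneck); clip_to_input caps each
        # window at the feature size instead of failing
        self.clip_to_input = clip_to_input
        for i, _ in enumerate(self.pool_sizes):
            setattr(self, f"reduce{i}", nn.Conv2d(channels, 1, 1, rng))

    @property
    def extra_channels(self) -> int:
        return len(self.pool_sizes)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        largest = max(self.pool_sizes)
        if (h < largest or w < largest) and not self.clip_to_input:
            raise ValueError(
                f"MRP input {h}x{w} smaller than largest pool window {largest}")
        paths = [x]
        for i, p in enumerate(self.pool_sizes):
            p = min(p, h, w)
            pooled = nn.max_pool2d(x, p)  # stride = window, floor mode
            reduced = getattr(self, f"reduce{i}")(pooled)
            paths.append(nn.upsample(reduced, (h, w), mode=self.upsample_mode))
        return nn.concat(paths, axis=1)


class CAGPModule(nn.Module):
    """Bottleneck composition: CGR -> GCA -> MRP -> 1x1 fusion."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, config: BlockConfig | None = None):
        super().__init__()
        cfg = (config or BlockConfig()).resolved(in_channels)
        self.cgr = CGRBlock(in_channels, rng, cfg.cgr_kernel_sizes)
        self.gca = GCABlock(in_channels, rng, cfg.gca_bottleneck_ratio)
        self.mrp = MRPBlock(in_channels, rng, cfg.mrp_pool_sizes,
                            clip_to_input=True)
        self.fuse = nn.Conv2d(in_channels + self.mrp.extra_channels,
                              out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(self.mrp(self.gca(self.cgr(x))))


class DecoderBlock(nn.Module):
    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_channels, out_channels, 4, rng,
                                     stride=2, padding=1)
        self.conv1 = nn.Conv2d(out_channels + skip_channels, out_channels, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        _, _, h, w = x.shape
        _, _, hs, ws = skip.shape
        if (hs, ws) != (2 * h, 2 * w):
            raise ValueError(
                f"decoder skip {hs}x{ws} must be exactly twice the input "
                f"{h}x{w}")
        y = self.up(x)
        y = nn.concat([y, skip], axis=1)
        y = nn.relu(self.bn1(self.conv1(y)))
        y = nn.relu(self.bn2(self.conv2(y)))
        return y


class RCAModule(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 bins: tuple[int, ...] = (1, 2, 3, 6),
                 clip_to_input: bool = False):
        super().__init__()
        self.bins = tuple(bins)
        self.clip_to_input = clip_to_input
        for i, _ in enumerate(self.bins):
            # zero-init: the module starts as the identity
            setattr(self, f"proj{i}",
                    nn.Conv2d(channels, channels, 1, rng, zero_init=True))

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        largest = max(self.bins)
        if (h < largest or w < largest) and not self.clip_to_input:
            raise ValueError(
                f"RCA input {h}x{w} smaller than largest pyramid bin {largest}")
        ctx = None
        for i, b in enumerate(self.bins):
            pooled = nn.adaptive_avg_pool2d(x, min(b, h, w))
            path = nn.upsample(getattr(self, f"proj{i}")(pooled), (h, w),
                               mode="bilinear")
            ctx = path if ctx is None else ctx + path
        return x + ctx
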