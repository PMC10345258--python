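"""Full encoder-decoder assembly and training loss.

The encoder is a densely connected CNN (DenseNet-style: bottlenecked dense
layers with feature concatenation and halving transitions). It exposes four
skip feature maps at strides 2/4/8/16 plus the deepest map at stride 32.
The deepest map passes through the CAGP bottleneck; four decoder stages
(transposed-conv upsampling + skip fusion, each followed by a residual
context aggregation module) bring the resolution back to stride 2, and a
final bilinear x2 + 1x1 convolution + sigmoid head produces a per-pixel
foreground probability map at the input resolution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .blocks import (BlockConfig, CAGPModule, ConfigurationError, DecoderBlock,
                     RCAModule)

#: name -> (initial channels, growth rate, layers per dense block)
ENCODER_SPECS = {
    "densenet121": dict(init_channels=64, growth=32, block_layers=(6, 12, 24, 16)),
    # compact variant with the same topology; keeps CPU training fast
    "densenet-mini": dict(init_channels=16, growth=8, block_layers=(2, 2, 2, 2)),
}


@dataclass
class ModelConfig:
    encoder_name: str = "densenet121"
    pretrained: bool = False
    decoder_widths: tuple[int, int, int, int] = (256, 128, 64, 32)
    blocks: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 0

    def __post_init__(self):
        if self.encoder_name not in ENCODER_SPECS:
            raise ConfigurationError(
                f"unknown encoder {self.encoder_name!r}; "
                f"available: {sorted(ENCODER_SPECS)}")
        if len(self.decoder_widths) != 4:
            raise ConfigurationError("decoder_widths must list 4 stage widths")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decoder_widths"] = list(self.decoder_widths)
        d["blocks"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.blocks).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        blocks = d.pop("blocks", {})
        blocks = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in blocks.items()}
        return cls(blocks=BlockConfig(**blocks),
                   decoder_widths=tuple(d.pop("decoder_widths", (256, 128, 64, 32))),
                   **d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class _DenseLayer(nn.Module):
    def __init__(self, in_channels: int, growth: int, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_channels)
        self.conv1 = nn.Conv2d(in_channels, 4 * growth, 1, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(4 * growth)
        self.conv2 = nn.Conv2d(4 * growth, growth, 3, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(nn.relu(self.bn1(x)))
        y = self.conv2(nn.relu(self.bn2(y)))
        return nn.concat([x, y], axis=1)


class _DenseBlock(nn.Module):
    def __init__(self, in_channels: int, n_layers: int, growth: int, rng):
        super().__init__()
        c = in_channels
        self.layers = []
        for i in range(n_layers):
            layer = _DenseLayer(c, growth, rng)
            setattr(self, f"layer{i}", layer)
            self.layers.append(layer)
            c += growth
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _Transition(nn.Module):
    def __init__(self, in_channels: int, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, in_channels // 2, 1, rng, bias=False)
        self.out_channels = in_channels // 2

    def forward(self, x: Tensor) -> Tensor:
        return nn.avg_pool2d(self.conv(nn.relu(self.bn(x))), 2)


class DenseEncoder(nn.Module):
    """Returns 4 skip maps (strides 2,4,8,16) and the deepest map (stride 32)."""

    def __init__(self, name: str, rng):
        super().__init__()
        spec = ENCODER_SPECS[name]
        c0, growth = spec["init_channels"], spec["growth"]
        self.stem_conv = nn.Conv2d(3, c0, 7, rng, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(c0)
        self.skip_channels = [c0]
        c = c0
        blocks, transitions = [], []
        for i, n_layers in enumerate(spec["block_layers"]):
            block = _DenseBlock(c, n_layers, growth, rng)
            setattr(self, f"block{i}", block)
            blocks.append(block)
            c = block.out_channels
            if i < 3:
                self.skip_channels.append(c)
                tr = _Transition(c, rng)
                setattr(self, f"transition{i}", tr)
                transitions.append(tr)
                c = tr.out_channels
        self.blocks_list = blocks
        self.transitions = transitions
        self.final_bn = nn.BatchNorm2d(c)
        self.out_channels = c

    def forward(self, x: Tensor):
        x0 = nn.relu(self.stem_bn(self.stem_conv(x)))          # stride 2
        skips = [x0]
        y = nn.max_pool2d(x0, 3, stride=2, padding=1)          # stride 4
        for i in range(4):
            y = self.blocks_list[i](y)
            if i < 3:
                skips.append(y)
                y = self.transitions[i](y)
        deepest = nn.relu(self.final_bn(y))                    # stride 32
        return skips, deepest


class GCUNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = DenseEncoder(config.encoder_name, rng)
        widths = config.decoder_widths
        self.cagp = CAGPModule(self.encoder.out_channels, widths[0], rng,
                               config.blocks)
        skip_ch = self.encoder.skip_channels  # strides [2, 4, 8, 16]
        in_ch = widths[0]
        bins = config.blocks.rca_pyramid_bins
        for i, w in enumerate(widths):
            skip = skip_ch[3 - i]
            setattr(self, f"decode{i}", DecoderBlock(in_ch, skip, w, rng))
            setattr(self, f"rca{i}", RCAModule(w, rng, bins, clip_to_input=True))
            in_ch = w
        self.head = nn.Conv2d(widths[-1], 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        _, _, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(
                f"input {h}x{w} not divisible by 32; pad to a multiple of 32 "
                f"(e.g. reflect-pad) before the forward pass")
        skips, deepest = self.encoder(x)
        y = self.cagp(deepest)
        for i in range(4):
            y = getattr(self, f"decode{i}")(y, skips[3 - i])
            y = getattr(self, f"rca{i}")(y)
        y = nn.upsample(y, (h, w), mode="bilinear")
        return nn.sigmoid(self.head(y))


def build_model(config: ModelConfig) -> GCUNet:
    """Construct a seeded model. ``pretrained=True`` needs downloaded weights
    which this build never fetches, so it raises with an offline hint."""
    if config.pretrained:
        raise ConfigurationError(
            "pretrained=True requires published classification weights, which "
            "are not bundled; run with pretrained=False for offline use")
    return GCUNet(config)


def forward(model: GCUNet, image: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward on one (3,H,W) image in [0,1] -> (H,W) map."""
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model(image[None].astype(np.float32))
    finally:
        model.train(was_training)
    return out.data[0, 0]


def segmentation_loss(pred: Tensor, target, bce_weight: float = 1.0,
                      dice_weight: float = 1.0, eps: float = 1.0) -> Tensor:
    """Weighted sum of mean BCE and smooth dice loss on probabilities."""
    pred = nn.as_tensor(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred.shape != t.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {t.shape}")
    if bce_weight < 0 or dice_weight < 0:
        raise ValueError("loss weights must be nonnegative")
    bce = nn.binary_cross_entropy(pred, t)
    inter = (pred * t).sum()
    dice = 1.0 - (2.0 * inter + eps) / (pred.sum() + float(t.sum()) + eps)
    return bce * bce_weight + dice * dice_weight


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, model: GCUNet, optimizer=None, epoch: int = 0):
    """Parameter file (.npz) plus a JSON sidecar with the model config."""
    path = Path(path)
    state = model.state_dict()
    if optimizer is not None:
        for k, v in optimizer.state_dict().items():
            state["optim." + k] = v
    state["epoch"] = np.asarray(epoch)
    with open(path, "wb") as fh:
        np.savez(fh, **state)
    sidecar = {"config": model.config.to_dict(), "config_hash": model.config.hash(),
               "epoch": epoch}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[GCUNet, int, dict]:
    """Returns (model, epoch, optimizer_state). Build an optimizer over
    ``model.parameters()`` and pass the state to ``load_state_dict`` to
    resume."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    if config.hash() != sidecar["config_hash"]:
        raise ValueError(
            f"checkpoint sidecar hash {sidecar['config_hash']} does not match "
            f"its recorded config (recomputed {config.hash()}); refusing to load")
    model = build_model(config)
    with np.load(path, allow_pickle=False) as z:
        state = {k: z[k] for k in z.files}
    epoch = int(state.pop("epoch"))
    optim_state = {k[len("optim."):]: v for k, v in state.items()
                   if k.startswith("optim.")}
    state = {k: v for k, v in state.items() if not k.startswith("optim.")}
    model.load_state_dict(state)
    return model, epoch, optim_state
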