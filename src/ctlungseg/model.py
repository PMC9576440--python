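"""The 2D ResUnet segmentation network.

A U-shaped encoder–decoder over single-channel 2D slices. Its building
block concatenates the feature map entering the block with the feature
map produced by its convolutions ("Res" in the dense/concatenative
sense, not an additive residual): higher-dimensional features are
extracted while the original-dimensional features are retained, fusing
scales at every block. Activations are Leaky-ReLU, each convolution is
followed by batch normalization, and dropout regularizes the two
deepest levels. The output head is a 1×1 convolution + sigmoid yielding
a per-pixel lung probability in [0, 1].

A plain U-Net variant (standard double-conv blocks, no concatenative
shortcut) is provided for ablation comparisons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, concat, conv2d, maxpool2x, upsample_nearest2x
from .volume import CTVolume, MaskVolume

__all__ = [
    "ModelConfig",
    "ResBlock",
    "PlainBlock",
    "ResUNet",
    "build_resunet",
    "build_unet",
    "predict_case",
    "save_checkpoint",
    "load_checkpoint",
]

# HU window used to normalize network inputs to [0, 1]
HU_LO, HU_HI = -1000.0, 400.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``base_channels`` is the convolutional width of the shallowest
    level (doubling per level); ``depth`` the number of down/up levels,
    so inputs must be divisible by 2**depth; ``leaky_slope`` the
    negative slope of Leaky-ReLU; ``dropout_rate`` the drop probability
    at the two deepest levels.
    """

    in_channels: int = 1
    base_channels: int = 32
    depth: int = 4
    leaky_slope: float = 0.01
    dropout_rate: float = 0.2
    out_channels: int = 1
    block: str = "res"  # "res" (concatenative) or "plain"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.block not in ("res", "plain"):
            raise ValueError(f"block must be 'res' or 'plain', got {self.block!r}")


class ResBlock(nn.Module):
    """Two 3×3 conv+BN+Leaky-ReLU stages, output concatenated with input.

    With C_in input channels and ``filters`` convolutional channels the
    output carries C_in + filters channels; spatial size is unchanged.
    """

    def __init__(self, in_channels: int, filters: int, slope: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.slope = slope
        self.conv1 = nn.Conv2d(in_channels, filters, 3, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(filters, dtype=dtype)
        self.conv2 = nn.Conv2d(filters, filters, 3, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(filters, dtype=dtype)
        self.out_channels = in_channels + filters

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(self.slope)
        h = self.bn2(self.conv2(h)).leaky_relu(self.slope)
        out = concat([x, h], axis=1)
        if out.shape[2:] != x.shape[2:]:
            raise RuntimeError("ResBlock must preserve spatial size")
        return out


class PlainBlock(nn.Module):
    """Standard U-Net double conv block (no concatenative shortcut)."""

    def __init__(self, in_channels: int, filters: int, slope: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.slope = slope
        self.conv1 = nn.Conv2d(in_channels, filters, 3, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(filters, dtype=dtype)
        self.conv2 = nn.Conv2d(filters, filters, 3, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(filters, dtype=dtype)
        self.out_channels = filters

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(self.slope)
        return self.bn2(self.conv2(h)).leaky_relu(self.slope)


class ResUNet(nn.Module):
    """Encoder–decoder with skip connections and (concatenative) blocks.

    Layout: ``depth`` encoder levels (block + 2×2 max-pool), a
    bottleneck block, ``depth`` decoder levels (×2 upsample + 1×1
    channel reduction + skip concatenation + block), then a 1×1
    projection and sigmoid. Dropout acts on the deepest encoder output
    and the bottleneck output.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        Block = ResBlock if cfg.block == "res" else PlainBlock
        mk = lambda c_in, f: Block(c_in, f, cfg.leaky_slope, rng, dtype)

        self.encoders: list[nn.Module] = []
        ch = cfg.in_channels
        skip_channels = []
        for lvl in range(cfg.depth):
            blk = mk(ch, cfg.base_channels * 2**lvl)
            self.encoders.append(blk)
            skip_channels.append(blk.out_channels)
            ch = blk.out_channels
        self.bottleneck = mk(ch, cfg.base_channels * 2**cfg.depth)
        ch = self.bottleneck.out_channels

        self.reducers: list[nn.Module] = []
        self.decoders: list[nn.Module] = []
        for lvl in reversed(range(cfg.depth)):
            filters = cfg.base_channels * 2**lvl
            self.reducers.append(nn.Conv2d(ch, filters, 1, rng=rng, dtype=dtype))
            blk = mk(filters + skip_channels[lvl], filters)
            self.decoders.append(blk)
            ch = blk.out_channels
        self.head = nn.Conv2d(ch, cfg.out_channels, 1, rng=rng, dtype=dtype)
        self.dropout = nn.Dropout(cfg.dropout_rate, rng=np.random.default_rng(seed + 1))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2:]
        div = 2**self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {div}"
            )
        skips = []
        for lvl, enc in enumerate(self.encoders):
            x = enc(x)
            skips.append(x)
            if lvl == self.cfg.depth - 1:
                x = self.dropout(x)
            x = maxpool2x(x)
        x = self.dropout(self.bottleneck(x))
        for reducer, dec, skip in zip(self.reducers, self.decoders, reversed(skips)):
            x = reducer(upsample_nearest2x(x))
            x = dec(concat([skip, x], axis=1))
        return self.head(x).sigmoid()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_resunet(cfg: ModelConfig | None = None, seed: int = 0, dtype=np.float32) -> ResUNet:
    """Construct the concatenative ResUnet (the default architecture)."""
    return ResUNet(cfg or ModelConfig(), seed=seed, dtype=dtype)


def build_unet(cfg: ModelConfig | None = None, seed: int = 0, dtype=np.float32) -> ResUNet:
    """Construct the plain U-Net ablation variant (same depth/width)."""
    cfg = cfg or ModelConfig()
    return ResUNet(
        ModelConfig(**{**asdict(cfg), "block": "plain"}), seed=seed, dtype=dtype
    )


def normalize_hu(voxels: np.ndarray) -> np.ndarray:
    """Map HU to [0, 1] over the fixed (−1000, 400) window."""
    return ((np.clip(voxels, HU_LO, HU_HI) - HU_LO) / (HU_HI - HU_LO)).astype(np.float32)


def predict_case(
    net: ResUNet,
    volume: CTVolume,
    threshold: float = 0.5,
    batch_size: int = 8,
) -> MaskVolume:
    """Segment every slice of a (cropped) case and binarize at ``threshold``.

    Slices are processed independently in evaluation mode; the result is
    a stacked binary mask volume aligned with the input.
    """
    net.eval()
    n, h, w = volume.voxels.shape
    probs = np.empty((n, h, w), dtype=np.float32)
    x = normalize_hu(volume.voxels)[:, None]  # (N, 1, H, W)
    for start in range(0, n, batch_size):
        out = net(Tensor(x[start : start + batch_size]))
        probs[start : start + batch_size] = out.data[:, 0]
    return MaskVolume((probs >= threshold).astype(np.uint8), case_id=volume.case_id)


def save_checkpoint(net: ResUNet, path: str | Path) -> None:
    """Write weights (npz) with the architecture config embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(net.cfg)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **state)


def load_checkpoint(path: str | Path) -> ResUNet:
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        net = ResUNet(cfg)
        net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net
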