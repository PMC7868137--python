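"""The six-block patch discriminator.

The discriminator consumes a channel-concatenated (image, attention map)
pairing and emits a grid of per-patch real/fake probabilities rather than a
single logit: on the canonical 512x512 input the map is 30x30, i.e. 900
overlapping patches, each judged through a 142x142 receptive field.  The
scalar verdict is the arithmetic mean of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .errors import InvalidConfig, ShapeMismatch
from .nn import Tensor


@dataclass(frozen=True)
class BlockSpec:
    """One discriminator block: conv -> (batch norm) -> activation."""

    kernel: int
    stride: int
    padding: int
    channels: int
    activation: str = "relu"  # "relu" | "sigmoid"
    batchnorm: bool = True

    def __post_init__(self):
        if self.activation not in ("relu", "sigmoid"):
            raise InvalidConfig(f"unknown activation {self.activation!r}")
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise InvalidConfig("kernel/stride must be >= 1 and padding >= 0")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Six-block patch-discriminator architecture.

    The canonical geometry — four stride-2 blocks then two stride-1 blocks,
    all kernel 4 / padding 1 — maps a 512 input through sides
    512 -> 256 -> 128 -> 64 -> 32 -> 31 -> 30 and has a 142-pixel receptive
    field.  Batch norm is omitted from the first and last blocks.
    """

    input_size: int = 512
    in_channels: int = 2  # image and attention map, channel-concatenated
    blocks: Tuple[BlockSpec, ...] = field(default_factory=lambda: (
        BlockSpec(4, 2, 1, 64, "relu", batchnorm=False),
        BlockSpec(4, 2, 1, 128, "relu"),
        BlockSpec(4, 2, 1, 256, "relu"),
        BlockSpec(4, 2, 1, 512, "relu"),
        BlockSpec(4, 1, 1, 512, "relu"),
        BlockSpec(4, 1, 1, 1, "sigmoid", batchnorm=False),
    ))

    def __post_init__(self):
        if len(self.blocks) != 6:
            raise InvalidConfig(f"need exactly six blocks, got {len(self.blocks)}")
        if self.blocks[-1].activation != "sigmoid":
            raise InvalidConfig("final block must end in a sigmoid")
        if self.input_size < 1 or self.in_channels < 1:
            raise InvalidConfig("input_size and in_channels must be positive")
        self.output_sides()  # raises if any block collapses the map

    def output_sides(self) -> List[int]:
        """Spatial side after each block, by the convolution arithmetic
        floor((side + 2p - k) / s) + 1."""
        side = self.input_size
        sides = []
        for b in self.blocks:
            side = (side + 2 * b.padding - b.kernel) // b.stride + 1
            if side < 1:
                raise InvalidConfig(
                    f"block {b} collapses the map (side {side})")
            sides.append(side)
        return sides

    @property
    def output_side(self) -> int:
        return self.output_sides()[-1]

    @property
    def patch_count(self) -> int:
        """Number of judged patches = squared output side."""
        return self.output_side ** 2

    @classmethod
    def toy(cls, input_size: int = 64, base_channels: int = 32) -> "DiscriminatorConfig":
        """The same 6-block pattern at desk scale."""
        c = base_channels
        return cls(input_size=input_size, blocks=(
            BlockSpec(4, 2, 1, c, "relu", batchnorm=False),
            BlockSpec(4, 2, 1, 2 * c, "relu"),
            BlockSpec(4, 2, 1, 4 * c, "relu"),
            BlockSpec(4, 2, 1, 8 * c, "relu"),
            BlockSpec(4, 1, 1, 8 * c, "relu"),
            BlockSpec(4, 1, 1, 1, "sigmoid", batchnorm=False),
        ))


def receptive_field(config: DiscriminatorConfig) -> int:
    """Side of the input region influencing one output unit.

    Standard recursion over blocks in input order:
    rf <- rf + (kernel - 1) * jump, jump <- jump * stride.
    """
    rf, jump = 1, 1
    for b in config.blocks:
        rf += (b.kernel - 1) * jump
        jump *= b.stride
    return rf


@dataclass(frozen=True)
class ProbabilityMap:
    """Grid of per-patch real/fake probabilities, entries in (0, 1)."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ShapeMismatch(f"probability map must be 2D, got {arr.shape}")
        if not (np.all(arr > 0.0) and np.all(arr < 1.0)):
            raise ValueError("probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "values", arr)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


class Discriminator(nn.Module):
    """Patch discriminator over channel-concatenated pairings."""

    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        in_ch = config.in_channels
        for i, b in enumerate(config.blocks, start=1):
            self.register_module(f"conv{i}", nn.Conv2d(
                in_ch, b.channels, kernel=b.kernel, stride=b.stride,
                padding=b.padding, rng=rng))
            if b.batchnorm:
                self.register_module(f"bn{i}", nn.BatchNorm2d(b.channels, rng=rng))
            in_ch = b.channels

    def __call__(self, pairing: Tensor) -> Tensor:
        cfg = self.config
        n, c, h, w = pairing.shape
        if c != cfg.in_channels or h != cfg.input_size or w != cfg.input_size:
            raise ShapeMismatch(
                f"expected (N, {cfg.in_channels}, {cfg.input_size}, "
                f"{cfg.input_size}), got {pairing.shape}")
        x = pairing
        for i, b in enumerate(cfg.blocks, start=1):
            x = self._modules[f"conv{i}"](x)
            if b.batchnorm:
                x = self._modules[f"bn{i}"](x)
            x = nn.sigmoid(x) if b.activation == "sigmoid" else nn.relu(x)
        return x


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    """Construct a discriminator with deterministic initialization."""
    return Discriminator(config, seed=seed)


def discriminator_score(disc: Discriminator, image: np.ndarray,
                        attention: np.ndarray) -> Tuple[ProbabilityMap, float]:
    """Score one pairing in evaluation mode.

    Returns the per-patch probability map and its arithmetic mean, which is
    the discriminator's verdict for the pairing.  Inputs are 2D arrays in
    normalized units.
    """
    image = np.asarray(image, dtype=np.float64)
    attention = np.asarray(attention, dtype=np.float64)
    if image.shape != attention.shape:
        raise ShapeMismatch(f"{image.shape} vs {attention.shape}")
    stacked = np.stack([image, attention])[None]  # (1, 2, H, W)
    was_training = disc.training
    disc.eval()
    try:
        out = disc(Tensor(stacked))
    finally:
        disc.train(was_training)
    pmap = ProbabilityMap(np.asarray(out.data[0, 0], dtype=np.float64))
    return pmap, pmap.mean


#: probabilities are clipped into [EPS, 1 - EPS] before taking logs
EPS = 1e-7


def discriminator_loss(real_map: np.ndarray, fake_map: np.ndarray) -> float:
    """Patch-averaged adversarial log-likelihood of the discriminator.

    mean(log D_real) + mean(log(1 - D_fake)); the discriminator maximizes
    this (a trainer minimizes its negation).  Entries are clipped to
    [EPS, 1 - EPS] so a saturated sigmoid cannot produce log(0).
    """
    real_map = np.asarray(real_map, dtype=np.float64)
    fake_map = np.asarray(fake_map, dtype=np.float64)
    if real_map.shape != fake_map.shape:
        raise ShapeMismatch(f"{real_map.shape} vs {fake_map.shape}")
    real = np.clip(real_map, EPS, 1.0 - EPS)
    fake = np.clip(fake_map, EPS, 1.0 - EPS)
    return float(np.log(real).mean() + np.log1p(-fake).mean())
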