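"""The U-shaped inpainting generator.

Two weight-independent contracting paths encode the (whitened) image and
the attention map; each block halves the spatial side, with dilated
convolutions in the leading blocks so early layers see a larger context.
At the 1x1 bottleneck the two streams are merged, and an expansive path of
transposed convolutions doubles the side back up to the input resolution.
Encoder features re-enter the decoder through residual connections: at
coarse scales (at most ``attention_max_positions`` flattened positions)
via trainable mask-attention fusion, at finer scales as plain additive
skips.  The output is linear — raw synthetic intensities in normalized
units; clamping to the 12-bit range happens only at export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import nn
from .attention import MaskAttentionFusion
from .errors import InvalidConfig, ShapeMismatch
from .nn import Tensor


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of the generator.

    The canonical configuration (512 input, depth 9, 1024-channel cap,
    dilated convolutions in the first 4 blocks, dropout 0.5) reproduces the
    printed size chain 512 -> 256 -> ... -> 1 with 1024 feature maps at the
    bottleneck.  ``input_size`` must equal ``2 ** depth`` so the repeated
    halving terminates exactly at 1x1.
    """

    input_size: int = 512
    depth: int = 9
    base_channels: int = 64
    max_channels: int = 1024
    dilation_blocks: int = 4
    dropout_rate: float = 0.5
    #: residual connections switch from attention fusion to plain skips
    #: once a scale has more flattened positions than this (32*32 = 1024).
    attention_max_positions: int = 1024

    def __post_init__(self):
        if not _is_power_of_two(self.input_size):
            raise InvalidConfig(f"input_size {self.input_size} is not a power of two")
        if self.input_size != 2 ** self.depth:
            raise InvalidConfig(
                f"input_size {self.input_size} != 2**depth (depth={self.depth})"
            )
        if self.dilation_blocks < 0 or self.dilation_blocks > self.depth:
            raise InvalidConfig("dilation_blocks must lie in [0, depth]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidConfig("dropout_rate must lie in [0, 1)")
        if self.base_channels < 1 or self.max_channels < self.base_channels:
            raise InvalidConfig("need 1 <= base_channels <= max_channels")

    def encoder_channels(self) -> List[int]:
        """Output channels of encoder blocks 1..depth (doubling, capped)."""
        return [min(self.base_channels * 2 ** k, self.max_channels)
                for k in range(self.depth)]

    def encoder_sides(self) -> List[int]:
        """Spatial side after each encoder block: input_size/2, ..., 1."""
        return [self.input_size >> (k + 1) for k in range(self.depth)]

    @classmethod
    def toy(cls, input_size: int = 64, base_channels: int = 32,
            max_channels: int = 256, dilation_blocks: int = 2) -> "GeneratorConfig":
        """A desk-scale configuration for CPU training and tests."""
        depth = int(np.log2(input_size))
        return cls(input_size=input_size, depth=depth,
                   base_channels=base_channels, max_channels=max_channels,
                   dilation_blocks=dilation_blocks)


class _EncoderBlock(nn.Module):
    """(ReLU ->) conv(stride 2) -> BN.  Pre-activation; the first block
    consumes raw inputs and therefore omits its leading ReLU."""

    def __init__(self, in_ch: int, out_ch: int, dilated: bool, first: bool,
                 last: bool, rng: np.random.Generator):
        super().__init__()
        self.first = first
        self.last = last
        if dilated:
            # dilation 2, effective kernel 7, padding 3: still halves the side
            self.conv = nn.Conv2d(in_ch, out_ch, kernel=4, stride=2,
                                  padding=3, dilation=2, rng=rng)
        else:
            self.conv = nn.Conv2d(in_ch, out_ch, kernel=4, stride=2,
                                  padding=1, rng=rng)
        if not last:
            # BN over a 1x1 map with batch 1 collapses the bottleneck to a
            # constant (zero gradient, no information flow), so the final
            # encoder block is conv-only — the pix2pix innermost convention.
            self.bn = nn.BatchNorm2d(out_ch, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.first:
            x = nn.relu(x)
        x = self.conv(x)
        if not self.last:
            x = self.bn(x)
        return x


class _Encoder(nn.Module):
    """One contracting path; returns the per-scale feature pyramid."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        chans = config.encoder_channels()
        in_ch = 1
        for k in range(config.depth):
            block = _EncoderBlock(in_ch, chans[k],
                                  dilated=(k < config.dilation_blocks),
                                  first=(k == 0),
                                  last=(k == config.depth - 1), rng=rng)
            self.register_module(f"block{k + 1}", block)
            in_ch = chans[k]
        self.depth = config.depth

    def __call__(self, x: Tensor) -> List[Tensor]:
        feats = []
        for k in range(self.depth):
            x = self._modules[f"block{k + 1}"](x)
            feats.append(x)
        return feats


class _DecoderBlock(nn.Module):
    """Transposed conv(stride 2) -> BN -> ReLU (the final block is a bare
    transposed convolution with linear output)."""

    def __init__(self, in_ch: int, out_ch: int, last: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.last = last
        self.up = nn.ConvTranspose2d(in_ch, out_ch, kernel=4, stride=2,
                                     padding=1, rng=rng)
        if not last:
            self.bn = nn.BatchNorm2d(out_ch, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.up(x)
        if self.last:
            return x
        return nn.relu(self.bn(x))


class Generator(nn.Module):
    """Mask-attention inpainting generator (two encoders, one decoder)."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder_image = _Encoder(config, rng)
        self.encoder_mask = _Encoder(config, rng)
        chans = config.encoder_channels()
        bottleneck = chans[-1]
        # merge the two 1x1 bottlenecks: concat then 1x1 projection
        self.merge = nn.Conv2d(2 * bottleneck, bottleneck, kernel=1, rng=rng)
        self.dropout = nn.Dropout(config.dropout_rate)

        # decoder block j upsamples side 2**(j-1) -> 2**j
        in_ch = bottleneck
        self._fusion_scales: Dict[int, bool] = {}
        for j in range(1, config.depth + 1):
            last = j == config.depth
            out_ch = 1 if last else chans[config.depth - 1 - j]
            self.register_module(
                f"dec{j}", _DecoderBlock(in_ch, out_ch, last=last, rng=rng))
            if not last:
                side = 2 ** j
                use_attn = side * side <= config.attention_max_positions
                self._fusion_scales[j] = use_attn
                if use_attn:
                    self.register_module(f"fusion{j}",
                                         MaskAttentionFusion(out_ch, rng=rng))
            in_ch = out_ch
        #: decoder blocks (three coarsest) that apply dropout in training
        self._dropout_blocks = {1, 2, 3} & set(range(1, config.depth))

    # -- introspection -------------------------------------------------
    def uses_attention_at(self, decoder_block: int) -> bool:
        return self._fusion_scales.get(decoder_block, False)

    def __call__(self, image: Tensor, attention: Tensor,
                 rng: Optional[np.random.Generator] = None,
                 return_features: bool = False):
        size = self.config.input_size
        if image.shape != (1, 1, size, size) or attention.shape != image.shape:
            raise ShapeMismatch(
                f"expected inputs (1, 1, {size}, {size}); got "
                f"{image.shape} and {attention.shape}"
            )
        feats_img = self.encoder_image(image)
        feats_msk = self.encoder_mask(attention)
        x = self.merge(nn.concat([feats_img[-1], feats_msk[-1]], axis=1))
        depth = self.config.depth
        for j in range(1, depth + 1):
            x = self._modules[f"dec{j}"](x)
            if j == depth:
                break
            if j in self._dropout_blocks:
                x = self.dropout(x, rng=rng)
            # encoder features living at side 2**j come from block depth-j
            fi, fm = feats_img[depth - j - 1], feats_msk[depth - j - 1]
            if self._fusion_scales[j]:
                x = x + self._modules[f"fusion{j}"](fi, fm)
            else:
                x = x + fi + fm
        if return_features:
            return x, {"image": feats_img, "mask": feats_msk}
        return x


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Construct a generator with deterministic initialization."""
    return Generator(config, seed=seed)


def generator_forward(gen: Generator, image: np.ndarray,
                      attention: np.ndarray) -> np.ndarray:
    """Run one deterministic (evaluation-mode) forward pass.

    Inputs are 2D arrays in normalized units; returns the synthesized 2D
    array in the same units.
    """
    image = np.asarray(image, dtype=np.float64)
    attention = np.asarray(attention, dtype=np.float64)
    if image.shape != attention.shape:
        raise ShapeMismatch(f"{image.shape} vs {attention.shape}")
    was_training = gen.training
    gen.eval()
    try:
        out = gen(Tensor(image[None, None]), Tensor(attention[None, None]))
    finally:
        gen.train(was_training)
    return np.asarray(out.data[0, 0], dtype=np.float64)


def generator_l1_loss(real: np.ndarray, synthesized: np.ndarray) -> float:
    """Mean absolute difference between real and synthesized pixels."""
    real = np.asarray(real, dtype=np.float64)
    synthesized = np.asarray(synthesized, dtype=np.float64)
    if real.shape != synthesized.shape:
        raise ShapeMismatch(f"{real.shape} vs {synthesized.shape}")
    return float(np.abs(real - synthesized).mean())
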