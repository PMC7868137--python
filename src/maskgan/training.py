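"""Adversarial training of the inpainting GAN, plus checkpointing and
inference.

Each iteration (batch size 1) builds the attention map of a labeled slice,
standardizes both inputs with the slice's own statistics, and alternates
one discriminator step — maximizing the patch log-likelihood of calling
pairing A real and pairing B fake — with one generator step minimizing

    lambda1 * L1(real, synthesized) + lambda2 * (-mean log D(pairing B)),

the usual conditional-GAN combination the 100:1 weighting implies.  A
strict mode drops the generator's adversarial term and trains on the bare
L1 objective.  Adam (beta1 = 0.5), learning rate 2e-4 with a 0.99
per-epoch exponential decay, losses logged every 100 iterations and
checkpoints written every 500 — the stated hyperparameter set.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .core import (AttentionMapImage, CtSlice, TumorMask, make_attention_map,
                   normalize_slice)
from .discriminator import (EPS, BlockSpec, Discriminator,
                            DiscriminatorConfig, build_discriminator)
from .errors import DivergedTraining, EmptyDataset, InvalidConfig, ShapeMismatch
from .generator import Generator, GeneratorConfig, build_generator
from .nn import Tensor


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters; the defaults are the published set."""

    learning_rate: float = 0.0002
    adam_momentum: float = 0.5    # Adam beta1
    adam_beta2: float = 0.999
    lambda1: float = 100.0        # weight of the generator (L1) loss
    lambda2: float = 1.0          # weight of the discriminator loss
    exponential_decay: float = 0.99  # learning-rate factor per epoch
    batch_size: int = 1
    epochs: int = 10
    dropout: float = 0.5
    loss_log_every: int = 100
    checkpoint_every: int = 500
    seed: int = 0
    #: generator trains on L1 alone (no adversarial feedback term)
    strict_l1_generator: bool = False
    #: feed the intact original to the image encoder instead of the
    #: whitened image (the literal reading of the training pairing)
    strict_original_input: bool = False

    def __post_init__(self):
        positives = {
            "learning_rate": self.learning_rate,
            "adam_momentum": self.adam_momentum,
            "adam_beta2": self.adam_beta2,
            "exponential_decay": self.exponential_decay,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "loss_log_every": self.loss_log_every,
            "checkpoint_every": self.checkpoint_every,
        }
        for name, value in positives.items():
            if value <= 0:
                raise InvalidConfig(f"{name} must be positive, got {value}")
        if not (0.0 <= self.dropout < 1.0):
            raise InvalidConfig(f"dropout must lie in [0, 1), got {self.dropout}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidConfig("lambda weights must be non-negative")
        if self.batch_size != 1:
            raise InvalidConfig("only batch size 1 is supported")


@dataclass(frozen=True)
class LossRecord:
    """One logged training point (losses are finite by construction)."""

    iteration: int
    generator_loss: float      # L1 reconstruction term
    discriminator_loss: float  # minimized negation of the patch log-likelihood
    total_loss: float          # lambda1 * G + lambda2 * D


def total_loss(gen_loss: float, disc_loss: float, config: TrainingConfig) -> float:
    """Weighted combination lambda1 * gen_loss + lambda2 * disc_loss."""
    return config.lambda1 * gen_loss + config.lambda2 * disc_loss


def _prepare_inputs(slc: CtSlice, mask: TumorMask, strict_original: bool):
    """Normalized (image-path, mask-path, real) arrays for one sample.

    Both paths are standardized with the source slice's statistics so the
    whitening value stays maximal in normalized units.
    """
    norm = normalize_slice(slc)
    attn = make_attention_map(slc, mask)
    attn_n = (attn.pixels - norm.source_mean) / norm.source_std
    image_in = norm.pixels if strict_original else attn_n
    return image_in, attn_n, norm.pixels


def _clipped_log(t: Tensor) -> Tensor:
    return nn.log(nn.clip(t, EPS, 1.0 - EPS))


def train(
    dataset: Sequence[Tuple[CtSlice, TumorMask]],
    gen_config: GeneratorConfig,
    disc_config: DiscriminatorConfig,
    train_config: TrainingConfig,
    checkpoint_dir: Optional[str] = None,
) -> Tuple[Generator, Discriminator, List[LossRecord]]:
    """Run adversarial training over ``epochs`` passes of the dataset.

    Fully deterministic given ``train_config.seed``: initialization,
    per-epoch shuffling and dropout all derive from it.  Loss records are
    appended every ``loss_log_every`` iterations; checkpoints are written
    every ``checkpoint_every`` iterations when ``checkpoint_dir`` is given.
    Raises :class:`DivergedTraining` as soon as any loss goes non-finite.
    """
    if len(dataset) == 0:
        raise EmptyDataset("cannot train on an empty dataset")
    if gen_config.input_size != disc_config.input_size:
        raise InvalidConfig(
            f"generator input {gen_config.input_size} != discriminator "
            f"input {disc_config.input_size}")
    if gen_config.dropout_rate != train_config.dropout:
        gen_config = replace(gen_config, dropout_rate=train_config.dropout)

    root = np.random.SeedSequence(train_config.seed)
    seed_init_g, seed_init_d, seed_loop = (
        int(s.generate_state(1)[0]) for s in root.spawn(3))
    gen = build_generator(gen_config, seed=seed_init_g)
    disc = build_discriminator(disc_config, seed=seed_init_d)
    rng = np.random.default_rng(seed_loop)

    opt_g = nn.Adam(gen.parameters(), lr=train_config.learning_rate,
                    beta1=train_config.adam_momentum, beta2=train_config.adam_beta2)
    opt_d = nn.Adam(disc.parameters(), lr=train_config.learning_rate,
                    beta1=train_config.adam_momentum, beta2=train_config.adam_beta2)

    records: List[LossRecord] = []
    if checkpoint_dir is not None:
        os.makedirs(checkpoint_dir, exist_ok=True)
    iteration = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        for idx in order:
            iteration += 1
            slc, mask = dataset[idx]
            image_in, attn_n, real_n = _prepare_inputs(
                slc, mask, train_config.strict_original_input)
            image_t = Tensor(image_in[None, None])
            attn_t = Tensor(attn_n[None, None])
            real_t = Tensor(real_n[None, None])

            fake = gen(image_t, attn_t, rng=rng)

            # -- discriminator step: maximize the patch log-likelihood
            d_real = disc(nn.concat([real_t, attn_t], axis=1))
            d_fake = disc(nn.concat([Tensor(fake.data), attn_t], axis=1))
            loglik = (nn.tmean(_clipped_log(d_real))
                      + nn.tmean(nn.log(nn.clip(1.0 - d_fake, EPS, 1.0 - EPS))))
            d_loss = -loglik
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # -- generator step
            l1 = nn.tmean(nn.absolute(real_t - fake))
            if train_config.strict_l1_generator:
                g_obj = l1 * train_config.lambda1
            else:
                adv = -nn.tmean(_clipped_log(disc(nn.concat([fake, attn_t], axis=1))))
                g_obj = l1 * train_config.lambda1 + adv * train_config.lambda2
            opt_g.zero_grad()
            disc.zero_grad()  # discard spillover from the shared tape
            g_obj.backward()
            opt_g.step()
            disc.zero_grad()

            g_val, d_val = l1.item(), d_loss.item()
            t_val = total_loss(g_val, d_val, train_config)
            if not (np.isfinite(g_val) and np.isfinite(d_val)):
                raise DivergedTraining(
                    f"non-finite loss at iteration {iteration}: "
                    f"G={g_val}, D={d_val}")
            if iteration % train_config.loss_log_every == 0:
                records.append(LossRecord(iteration, g_val, d_val, t_val))
            if (checkpoint_dir is not None
                    and iteration % train_config.checkpoint_every == 0):
                save_checkpoint(
                    os.path.join(checkpoint_dir, f"checkpoint_{iteration:07d}.npz"),
                    gen, disc)
        opt_g.lr *= train_config.exponential_decay
        opt_d.lr *= train_config.exponential_decay
    return gen, disc, records


def synthesize(gen: Generator, whitened: AttentionMapImage) -> CtSlice:
    """Fill the whitened regions of a slice with synthesized texture.

    Standardizes the whitened slice, runs the generator in evaluation mode
    (deterministic), de-standardizes and clamps to the 12-bit range.
    """
    size = gen.config.input_size
    if whitened.shape != (size, size):
        raise ShapeMismatch(
            f"whitened input {whitened.shape} does not match generator "
            f"size {size}")
    norm = normalize_slice(CtSlice(whitened.pixels))
    x = Tensor(norm.pixels[None, None])
    was_training = gen.training
    gen.eval()
    try:
        out = gen(x, x)
    finally:
        gen.train(was_training)
    pixels = (np.asarray(out.data[0, 0], dtype=np.float64)
              * norm.source_std + norm.source_mean)
    return CtSlice(np.clip(pixels, 0.0, 4096.0))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def _encode_configs(gen: Generator, disc: Discriminator) -> str:
    return json.dumps({
        "generator": asdict(gen.config),
        "discriminator": asdict(disc.config),
    })


def save_checkpoint(path: str, gen: Generator, disc: Discriminator) -> None:
    """Serialize both networks (configs + parameters + norm statistics)."""
    arrays = {f"gen.{k}": v for k, v in gen.state_dict().items()}
    arrays.update({f"disc.{k}": v for k, v in disc.state_dict().items()})
    np.savez(path, __configs__=_encode_configs(gen, disc), **arrays)


def load_checkpoint(path: str) -> Tuple[Generator, Discriminator]:
    """Restore networks bitwise from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as data:
        configs = json.loads(str(data["__configs__"]))
        gcfg = GeneratorConfig(**configs["generator"])
        dcfg_raw = configs["discriminator"]
        dcfg_raw["blocks"] = tuple(BlockSpec(**b) for b in dcfg_raw["blocks"])
        dcfg = DiscriminatorConfig(**dcfg_raw)
        gen = build_generator(gcfg, seed=0)
        disc = build_discriminator(dcfg, seed=0)
        gen.load_state_dict({k[4:]: data[k] for k in data.files
                             if k.startswith("gen.")})
        disc.load_state_dict({k[5:]: data[k] for k in data.files
                              if k.startswith("disc.")})
    return gen, disc
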