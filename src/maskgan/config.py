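"""Run configuration: defaults, file loading, overrides and seeding.

A run configuration bundles the generator / discriminator architectures
and the training hyperparameters.  Defaults are the published values
(learning rate 2e-4, lambda1 100, lambda2 1, batch 1, 10 epochs, dropout
0.5, canonical 512 architectures); a YAML or JSON file overlays them and
programmatic overrides overlay the file.  Every run can serialize its
resolved configuration next to its outputs so results are reproducible
byte for byte given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Optional

import numpy as np

from .discriminator import DiscriminatorConfig
from .errors import ConfigError, InvalidConfig
from .generator import GeneratorConfig
from .training import TrainingConfig


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def snapshot(self, path: str) -> None:
        """Write the resolved configuration as JSON alongside run outputs."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


_SECTION_TYPES = {
    "generator": GeneratorConfig,
    "discriminator": DiscriminatorConfig,
    "training": TrainingConfig,
}


def _build_section(name: str, cls, values: Mapping[str, Any]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    if name == "discriminator" and "blocks" in values:
        raise ConfigError(
            "discriminator.blocks cannot be set from a config file; "
            "construct a DiscriminatorConfig programmatically instead")
    for key in values:
        if key not in allowed:
            raise ConfigError(f"unknown field {name}.{key}")
    try:
        return cls(**values)
    except InvalidConfig as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad section {name!r}: {exc}") from exc


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults <- file <- overrides.

    The file may be YAML or JSON with sections ``generator``,
    ``discriminator``, ``training`` plus top-level ``seed`` and
    ``log_level``.  ``overrides`` uses dotted keys, e.g.
    ``{"training.learning_rate": 1e-3}``.  Validation failures raise
    :class:`ConfigError` naming the offending field.
    """
    data: Dict[str, Any] = {}
    if path is not None:
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            text = fh.read()
        if path.endswith(".json"):
            loaded = json.loads(text) if text.strip() else {}
        else:
            import yaml

            loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded)}")
        data = dict(loaded)

    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        if len(parts) == 1:
            data[parts[0]] = value
        elif len(parts) == 2:
            data.setdefault(parts[0], {})
            if not isinstance(data[parts[0]], dict):
                raise ConfigError(f"cannot override non-section {parts[0]!r}")
            data[parts[0]][parts[1]] = value
        else:
            raise ConfigError(f"override key too deep: {dotted!r}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        raw = data.pop(name, {})
        if not isinstance(raw, Mapping):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, cls, raw)
    seed = data.pop("seed", 0)
    log_level = data.pop("log_level", "INFO")
    if data:
        raise ConfigError(f"unknown top-level field {sorted(data)[0]!r}")
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"log_level must be a standard level, got {log_level!r}")
    return RunConfig(seed=seed, log_level=log_level, **sections)


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based child seed: independent streams per subsystem index.

    Uses numpy's SeedSequence spawn keys, so child streams do not depend on
    the order in which they are drawn.  Results stay below 2**31.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


#: fixed fan-out indices for the package's subsystems
SEED_CHANNELS = {"phantom": 0, "augment": 1, "train": 2, "eval": 3}


def subsystem_seed(master_seed: int, channel: str) -> int:
    """Seed for a named subsystem under the documented counter scheme."""
    if channel not in SEED_CHANNELS:
        raise ConfigError(f"unknown seed channel {channel!r}")
    return derive_seed(master_seed, SEED_CHANNELS[channel])
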