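"""Model and training configuration.

A single flat :class:`ModelConfig` carries every tunable the pipeline
uses: hidden widths h1–h6 for the encoder/decoder stacks, the attention
blend λ, the RBF width σ (Å), the number of message-passing layers T,
the interface neighbor count k, attention heads, dropout, the focal-loss
parameters, and the optimizer settings. Configs load from flat YAML
key-value files; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Bad configuration file or override."""


@dataclass
class ModelConfig:
    # architecture widths
    h1: int = 128   # protein encoder hidden
    h2: int = 32    # surface projection
    h3: int = 128   # drug encoder hidden
    h4: int = 128   # occurrence decoder hidden
    h5: int = 128   # site decoder hidden
    h6: int = 128   # affinity decoder hidden
    # graph construction
    cutoff: float = 12.0       # Å, residue-graph Cα cutoff
    sigma: float = 1.0         # Å, RBF width
    k_neighbors: int = 6       # hetero-graph k-NN
    pocket_cutoff: float = 10.0  # Å, ligand-distance pocket rule
    surface_grid: float = 1.0  # Å, marching-cubes spacing
    pairwise: str = "edges"    # affinity pair attention: "edges" or "all"
    # attention
    lam: float = 0.5           # λ blend of node- vs edge-similarity attention
    layers: int = 3            # T
    heads: int = 4
    dropout: float = 0.1
    # losses — alpha weighs the positive (binding) class, which is the
    # rare one at residue level, hence > 0.5
    focal_alpha: float = 0.75
    focal_gamma: float = 2.0
    # optimisation
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 8
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError("lam must lie in [0, 1]")
        if self.layers < 1:
            raise ConfigError("layers must be >= 1")
        for name in ("h1", "h2", "h3", "h4", "h5", "h6"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.pairwise not in ("edges", "all"):
            raise ConfigError("pairwise must be 'edges' or 'all'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ModelConfig:
    """Load a flat YAML config; defaults fill gaps, overrides apply last."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path} is not a flat key-value file")
        values.update(loaded)
    if overrides:
        values.update(overrides)
    known = {f.name: f.type for f in dataclasses.fields(ModelConfig)}
    unknown = set(values) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, val in values.items():
        field = next(f for f in dataclasses.fields(ModelConfig) if f.name == key)
        try:
            coerced[key] = type(field.default)(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: {exc}") from exc
    return ModelConfig(**coerced)
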