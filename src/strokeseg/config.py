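"""Run configuration: YAML-backed, schema-validated, nested sections.

A :class:`RunConfig` bundles one setting object per pipeline stage.
Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults), and every resolved run writes its configuration next
to its outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .model import ModelConfig
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    n_subjects: int = 12
    split_sizes: tuple[int, int, int] = (8, 2, 2)
    seed: int = 0
    threshold: float = 0.5

    def reseed(self, seed: int) -> "RunConfig":
        """Propagate one run seed into every stochastic stage."""
        return dataclasses.replace(
            self,
            seed=seed,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
            model=dataclasses.replace(self.model, seed=seed),
            training=dataclasses.replace(self.training, seed=seed),
        )


_TUPLE_FIELDS = {"lesion_count_range", "lesion_radius_range", "brain_intensity",
                 "target", "split_sizes"}


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        if k == "crop" and v is not None:
            v = (tuple(v[0]), tuple(v[1]))
        if k == "loss_weights" and isinstance(v, dict):
            v = _build(LossWeights, v, f"{section}.loss_weights")
        kwargs[k] = v
    return cls(**kwargs)


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "preprocessing": PreprocessConfig,
    "model": ModelConfig,
    "training": TrainConfig,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``overrides`` maps dotted keys
    (e.g. ``training.n_epoch``) to values and wins over file values."""
    data = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data = dict(loaded)
    for dotted, value in (overrides or {}).items():
        node = data
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value

    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {}, name)
    for name in ("n_subjects", "seed", "threshold"):
        if name in data:
            kwargs[name] = data[name]
    if "split_sizes" in data:
        kwargs["split_sizes"] = tuple(data["split_sizes"])
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path):
    """Write the fully-resolved configuration as YAML."""
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [plain(o) for o in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(plain(cfg), sort_keys=True))
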