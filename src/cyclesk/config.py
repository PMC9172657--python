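"""Run configuration: profiles, YAML round-trip, config hashing.

Two built-in profiles:

* ``full`` — the full-scale training setup: 512x512 slices, 256x256 patches
  every 16 pixels, 64-channel branches, lambda = 10, Adam with lr 1e-5
  linearly decayed to 1e-7 between steps 100k and 700k, 1M steps total.
* ``tiny`` — a CPU-scale profile with the same structure throughout (96x96
  slices, 64x64 patches, 16-channel branches, shallower stacks, a constant-
  then-decayed lr of 2e-4, least-squares adversarial form) so the whole loop
  runs end to end on one core.

Any field of any section can be overridden from a YAML file or a flat
``section.field=value`` mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generator import GeneratorConfig
from .losses import LossConfig
from .metrics import WindowSpec
from .phantoms import DoseModel, PhantomSpec
from .trainer import TrainConfig

__all__ = ["DatasetConfig", "RunConfig", "load_profile", "from_yaml",
           "config_hash"]


@dataclass(frozen=True)
class DatasetConfig:
    n_subjects_x: int = 4
    n_subjects_y: int = 4
    slices_per_subject: int = 4
    image_size: int = 512
    patch_size: int = 256
    stride: int = 16
    n_eval_slices: int = 1
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    profile: str = "full"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    dose: DoseModel = field(default_factory=DoseModel)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    window_tissue: WindowSpec = field(
        default_factory=lambda: WindowSpec(0.20, 0.28))
    window_lung: WindowSpec = field(
        default_factory=lambda: WindowSpec(0.0, 0.33))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_PROFILES: dict[str, dict] = {
    "full": {},
    "tiny": {
        "phantom": {"image_size": 96, "n_ellipses": 6},
        "dose": {"photons_i0": 2000.0, "n_angles": 90},
        "dataset": {"n_subjects_x": 2, "n_subjects_y": 2,
                    "slices_per_subject": 2, "image_size": 96,
                    "patch_size": 64, "stride": 32, "n_eval_slices": 5},
        "generator": {"channels": 16, "redcnn_layers": 3, "unet_layers": 3,
                      "reduction_dim": 8},
        "loss": {"adversarial_form": "least_squares",
                 "vgg_width_factor": 0.125},
        "train": {"lr_init": 2e-4, "lr_final": 2e-5,
                  "decay_start_step": 600, "decay_end_step": 1000,
                  "total_steps": 1000, "checkpoint_every": 0,
                  "input_size": 64, "disc_base_channels": 32},
    },
}

_SECTIONS = {
    "phantom": PhantomSpec, "dose": DoseModel, "dataset": DatasetConfig,
    "generator": GeneratorConfig, "loss": LossConfig, "train": TrainConfig,
    "window_tissue": WindowSpec, "window_lung": WindowSpec,
}


def _build_section(cls, base, overrides: dict):
    values = dataclasses.asdict(base)
    for key, val in overrides.items():
        if key not in values:
            raise KeyError(f"unknown config field "
                           f"{cls.__name__}.{key}")
        if isinstance(values[key], tuple) and isinstance(val, list):
            val = tuple(val)
        values[key] = val
    for key in list(values):
        if isinstance(values[key], list):
            values[key] = tuple(values[key])
    return cls(**values)


def load_profile(name: str, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig for a profile, optionally overriding nested fields."""
    if name not in _PROFILES:
        raise KeyError(f"unknown profile {name!r}; one of "
                       f"{sorted(_PROFILES)}")
    merged: dict[str, dict] = {k: dict(v) for k, v in _PROFILES[name].items()}
    for section, vals in (overrides or {}).items():
        if section == "profile":
            continue
        if section not in _SECTIONS:
            raise KeyError(f"unknown config section {section!r}")
        merged.setdefault(section, {}).update(vals)
    base = RunConfig(profile=name)
    kwargs = {"profile": name}
    for section, cls in _SECTIONS.items():
        kwargs[section] = _build_section(cls, getattr(base, section),
                                         merged.get(section, {}))
    return RunConfig(**kwargs)


def from_yaml(path: str | Path) -> RunConfig:
    """Load a YAML run config; the optional ``profile`` key selects a base."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", "full")
    return load_profile(profile, raw)


def to_yaml(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a fully resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
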