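"""YAML pipeline configuration with schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class TemplateParams:
    width: int = 128
    height: int = 128
    n_trees: int = 2
    radius_min: float = 2.0
    radius_max: float = 6.0
    tortuosity: float = 0.15
    seed: int = 0


@dataclass
class SimParams:
    n_bubbles: int = 50
    dt: float = 1.0
    n_steps: int = 16
    jitter_sigma: float = 0.1
    profile_exponent: int = 1
    seed: int = 0


@dataclass
class RenderParams:
    sigma_ax: float = 4.0
    sigma_lat: float = 6.0
    psf_size: int = 25
    noise_sigma_rel: float = 0.1
    pixel_size: float = 4.9
    frame_interval: float = 1.0
    seed: int = 0


@dataclass
class NetParams:
    depth: int = 3
    base_width: int = 32
    skip_mode: str = "temporal_mean"


@dataclass
class TrainParams:
    lr: float = 0.001
    batch: int = 4
    epochs: int = 100
    validation_fraction: float = 0.1
    seed: int = 0


@dataclass
class DatasetParams:
    n_samples: int = 20
    clip_len: int = 16
    patch: int = 64
    seed: int = 0


@dataclass
class PipelineConfig:
    stages: list = field(default_factory=lambda: ["template", "simulate", "render"])
    out_dir: str = "smv_out"
    template: TemplateParams = field(default_factory=TemplateParams)
    sim: SimParams = field(default_factory=SimParams)
    render: RenderParams = field(default_factory=RenderParams)
    net: NetParams = field(default_factory=NetParams)
    train: TrainParams = field(default_factory=TrainParams)
    dataset: DatasetParams = field(default_factory=DatasetParams)


_SECTIONS = {
    "template": TemplateParams,
    "sim": SimParams,
    "render": RenderParams,
    "net": NetParams,
    "train": TrainParams,
    "dataset": DatasetParams,
}

_VALID_STAGES = ["template", "graph", "simulate", "render", "make-dataset", "train", "infer", "evaluate"]


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML config, listing every offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key == "stages":
            bad = [s for s in value if s not in _VALID_STAGES]
            errors.extend(f"stages: unknown stage {s!r}" for s in bad)
            cfg.stages = [s for s in value if s in _VALID_STAGES]
        elif key == "out_dir":
            cfg.out_dir = str(value)
        elif key in _SECTIONS:
            section_cls = _SECTIONS[key]
            valid = {f.name: f.type for f in fields(section_cls)}
            section = getattr(cfg, key)
            for k, v in (value or {}).items():
                if k not in valid:
                    errors.append(f"{key}.{k}: unknown key")
                else:
                    setattr(section, k, v)
        else:
            errors.append(f"{key}: unknown section")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg
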