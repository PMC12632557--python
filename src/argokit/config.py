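"""YAML round-tripping of the synthetic-cohort configuration."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .synthetic import (
    CohortDesign,
    KineticsModel,
    NeuronPreset,
    NoiseModel,
    OpticsModel,
    PiecewiseLinear,
    SyntheticConfig,
)

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]

_CURVES = {
    "optics": ["acidic_fraction"],
    "preset": ["growth", "count_growth"],
}


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["design"]["chase_times"] = list(config.design.chase_times)
    for section, names in _CURVES.items():
        for name in names:
            d[section][name] = getattr(getattr(config, section), name).to_dict()
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}
    for section, names in _CURVES.items():
        for name in names:
            if section in d and name in d[section]:
                d[section][name] = PiecewiseLinear(
                    {float(k): float(v) for k, v in d[section][name].items()}
                )
    parts = {
        "kinetics": KineticsModel,
        "optics": OpticsModel,
        "preset": NeuronPreset,
        "design": CohortDesign,
        "noise": NoiseModel,
    }
    kwargs = {}
    for key, cls in parts.items():
        if key in d:
            kwargs[key] = cls(**d[key])
    for key in ("pixel_size_um", "z_step_um", "seed"):
        if key in d:
            kwargs[key] = d[key]
    return SyntheticConfig(**kwargs)


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
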