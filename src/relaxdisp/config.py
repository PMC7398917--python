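"""YAML configuration: spectrometer context defaults, fit policy, seeds."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .dispersion_fit import DEFAULT_CONFIG, FitConfig
from .tables_io import SpectrometerContext

DEFAULTS = {
    "context": {
        "proton_frequency_MHz": 800.4,
        "temperature_K": 298.0,
        "t_relax_s": 0.030,
        "condition_label": "free",
    },
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Merge a YAML config over the built-in defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def context_from_config(cfg: dict, **overrides) -> SpectrometerContext:
    kwargs = dict(cfg.get("context", {}))
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return SpectrometerContext(**kwargs)


def fit_config_from_config(cfg: dict) -> FitConfig:
    user = cfg.get("fit", {})
    if not user:
        return DEFAULT_CONFIG
    fields = asdict(DEFAULT_CONFIG)
    unknown = set(user) - set(fields)
    if unknown:
        raise ValueError(f"unknown fit config keys: {sorted(unknown)}")
    fields.update({k: tuple(v) if isinstance(v, list) else v for k, v in user.items()})
    return FitConfig(**fields)
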