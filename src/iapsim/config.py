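"""Configuration parsing for experiment runs (YAML or JSON).

A minimal file like ``{n: 30}`` is expanded with the study defaults:
beta = 1.677, clustering target 0.25, 1000 iterations, learning thresholds
1 (Easy) / 2 (Hard), p in {1/500, 1/200}, both transmission modes.  Unknown
keys and invariant violations raise :class:`ConfigError` naming the field.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import LearningThresholds
from .experiment import ExperimentConfig

__all__ = ["ConfigError", "parse_config"]


class ConfigError(ValueError):
    """Invalid experiment configuration; message names the offending field."""


# aliases: config-file key -> ExperimentConfig field
_SCALAR_KEYS = {
    "beta": "beta",
    "target_C": "target_C",
    "clustering": "target_C",
    "networks_per_n": "networks_per_n",
    "runs_per_condition": "runs_per_condition",
    "iterations": "iterations",
    "class_prob": "class_prob",
    "base_seed": "base_seed",
    "seed": "base_seed",
    "crossed": "crossed",
    "tolerance": "tolerance",
    "sampler_max_steps": "sampler_max_steps",
}
_LIST_KEYS = {
    "n": "population_sizes",
    "population_sizes": "population_sizes",
    "p": "p_values",
    "p_values": "p_values",
    "mode": "modes",
    "modes": "modes",
}
_THRESHOLD_KEYS = {"easy_exposures", "hard_exposures"}


def _load(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def parse_config(source) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a file or dict."""
    data = _load(source)
    kwargs: dict = {}
    thresholds: dict = {}
    for key, value in data.items():
        if key in _THRESHOLD_KEYS:
            thresholds[key] = value
        elif key in _LIST_KEYS:
            if not isinstance(value, (list, tuple)):
                value = [value]
            kwargs[_LIST_KEYS[key]] = tuple(value)
        elif key in _SCALAR_KEYS:
            kwargs[_SCALAR_KEYS[key]] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    if thresholds:
        try:
            kwargs["thresholds"] = LearningThresholds(
                easy_exposures=int(thresholds.get("easy_exposures", 1)),
                hard_exposures=int(thresholds.get("hard_exposures", 2)),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    try:
        return ExperimentConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
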