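"""Pipeline configuration: a single YAML document with strict validation.

Defaults mirror the analysis this pipeline implements: 200 response
permutations per PLS model, VIP >= 1 and joint p < 0.05 for influential
metabolites, FDR < 0.05 for the running-speed screen, 2 PLS components with
stratified 7-fold cross-validation, and a Box-Cox lambda grid from -2 to 2 in
steps of 0.1.  Unknown keys are rejected so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """The configuration document is malformed."""


def _default_grid() -> dict:
    return {"min": -2.0, "max": 2.0, "step": 0.1}


@dataclass
class PipelineConfig:
    tissues: dict = field(default_factory=dict)   # tissue name -> abundance path
    design: str | None = None                     # metadata path
    gmt: str | None = None                        # optional pathway library
    outdir: str = "aerometab_out"
    seed: int = 0
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    components: int = 2
    folds: int = 7
    cv_scheme: str = "random"
    permutations: int = 200
    response: str = "four_class"
    lambda_grid: dict = field(default_factory=_default_grid)
    missing_policy: str = "impute"

    def grid(self) -> np.ndarray:
        g = self.lambda_grid
        return np.round(np.arange(g["min"], g["max"] + 1e-9, g["step"]), 10)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {
    "tissues": dict,
    "design": str,
    "gmt": str,
    "outdir": str,
    "seed": int,
    "vip_threshold": (int, float),
    "p_threshold": (int, float),
    "fdr_threshold": (int, float),
    "components": int,
    "folds": int,
    "cv_scheme": str,
    "permutations": int,
    "response": str,
    "lambda_grid": dict,
    "missing_policy": str,
}


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file path or a plain dict.

    Defaults fill anything unspecified; explicit values win; unknown keys or
    wrongly typed values raise ConfigError naming the key.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config document must be a YAML mapping")
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    for key, value in raw.items():
        expected = _FIELD_TYPES[key]
        if value is None:
            continue
        if expected is int and isinstance(value, bool):
            raise ConfigError(f"config key '{key}' must be an integer")
        if not isinstance(value, expected):
            raise ConfigError(
                f"config key '{key}' has wrong type {type(value).__name__}"
            )
    cfg = PipelineConfig(**raw)
    if cfg.permutations < 1:
        raise ConfigError("permutations must be >= 1")
    if cfg.components < 1:
        raise ConfigError("components must be >= 1")
    if cfg.folds < 2:
        raise ConfigError("folds must be >= 2")
    if not 0 < cfg.p_threshold <= 1 or not 0 < cfg.fdr_threshold <= 1:
        raise ConfigError("p_threshold and fdr_threshold must lie in (0, 1]")
    if cfg.vip_threshold <= 0:
        raise ConfigError("vip_threshold must be positive")
    if cfg.response not in ("four_class", "capacity", "age", "speed"):
        raise ConfigError(f"unknown response mode '{cfg.response}'")
    if cfg.cv_scheme not in ("random", "venetian_blinds", "loo"):
        raise ConfigError(f"unknown cv_scheme '{cfg.cv_scheme}'")
    if cfg.missing_policy not in ("impute", "error"):
        raise ConfigError(f"unknown missing_policy '{cfg.missing_policy}'")
    g = cfg.lambda_grid
    if set(g) != {"min", "max", "step"} or g["step"] <= 0 or g["max"] < g["min"]:
        raise ConfigError("lambda_grid needs min <= max and step > 0")
    for tissue, path in cfg.tissues.items():
        if not isinstance(path, str):
            raise ConfigError(f"tissues entry '{tissue}' must map to a file path")
    return cfg
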