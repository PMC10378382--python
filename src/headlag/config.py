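"""Run configuration: defaults, YAML file loading, override precedence.

Precedence is CLI override > config file > defaults. Unknown keys are
rejected by name so typos fail loudly rather than silently falling back
to a default.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

DEFAULTS: dict[str, Any] = {
    "preprocess": {
        "N": "auto-min",            # integer, or "auto-min" = dataset minimum
        "rotation_reference": "first_frame",   # or "per_frame"
        "keypoints": "thirteen",    # or "five"
    },
    "eval": {
        "folds": 5,
        "repeats": 30,
        "seed": 0,
        "ttest_unit": "repeat",     # or "fold"
    },
    "simulate": {
        "counts": {0: 84, 1: 106, 3: 80},
        "frame_count_range": [90, 180],
        "seed": 0,
        "presets": {},              # per-level PTSMotionParams overrides
    },
}

_CHOICES = {
    ("preprocess", "rotation_reference"): ("first_frame", "per_frame"),
    ("preprocess", "keypoints"): ("thirteen", "five"),
    ("eval", "ttest_unit"): ("repeat", "fold"),
}


def _merge(base: dict, overlay: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in overlay.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key {here!r}")
        if isinstance(base[key], dict) and key != "counts" and key != "presets":
            if not isinstance(value, Mapping):
                raise ConfigError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(
    path: str | Path | None = None, overrides: Mapping | None = None
) -> dict[str, Any]:
    """Resolve the run configuration (defaults <- file <- overrides)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(Path(path), "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, Mapping):
            raise ConfigError(f"{path}: config file must hold a mapping")
        cfg = _merge(cfg, doc)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict[str, Any]) -> None:
    for (section, key), choices in _CHOICES.items():
        value = cfg[section][key]
        if value not in choices:
            raise ConfigError(
                f"configuration key {section}.{key} must be one of {choices}, "
                f"got {value!r}"
            )
    n = cfg["preprocess"]["N"]
    if n != "auto-min" and (not isinstance(n, int) or n < 1):
        raise ConfigError("preprocess.N must be a positive integer or 'auto-min'")
    for key in ("folds", "repeats"):
        if not isinstance(cfg["eval"][key], int) or cfg["eval"][key] < 1:
            raise ConfigError(f"eval.{key} must be a positive integer")
    counts = cfg["simulate"]["counts"]
    if not isinstance(counts, Mapping) or any(
        int(lvl) not in (0, 1, 3) for lvl in counts
    ):
        raise ConfigError("simulate.counts must map levels {0, 1, 3} to integers")
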