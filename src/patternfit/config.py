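"""Run configuration: defaults, validation, and deterministic seed fan-out.

A single global seed reproduces a whole experiment: every stochastic
stage derives its own substream seed from ``(global_seed, stage_name)``,
so re-running one stage in isolation gives the same draws as running the
full pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "validate_config", "stage_seed",
           "config_hash"]

# Protocol defaults, greppable in one place: estimation-dataset constants
# and ranges, reducer architecture/training settings, boosting settings.
DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "patternfit_out",
    "log_level": "INFO",
    "generate": {
        "image_size": 128,
        "selection_composition": {
            "turing": 228, "kt": 288, "gray_scott": 486,
            "edwards_wilkinson": 99, "eden": 182, "dla": 300,
            "l_system": 133, "phase_field": 83,
        },
        "estimation": {
            "n_train": 9700, "n_val": 600,
            "f_v_range": [0.6, 1.0], "g_v_range": [0.6, 1.0],
            "f_u": 0.51, "g_u": 0.81, "q": 0.0, "D_u": 0.1, "D_v": 1.0,
        },
    },
    "preprocess": {"blur_sigma": 1.5, "crop_ratios": "0.50:1.00:0.05"},
    "encode": {"encoder": "spectral_fallback"},
    "select": {"top_n": 5, "map_k": 50, "crop_scan": True},
    "dimred": {
        "layer_widths": [512, 256, 128, 128, 64, 64, 32, 32, 16, 2],
        "batch_size": 32, "learning_rate": 0.001, "weight_decay": 0.001,
        "margin": 0.1, "miner_epsilon": 0.2, "grid": [10, 10],
        "max_epochs": 100, "patience": 20,
    },
    "sdnpe": {
        "criterion": "friedman_mse", "max_depth": 3, "n_estimators": 150,
        "learning_rate": 0.087, "lattice_cell": 0.005, "lattice_n": [100, 100],
        "images_per_group": 20,
    },
    "stability": {},
}


# mappings replaced wholesale rather than key-merged (their keys are data,
# not schema: e.g. omitting a model from the composition means zero images)
_REPLACE_KEYS = {"selection_composition"}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if key in _REPLACE_KEYS:
                out[key] = uval
            elif isinstance(dval, dict):
                if not isinstance(uval, dict):
                    raise ValueError(f"config key {path + key!r} must be a mapping")
                out[key] = _merge(dval, uval, path + key + ".")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         f"{sorted(path + k for k in unknown)}")
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults and reject unknown keys; returns the echoed config."""
    return _merge(DEFAULTS, config or {})


def load_config(path=None) -> dict:
    """Load YAML (or JSON) config; an empty/missing file yields all defaults."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return validate_config(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic substream seed for a named stage (below 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
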