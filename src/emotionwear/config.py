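"""Pipeline configuration: nested defaults, YAML overrides, strict keys."""

from __future__ import annotations

import copy

import yaml

CONFIG_VERSION = "1"

DEFAULT_CONFIG: dict = {
    "version": CONFIG_VERSION,
    "seed": 0,
    "sample_rate_hz": 100.0,
    "hrv": {
        "window_s": 10.0,
        "freq_window_s": 60.0,
        "lf_band": [0.04, 0.15],
        "hf_band": [0.15, 0.40],
        "refractory_s": 0.33,
        "hop_s": 1.0,
        "or_hr_window_s": 2.0,   # short smoothing for the OR slope test
    },
    "tonic": {
        "filter": {"order": 2, "normalized_cutoff": 0.005},
        "window_s": 10.0,
    },
    "or": {
        "pre_s": 1.0,
        "span_s": 2.0,
        "min_decel": 0.5,
        "deriv_k": 4.0,
        "min_run_s": 0.5,
        "refractory_s": 5.0,
        "baseline_interval_s": [0.0, 180.0],
    },
    "specificity": {
        "deadband_k": 0.5,
        "interval_s": 60.0,
        "min_score": 0.5,
        "patterns": {
            "joy": {"hr": 1, "eda": 1, "skt": 1},
            "disgust": {"hr": 1, "eda": 1, "skt": -1},
            "fear": {"hr": 1, "eda": 1, "skt": -1},
        },
    },
    "rss": {"max_latency_s": 10.0, "pre_window_s": 0.0},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base and path != "specificity.patterns":
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base.get(key), dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and/or a dict.
    Unknown keys are rejected (except user-defined emotion patterns)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, file_cfg)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def echo_config(cfg: dict, path) -> None:
    """Write the effective configuration next to the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
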