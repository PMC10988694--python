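"""Structured configuration: every tunable of the pipeline in one nested
mapping, YAML round-trippable.

``default_config()`` is the calibrated base model: the transduction weights
and fibre gains were fitted once to the prototypical Ia response (initial
burst > 100 pps, peak dynamic > static average > 0; see
``experiments.fit_base_model``) and are held fixed for all simulations.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["default_config", "load_config", "save_config", "merge_config", "config_hash"]


def default_config() -> dict:
    return {
        "stimulus": {
            "baseline_s": 0.5,
            "amplitude_mm": 3.0,
            "velocity_mm_per_s": 20.0,
            "hold_s": 1.0,
            "post_s": 0.3,
            "dt_s": 1e-4,
        },
        "bag": {
            "rate_scale": 1.0,
            "activation": 0.3,
            "length_gain": 20.0,
        },
        "chain": {
            "rate_scale": 6.0,
            "activation": 0.3,
            "length_gain": 20.0,
        },
        "transduction": {
            "kfb": 8.83e-8,
            "kyb": 2.52e-9,
            "kfc": 4.56e-8,
            "scale": 2e5,
            "e_rev_mV": 0.0,
        },
        "morphology": {
            "terminal_length_multiplier": 1.0,
            "preterminal_length_multiplier": 1.0,
            "n_nodes": 5,
        },
        "densities": {
            "terminal": {
                "nav11": 250.0, "nav16": 25.0, "nav17": 250.0,
                "kv33": 0.012, "sk2": 0.0025, "kcnq": 0.0005,
            },
            "preterminal": {"nav16": 250.0, "nav17": 500.0, "sk2": 0.0025},
            "heminode": {"nav16": 2500.0, "kv33": 0.012, "kcnq": 0.0005},
            "node": {"nav16": 1200.0, "kv33": 0.012, "kcnq": 0.05},
            "paranode": {"kv1": 0.01},
        },
        "sim": {
            "dt_ms": 0.0125,
            "settle_ms": 500.0,
            "v_init": -65.0,
        },
        "features": {
            "threshold_mv": -20.0,
            "min_isi_ms": 1.0,
            "site": "node5",
            "onset_window_s": 0.1,
            "static_fraction": 0.8,
            "dynamic_skip_fraction": 0.3,
        },
    }


def merge_config(base: dict, override: dict | None) -> dict:
    """Deep merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    if not override:
        return out

    def rec(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                rec(dst[k], v)
            else:
                dst[k] = copy.deepcopy(v)

    rec(out, override)
    return out


def load_config(path) -> dict:
    """Load a YAML config, merged over the calibrated defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(default_config(), user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Deterministic short hash of a config (provenance tag in sweeps)."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
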