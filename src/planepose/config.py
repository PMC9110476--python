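"""Run configuration: defaults, YAML loading, strict key checking.

A run configuration is a nested mapping with four sections — ``phantom``,
``sampler``, ``slice`` and ``train`` — every field defaulted.  Values from
a YAML/JSON file override defaults; command-line flags override both
(precedence: flags > file > defaults).  Unknown keys are rejected rather
than silently ignored.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "merge_config"]


def default_config() -> dict:
    from .dataset import PoseSamplerConfig
    from .phantom import PhantomParams
    from .regressor import PlanePoseRegressor

    phantom = PhantomParams()
    sampler = PoseSamplerConfig()
    train = PlanePoseRegressor().get_params()
    train.pop("verbose")
    return {
        "phantom": {
            "shape": list(phantom.shape),
            "spacing": phantom.spacing,
            "skull_radii": list(phantom.skull_radii),
            "structure_count": phantom.structure_count,
            "speckle_strength": phantom.speckle_strength,
            "seed": phantom.seed,
        },
        "sampler": {k: getattr(sampler, k) for k in (
            "n_random", "n_near_sp", "trans_range", "rot_range",
            "sp_trans_interval_max", "sp_trans_interval_min",
            "sp_rot_interval_max", "sp_rot_interval_min",
            "min_overlap", "seed")},
        "slice": {"field_of_view": None, "resolution": 128},
        "train": train,
    }


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``; unknown keys raise."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration section {where} must be a mapping")
            out[key] = merge_config(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults, optionally overridden by a YAML/JSON file."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return merge_config(cfg, data)
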