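"""Declarative YAML experiment configs and result serialization.

Schema (version 1)::

    schema: 1
    model: 5d                # 3d | 5d | 9d | no_parole
    params: {beta: 1.0, ...} # semantic names, see params module
    init: {X: 118.8, C1: 1.2, ...}   # optional; default 1% perturbation
    criminal_fraction: 0.01  # used when init is absent
    horizon: 10000.0
    seed: 0
    sweep:                   # only for the sweep commands
      parameter: rho
      grid: [10.0, ...]

Serialization is deterministic: JSON with sorted keys, CSV with fixed
%.12g formatting — identical config + seed reproduce bit-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .params import Params3D, Params5D, Params9D, COMPARTMENTS, Trajectory, state_array

__all__ = [
    "load_config",
    "params_from_config",
    "init_from_config",
    "write_trajectory_csv",
    "write_json",
]

SCHEMA_VERSION = 1

_PARAM_TYPES = {"3d": Params3D, "no_parole": Params3D, "5d": Params5D, "9d": Params9D}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    if cfg.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {cfg.get('schema')!r}")
    if cfg.get("model") not in _PARAM_TYPES:
        raise ValueError(
            f"config must set model to one of {sorted(_PARAM_TYPES)}, "
            f"got {cfg.get('model')!r}"
        )
    if "params" not in cfg:
        raise ValueError("config must provide a params mapping")
    return cfg


def params_from_config(cfg: dict):
    model = cfg["model"]
    p = _PARAM_TYPES[model](**{k: float(v) for k, v in cfg["params"].items()})
    if model == "no_parole" and not p.is_no_parole:
        raise ValueError("no_parole model requires rho_x = rho_c = 0")
    return p


def init_from_config(cfg: dict, params) -> np.ndarray:
    from .simulate import default_init
    model = cfg["model"]
    if "init" in cfg and cfg["init"] is not None:
        return state_array(model, cfg["init"])
    return default_init(model, params, float(cfg.get("criminal_fraction", 0.01)))


def write_trajectory_csv(traj: Trajectory, path) -> None:
    names = COMPARTMENTS[traj.model]
    with open(path, "w", newline="") as fh:
        fh.write(",".join(("time",) + names) + "\r\n")
        for t, row in zip(traj.t, traj.y):
            fh.write(",".join("%.12g" % v for v in (t, *row)) + "\r\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return str(obj)
    return obj


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n")
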