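"""Run configuration: defaults, YAML loading, strict validation.

The resolved configuration is a nested structure whose defaults are the
simulation values used throughout the package (5 ms clock, 221-step horizon
with a 21-step dwell, 50-step prediction horizon, 50 N/m / 10 N s/m
impedance).  Precedence: built-in defaults < config file < explicit
overrides.  Unknown keys are rejected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .control import ImpedanceParams, NMPCConfig
from .ofc import InternalModelParams

__all__ = ["RunConfig", "load_config", "save_config", "DEFAULTS"]

DEFAULTS: dict = {
    "internal_model": {
        "mass": 3.0, "tau": 0.030, "fmax": 1000.0, "dt": 0.005,
        "n_steps": 221, "dwell": 21, "delay": 0.050,
        "process_noise": 2e-7, "sensory_noise": 1e-6,
        "estimation_noise": 1e-9, "mult_noise_scale": 0.2,
    },
    "synergies": {"n_synergies": 4, "n_directions": 16, "seed": 0,
                  "force_fraction": 0.25},
    "arm_fixture": None,        # path to a YAML arm fixture; None = bundled
    "robot": {"l1": 0.3, "l2": 0.3, "m1": 0.5, "m2": 0.5,
              "d1": 0.15, "d2": 0.15, "I1": 5e-3, "I2": 5e-3,
              "base": [0.0, 0.75]},
    "nmpc": {"horizon": 50, "beta0_bound": 20.0, "higher_order_bound": 10.0,
             "tol": 1e-6, "max_evals": 40, "warm_start": True},
    "impedance": {"kp": 50.0, "kd": 10.0, "time_shift": 0.050},
    "scenario": {"name": "A", "start": [0.0, 0.40], "target": None,
                 "field_b": 0.0, "noise": False},
    "seed": None,
    "out_dir": "results",
    "verbosity": 1,
}

_RANGES = {
    ("internal_model", "dt"): (0.0, None),
    ("internal_model", "tau"): (0.0, None),
    ("internal_model", "mass"): (0.0, None),
    ("internal_model", "fmax"): (0.0, None),
    ("impedance", "kp"): (0.0, None, True),
    ("impedance", "kd"): (0.0, None, True),
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.raw[key]

    def internal_model_params(self) -> InternalModelParams:
        im = self.raw["internal_model"]
        return InternalModelParams(
            mass=im["mass"], tau=im["tau"], fmax=im["fmax"], dt=im["dt"],
            n_steps=im["n_steps"], dwell=im["dwell"], delay=im["delay"],
            process_noise=np.eye(6) * im["process_noise"],
            sensory_noise=np.eye(6) * im["sensory_noise"],
            estimation_noise=np.eye(2) * im["estimation_noise"],
            mult_noise_scale=np.eye(2) * im["mult_noise_scale"],
        )

    def nmpc_config(self) -> NMPCConfig:
        n = self.raw["nmpc"]
        return NMPCConfig(horizon=n["horizon"], dt=self.raw["internal_model"]["dt"],
                          beta0_bound=n["beta0_bound"],
                          higher_order_bound=n["higher_order_bound"],
                          tol=n["tol"], max_evals=n["max_evals"],
                          warm_start=n["warm_start"])

    def impedance_params(self) -> ImpedanceParams:
        i = self.raw["impedance"]
        return ImpedanceParams(kp=i["kp"], kd=i["kd"], time_shift=i["time_shift"])

    def robot_params(self):
        from .robot import RobotParams
        r = self.raw["robot"]
        return RobotParams(l1=r["l1"], l2=r["l2"], m1=r["m1"], m2=r["m2"],
                           d1=r["d1"], d2=r["d2"], I1=r["I1"], I2=r["I2"],
                           base=np.asarray(r["base"], dtype=float))


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"configuration key {here!r} expects a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict) -> None:
    for (section, key), spec in _RANGES.items():
        lo, hi = spec[0], spec[1]
        inclusive = len(spec) > 2 and spec[2]
        val = cfg[section][key]
        if not isinstance(val, (int, float)):
            raise TypeError(f"{section}.{key} must be a number")
        if inclusive:
            ok = val >= lo and (hi is None or val <= hi)
        else:
            ok = val > lo and (hi is None or val < hi)
        if not ok:
            bound = f">= {lo}" if inclusive else f"> {lo}"
            raise ValueError(f"{section}.{key} = {val} out of range (expected {bound})")
    im = cfg["internal_model"]
    if not (im["n_steps"] > im["dwell"] >= 1):
        raise ValueError("internal_model: need n_steps > dwell >= 1")
    name = cfg["scenario"]["name"]
    if name not in ("center_out", "curl", "A", "B", "C", "D"):
        raise ValueError(f"scenario.name {name!r} not one of "
                         "center_out/curl/A/B/C/D")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Resolve defaults <- file <- overrides, validating strictly."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise TypeError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return RunConfig(raw=cfg)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.raw, sort_keys=True))
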