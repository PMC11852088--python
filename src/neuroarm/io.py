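"""Result serialization: CSV time series with a JSON metadata sidecar.

Every run can be reconstructed from its saved config and seed; the CSV holds
the full per-step time series at float precision sufficient for lossless
round-tripping (17 significant digits).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import MovementMetrics, SimulationResult

__all__ = ["result_columns", "write_result", "read_result"]

_VECTOR_FIELDS = [
    ("hand_pos", 2, ("x", "y")),
    ("hand_vel", 2, ("x", "y")),
    ("q", 2, ("1", "2")),
    ("dq", 2, ("1", "2")),
    ("act", 6, tuple("123456")),
    ("exc", 6, tuple("123456")),
    ("u_abstract", 2, ("x", "y")),
    ("xhat", 6, tuple("123456")),
    ("theta", 2, ("1", "2")),
    ("dtheta", 2, ("1", "2")),
    ("torques", 2, ("1", "2")),
    ("f_interaction", 2, ("x", "y")),
]


def result_columns() -> list[str]:
    """Documented CSV column order."""
    cols = ["time"]
    for name, _, subs in _VECTOR_FIELDS:
        cols.extend(f"{name}_{s}" for s in subs)
    cols.append("effort_inst")
    return cols


def write_result(result: SimulationResult, path: str | Path,
                 metrics: MovementMetrics | None = None,
                 config_echo: dict | None = None,
                 mkdir: bool = True) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (time series) and ``<path>.json`` (metadata).

    Returns the two paths written.
    """
    path = Path(path)
    if path.suffix == ".csv":
        path = path.with_suffix("")
    if mkdir:
        path.parent.mkdir(parents=True, exist_ok=True)
    data = {"time": result.time}
    for name, width, subs in _VECTOR_FIELDS:
        arr = getattr(result, name)
        for i, s in enumerate(subs):
            data[f"{name}_{s}"] = arr[:, i]
    data["effort_inst"] = result.effort_inst
    frame = pd.DataFrame(data, columns=result_columns())
    csv_path = path.with_suffix(".csv")
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "scenario": result.scenario,
        "dt": result.dt,
        "seed": result.seed,
        "start": list(result.start),
        "target": list(result.target),
        "n_steps": result.n_steps,
        "effort": result.effort,
    }
    if metrics is not None:
        meta["metrics"] = asdict(metrics)
    if config_echo is not None:
        meta["config"] = config_echo
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return csv_path, json_path


def read_result(path: str | Path) -> SimulationResult:
    """Reload a result written by :func:`write_result`."""
    path = Path(path)
    if path.suffix in (".csv", ".json"):
        path = path.with_suffix("")
    frame = pd.read_csv(path.with_suffix(".csv"))
    meta = json.loads(path.with_suffix(".json").read_text())
    kwargs = {"time": frame["time"].to_numpy()}
    for name, width, subs in _VECTOR_FIELDS:
        kwargs[name] = np.column_stack(
            [frame[f"{name}_{s}"].to_numpy() for s in subs])
    return SimulationResult(
        effort_inst=frame["effort_inst"].to_numpy(),
        start=np.asarray(meta["start"]), target=np.asarray(meta["target"]),
        scenario=meta["scenario"], dt=meta["dt"], seed=meta["seed"],
        **kwargs)
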