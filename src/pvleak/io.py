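"""Reading and writing slice stacks (JSON and long-form CSV).

The JSON schema is ``{"z": [...], "theta": [...], "R_i": [[...]],
"R_o": [[...]], "units": "mm"}`` with slice-by-station (row-major)
radius matrices.  The CSV form is long: one row per (z, theta) station
with columns ``z, theta, R_i, R_o`` and a ``# units: mm`` header line.
Internally everything is metres; files default to millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SliceStack

__all__ = ["write_stack_json", "read_stack_json", "write_stack_csv", "read_stack_csv",
           "read_stack", "write_stack"]

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3}


def _unit_factor(units: str) -> float:
    try:
        return _LENGTH_UNITS[units]
    except KeyError:
        raise ValueError(f"unsupported length unit {units!r}; use 'mm' or 'm'") from None


def write_stack_json(stack: SliceStack, path: str | Path, units: str = "mm",
                     metadata: dict | None = None) -> Path:
    f = _unit_factor(units)
    payload = {
        "units": units,
        "z": (stack.z / f).tolist(),
        "theta": stack.theta.tolist(),
        "R_i": (stack.inner_radius / f).tolist(),
        "R_o": (stack.outer_radius / f).tolist(),
    }
    if metadata:
        payload["metadata"] = metadata
    path = Path(path)
    path.write_text(json.dumps(payload) + "\n")
    return path


def read_stack_json(path: str | Path) -> SliceStack:
    data = json.loads(Path(path).read_text())
    for key in ("z", "theta", "R_i", "R_o"):
        if key not in data:
            raise ValueError(f"slice-stack file is missing field {key!r}")
    f = _unit_factor(data.get("units", "mm"))
    return SliceStack(
        z=np.asarray(data["z"], dtype=float) * f,
        theta=np.asarray(data["theta"], dtype=float),
        inner_radius=np.asarray(data["R_i"], dtype=float) * f,
        outer_radius=np.asarray(data["R_o"], dtype=float) * f,
    )


def write_stack_csv(stack: SliceStack, path: str | Path, units: str = "mm") -> Path:
    f = _unit_factor(units)
    K, n = stack.n_slices, stack.n_theta
    df = pd.DataFrame(
        {
            "z": np.repeat(stack.z / f, n),
            "theta": np.tile(stack.theta, K),
            "R_i": (stack.inner_radius / f).ravel(),
            "R_o": (stack.outer_radius / f).ravel(),
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)
    return path


def read_stack_csv(path: str | Path) -> SliceStack:
    path = Path(path)
    units = "mm"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "units:" in first:
                units = first.split("units:")[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    for col in ("z", "theta", "R_i", "R_o"):
        if col not in df.columns:
            raise ValueError(f"slice-stack CSV is missing column {col!r}")
    f = _unit_factor(units)
    z = np.unique(df["z"].to_numpy())
    theta = np.unique(df["theta"].to_numpy())
    K, n = z.size, theta.size
    if len(df) != K * n:
        raise ValueError("CSV rows do not form a full (z, theta) grid")
    df = df.sort_values(["z", "theta"], kind="mergesort")
    return SliceStack(
        z=z * f,
        theta=theta,
        inner_radius=df["R_i"].to_numpy().reshape(K, n) * f,
        outer_radius=df["R_o"].to_numpy().reshape(K, n) * f,
    )


def read_stack(path: str | Path) -> SliceStack:
    """Dispatch on extension: .json or .csv."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_stack_json(path)
    if path.suffix.lower() == ".csv":
        return read_stack_csv(path)
    raise ValueError(f"unrecognised slice-stack format: {path.suffix!r}")


def write_stack(stack: SliceStack, path: str | Path, units: str = "mm") -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return write_stack_json(stack, path, units=units)
    if path.suffix.lower() == ".csv":
        return write_stack_csv(stack, path, units=units)
    raise ValueError(f"unrecognised slice-stack format: {path.suffix!r}")
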