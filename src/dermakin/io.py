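"""Tidy CSV input/output and run provenance.

The on-disk schema is one row per observation:

    scenario_id,replicate,time_h,value,unit

Units must be homogeneous within a file.  Numbers are written with 10
significant digits, rows ordered by (scenario, replicate, time), so a
write → read round trip is the identity on values and grouping.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ObservationSeries, RateParameters

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_provenance",
]

_COLUMNS = ["scenario_id", "replicate", "time_h", "value", "unit"]


def read_timeseries_csv(
    path: str | Path, expected_unit: str | None = None
) -> list[ObservationSeries]:
    """Load a tidy observation file into one series per (scenario, replicate).

    Validation problems (missing columns, non-numeric fields, duplicated
    sample times within a replicate, mixed units) are collected and
    reported together with 1-based data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    errors: list[str] = []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time_h", "value"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        errors.extend(f"row {i + 2}: non-numeric {col} {df[col][i]!r}" for i in bad)
        df[col] = converted
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError:
        bad = df.index[pd.to_numeric(df["replicate"], errors="coerce").isna()]
        errors.extend(f"row {i + 2}: non-integer replicate" for i in bad)
    units = df["unit"].unique()
    if len(units) > 1:
        errors.append(f"mixed units in one file: {sorted(units)}")
    elif expected_unit is not None and len(units) and units[0] != expected_unit:
        errors.append(f"unit {units[0]!r} does not match expected {expected_unit!r}")
    if not errors:
        dup = df.duplicated(subset=["scenario_id", "replicate", "time_h"])
        errors.extend(f"row {i + 2}: duplicated (replicate, time)" for i in df.index[dup])
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    out = []
    for (sid, rep), grp in df.groupby(["scenario_id", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ObservationSeries(
                times=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                unit=str(grp["unit"].iloc[0]),
                replicate=int(rep),
                scenario_id=str(sid) if sid != "" else None,
            )
        )
    return out


def write_timeseries_csv(
    series: Sequence[ObservationSeries], path: str | Path
) -> Path:
    """Write series in the tidy schema (deterministic order, 10 sig digits)."""
    path = Path(path)
    units = {s.unit for s in series}
    if len(units) > 1:
        raise ValueError(f"units must be homogeneous per file, got {sorted(units)}")
    rows = []
    for s in sorted(series, key=lambda s: (s.scenario_id or "", s.replicate)):
        for t, v in zip(s.times, s.values):
            rows.append(
                {
                    "scenario_id": s.scenario_id or "",
                    "replicate": s.replicate,
                    "time_h": f"{t:.10g}",
                    "value": f"{v:.10g}",
                    "unit": s.unit,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return path


def write_ground_truth(params: RateParameters, path: str | Path, **extra) -> Path:
    """Sidecar JSON with the generating rates (and any run metadata)."""
    path = Path(path)
    payload = {
        "k_in": params.k_in,
        "k_d": params.k_d,
        "k_c": params.k_c,
        "k_out": params.k_out,
        **extra,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> RateParameters:
    data = json.loads(Path(path).read_text())
    return RateParameters(
        k_in=data["k_in"], k_d=data["k_d"], k_c=data["k_c"], k_out=data["k_out"]
    )


def write_provenance(out_dir: str | Path, command: str, seed: int, config) -> Path:
    """Record how an output directory was produced (command, seed, config,
    library versions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
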