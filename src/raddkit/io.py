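"""Plate CSV formats and provenance files.

Data file: long-format CSV with columns ``time_s, well_id, rfu`` (one row
per scan per well).  A companion layout CSV with columns ``well_id, role,
reporter, reporter_uM, deaminase_uM, endoq_uM, inhibitor_nM, dilution``
assigns each well its role and concentrations.  A wide-format reader
(one time column plus one RFU column per well) is provided for convenience;
instrument-native exports are out of scope.

Scenario JSON records full generator provenance, including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimulationScenario
from .traces import KineticTrace

__all__ = [
    "LAYOUT_COLUMNS",
    "read_plate",
    "read_plate_wide",
    "write_plate",
    "write_scenario",
    "read_scenario",
]

LAYOUT_COLUMNS = (
    "well_id",
    "role",
    "reporter",
    "reporter_uM",
    "deaminase_uM",
    "endoq_uM",
    "inhibitor_nM",
    "dilution",
)

_META_KEYS = tuple(c for c in LAYOUT_COLUMNS if c not in ("well_id", "role"))


def default_layout_path(data_path: str | Path) -> Path:
    data_path = Path(data_path)
    return data_path.with_name(data_path.stem + "_layout.csv")


def write_plate(traces, data_path: str | Path, layout_path: str | Path | None = None) -> None:
    """Write traces to the long-format data CSV plus the layout CSV."""
    data_path = Path(data_path)
    layout_path = Path(layout_path) if layout_path else default_layout_path(data_path)
    frames = [
        pd.DataFrame({"time_s": tr.times, "well_id": tr.well_id, "rfu": tr.values})
        for tr in traces
    ]
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_s", "well_id", "rfu"]
    )
    # %.17g guarantees bit-exact float round trips through the CSV
    data.to_csv(data_path, index=False, float_format="%.17g")
    rows = []
    for tr in traces:
        row = {"well_id": tr.well_id, "role": tr.role}
        for key in _META_KEYS:
            row[key] = tr.meta.get(key, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS)).to_csv(
        layout_path, index=False, float_format="%.17g"
    )


def _parse_layout(layout_path: Path) -> dict:
    layout = pd.read_csv(layout_path)
    missing = {"well_id", "role"} - set(layout.columns)
    if missing:
        raise ValueError(f"{layout_path}: layout is missing columns {sorted(missing)}")
    entries = {}
    for i, row in layout.iterrows():
        wid = str(row["well_id"])
        if wid in entries:
            raise ValueError(f"{layout_path}: line {i + 2}: duplicate well {wid!r}")
        meta = {}
        for key in _META_KEYS:
            if key in layout.columns and pd.notna(row[key]) and row[key] != "":
                val = row[key]
                meta[key] = str(val) if key == "reporter" else float(val)
        entries[wid] = {"role": str(row["role"]), "meta": meta}
    return entries


def read_plate(data_path: str | Path, layout_path: str | Path | None = None) -> list:
    """Read the long-format data CSV + layout CSV back into traces.

    Validates that every data well appears in the layout and that all wells
    share one time grid; errors name the offending well.
    """
    data_path = Path(data_path)
    layout_path = Path(layout_path) if layout_path else default_layout_path(data_path)
    data = pd.read_csv(data_path, float_precision="round_trip")
    missing = {"time_s", "well_id", "rfu"} - set(data.columns)
    if missing:
        raise ValueError(f"{data_path}: data file is missing columns {sorted(missing)}")
    entries = _parse_layout(layout_path)
    traces = []
    ref_times = None
    for wid, grp in data.groupby("well_id", sort=False):
        wid = str(wid)
        if wid not in entries:
            raise ValueError(f"{data_path}: well {wid!r} has no layout entry in {layout_path}")
        times = grp["time_s"].to_numpy(dtype=float)
        order = np.argsort(times, kind="stable")
        times = times[order]
        values = grp["rfu"].to_numpy(dtype=float)[order]
        if ref_times is None:
            ref_times = times
        elif times.shape != ref_times.shape or not np.allclose(times, ref_times, atol=1e-3):
            raise ValueError(f"{data_path}: well {wid!r} is on a different time grid")
        traces.append(
            KineticTrace(
                well_id=wid,
                times=times,
                values=values,
                role=entries[wid]["role"],
                meta=dict(entries[wid]["meta"]),
            )
        )
    return traces


def read_plate_wide(data_path: str | Path, layout_path: str | Path | None = None) -> list:
    """Read a wide-format export: a ``time_s`` column plus one column per well."""
    data_path = Path(data_path)
    layout_path = Path(layout_path) if layout_path else default_layout_path(data_path)
    data = pd.read_csv(data_path, float_precision="round_trip")
    if "time_s" not in data.columns:
        raise ValueError(f"{data_path}: wide format needs a 'time_s' column")
    entries = _parse_layout(layout_path)
    times = data["time_s"].to_numpy(dtype=float)
    traces = []
    for col in data.columns:
        if col == "time_s":
            continue
        if col not in entries:
            raise ValueError(f"{data_path}: well {col!r} has no layout entry in {layout_path}")
        traces.append(
            KineticTrace(
                well_id=col,
                times=times.copy(),
                values=data[col].to_numpy(dtype=float),
                role=entries[col]["role"],
                meta=dict(entries[col]["meta"]),
            )
        )
    return traces


def write_scenario(scenario: SimulationScenario, path: str | Path, extra: dict | None = None) -> None:
    """Record generator provenance (all scenario fields incl. seed) as JSON."""
    payload = {"scenario": asdict(scenario)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_scenario(path: str | Path) -> SimulationScenario:
    payload = json.loads(Path(path).read_text())
    return SimulationScenario(**payload["scenario"])
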