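"""Plate CSV, well-map CSV and standard-curve JSON read/write.

The plate format is the generic plate-reader export the pipeline consumes:
a CSV whose first column is ``time_s`` and remaining columns are well IDs
(A1…H12); the companion well map lists one row per well with its role
(standard / control / sample), substrate, enzyme, concentrations, replicate
bookkeeping, and for standards the assigned ladder length.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .calibrate import StandardCurveSeries
from .simulate import PlateRun

__all__ = [
    "write_plate",
    "read_plate",
    "write_curve",
    "read_curve",
    "write_curves_long",
    "read_curves_long",
]

_MAP_COLUMNS = [
    "well",
    "role",
    "substrate",
    "enzyme",
    "enzyme_conc_nM",
    "substrate_conc_nM",
    "replicate_group",
    "replicate",
    "length_bp",
    "control_well",
]


def write_plate(plate: PlateRun, plate_path, map_path) -> None:
    df = plate.data.reset_index()
    df.to_csv(plate_path, index=False, float_format="%.6g")
    plate.wellmap[_MAP_COLUMNS].to_csv(map_path, index=False)


def read_plate(plate_path, map_path) -> PlateRun:
    df = pd.read_csv(plate_path)
    if df.columns[0] != "time_s":
        raise ValueError("plate CSV must have time_s as its first column")
    data = df.set_index("time_s")
    wellmap = pd.read_csv(
        map_path, dtype={"well": str, "control_well": str}, keep_default_na=False
    )
    wellmap["length_bp"] = pd.to_numeric(wellmap["length_bp"], errors="coerce")
    wellmap["replicate"] = pd.to_numeric(wellmap["replicate"], errors="coerce").fillna(0).astype(int)
    wellmap["enzyme_conc_nM"] = pd.to_numeric(wellmap["enzyme_conc_nM"], errors="coerce").fillna(0.0)
    return PlateRun(data=data, wellmap=wellmap)


def write_curve(curve: StandardCurveSeries, path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=1))


def read_curve(path) -> StandardCurveSeries:
    return StandardCurveSeries.from_dict(json.loads(Path(path).read_text()))


def write_curves_long(curves: dict, path) -> None:
    """Converted length curves as long-format CSV: well, time_s, length_bp."""
    rows = []
    for well, rc in curves.items():
        for t, L, raw in zip(rc.time_s, rc.length_bp, rc.raw_length_bp):
            rows.append({"well": well, "time_s": t, "length_bp": L, "raw_length_bp": raw})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_curves_long(path) -> pd.DataFrame:
    return pd.read_csv(path)
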