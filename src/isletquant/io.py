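"""File formats: islet/calibration/assay CSV, YAML models and schemes.

All CSV dialects are comma-separated UTF-8 with a mandatory header and
``.`` decimals. Diameters are um throughout; no unit autodetection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationPoint
from .geometry import BinningScheme, IsletRecord, ie_exact
from .model import CellCountModel, kansas_rat_2012, predict_cells
from .normalization import AssayGroup, AssayReplicate

__all__ = [
    "read_islet_csv",
    "write_islet_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_assay_csv",
    "write_assay_csv",
    "model_to_yaml",
    "model_from_yaml",
    "scheme_to_yaml",
    "scheme_from_yaml",
    "load_model",
    "conversion_table",
    "write_report",
]

logger = logging.getLogger("isletquant")

_ISLET_COLUMNS = ["islet_id", "d1_um", "d2_um", "d3_um", "d4_um"]


def read_islet_csv(path: str | Path) -> list[IsletRecord]:
    """Read an islet list CSV (``islet_id, d1_um, d2_um, d3_um, d4_um``).

    Repeated diameter measurements (d2–d4 optional/blank) are averaged
    into the working diameter. Malformed rows raise with their line
    number.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ISLET_COLUMNS[:2] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[IsletRecord] = []
    for row_idx, row in frame.iterrows():
        line = row_idx + 2  # header is line 1
        measures = []
        for col in _ISLET_COLUMNS[1:]:
            raw = str(row.get(col, "")).strip()
            if not raw:
                continue
            try:
                measures.append(float(raw))
            except ValueError:
                raise ValueError(
                    f"{path}:{line}: non-numeric diameter {raw!r} in {col}"
                ) from None
        if not measures:
            raise ValueError(f"{path}:{line}: no diameter measurements")
        try:
            records.append(
                IsletRecord(tuple(measures), islet_id=str(row["islet_id"]))
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from None
    if not records:
        logger.warning("%s: no islet rows found", path)
    return records


def write_islet_csv(islets: Sequence[IsletRecord], path: str | Path) -> None:
    rows = []
    for idx, islet in enumerate(islets):
        row = {"islet_id": islet.islet_id or f"islet_{idx}"}
        for k in range(4):
            mm = islet.diameter_measurements
            row[f"d{k + 1}_um"] = mm[k] if k < len(mm) else ""
        rows.append(row)
    pd.DataFrame(rows, columns=_ISLET_COLUMNS).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read calibration points (``diameter_um, cells[, group, weight]``)."""
    frame = pd.read_csv(path)
    for col in ("diameter_um", "cells"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    points = []
    for _, row in frame.iterrows():
        group = row.get("group")
        weight = row.get("weight")
        points.append(
            CalibrationPoint(
                diameter=float(row["diameter_um"]),
                cells=float(row["cells"]),
                group=None if pd.isna(group) else str(group),
                weight=None if weight is None or pd.isna(weight) else float(weight),
            )
        )
    return points


def write_calibration_csv(
    points: Sequence[CalibrationPoint], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "diameter_um": [p.diameter for p in points],
            "cells": [p.cells for p in points],
            "group": [p.group for p in points],
            "weight": [p.weight for p in points],
        }
    ).to_csv(path, index=False)


def read_assay_csv(path: str | Path, readout_units: str = "arbitrary") -> list[AssayGroup]:
    """Read assay experiments into one :class:`AssayGroup` per group label.

    Columns: ``experiment_id, group, readout_total, readout_units,
    n_islets, diameters_um`` where ``diameters_um`` is a
    semicolon-separated per-islet diameter list.
    """
    frame = pd.read_csv(path)
    required = ["experiment_id", "group", "readout_total", "diameters_um"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    groups: dict[str, list[AssayReplicate]] = {}
    units: dict[str, str] = {}
    for _, row in frame.iterrows():
        diam = [float(x) for x in str(row["diameters_um"]).split(";") if x.strip()]
        if "n_islets" in frame.columns and not pd.isna(row["n_islets"]):
            if int(row["n_islets"]) != len(diam):
                raise ValueError(
                    f"{path}: experiment {row['experiment_id']!r} declares "
                    f"{row['n_islets']} islets but lists {len(diam)} diameters"
                )
        rep = AssayReplicate(
            readout_total=float(row["readout_total"]),
            islets=tuple(
                IsletRecord.from_diameter(d, islet_id=f"{row['experiment_id']}_{i}")
                for i, d in enumerate(diam)
            ),
        )
        label = str(row["group"])
        groups.setdefault(label, []).append(rep)
        units[label] = str(row.get("readout_units", readout_units))
    return [
        AssayGroup(label=label, replicates=tuple(reps),
                   readout_units=units.get(label, readout_units))
        for label, reps in groups.items()
    ]


def write_assay_csv(groups: Sequence[AssayGroup], path: str | Path) -> None:
    rows = []
    counter = 0
    for group in groups:
        for rep in group.replicates:
            rows.append(
                {
                    "experiment_id": f"exp_{counter}",
                    "group": group.label,
                    "readout_total": rep.readout_total,
                    "readout_units": group.readout_units,
                    "n_islets": len(rep.islets),
                    "diameters_um": ";".join(
                        f"{islet.diameter:g}" for islet in rep.islets
                    ),
                }
            )
            counter += 1
    pd.DataFrame(rows).to_csv(path, index=False)


def model_to_yaml(model: CellCountModel, path: str | Path) -> None:
    payload = {
        "coefficients": [float(c) for c in model.coefficients],
        "valid_range_um": [float(v) for v in model.valid_range],
        "reference_cells_per_ie": float(model.reference_cells_per_ie),
        "provenance": model.provenance,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def model_from_yaml(path: str | Path) -> CellCountModel:
    payload = yaml.safe_load(Path(path).read_text())
    return CellCountModel(
        coefficients=tuple(float(c) for c in payload["coefficients"]),
        valid_range=tuple(payload["valid_range_um"]),
        reference_cells_per_ie=float(
            payload.get("reference_cells_per_ie", 943.0)
        ),
        provenance=str(payload.get("provenance", "yaml")),
    )


def load_model(spec: str | Path) -> CellCountModel:
    """Load a model by builtin name (``kansas-rat-2012``) or YAML path."""
    if str(spec) == "kansas-rat-2012":
        return kansas_rat_2012()
    return model_from_yaml(spec)


def scheme_to_yaml(scheme: BinningScheme, path: str | Path) -> None:
    payload = {
        "bin_edges_um": [float(e) for e in scheme.bin_edges],
        "rule": scheme.rule,
        "factors": [float(f) for f in scheme.factors],
        "minimum_countable_diameter_um": float(scheme.minimum_countable_diameter),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def scheme_from_yaml(path: str | Path) -> BinningScheme:
    payload = yaml.safe_load(Path(path).read_text())
    return BinningScheme(
        bin_edges=tuple(float(e) for e in payload["bin_edges_um"]),
        factors=tuple(float(f) for f in payload["factors"]),
        rule=str(payload.get("rule", "explicit_table")),
        minimum_countable_diameter=float(
            payload.get("minimum_countable_diameter_um", 50.0)
        ),
    )


def conversion_table(
    model: CellCountModel | None = None,
    d_min: float = 20.0,
    d_max: float = 350.0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Diameter-by-diameter conversion table (the spreadsheet equivalent).

    One row per diameter from ``d_min`` to ``d_max`` inclusive at
    ``step`` um: predicted cells, exact-sphere IE, and cells per IE.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if model is None:
        model = kansas_rat_2012()
    lo, hi = model.valid_range
    if d_min < lo or d_max > hi:
        raise ValueError(
            f"table range [{d_min}, {d_max}] outside model range [{lo}, {hi}]"
        )
    d = np.arange(d_min, d_max + step / 2, step)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # low-diameter dip warning, by design here
        cells = np.asarray(predict_cells(model, d))
    ie = (d / 150.0) ** 3
    return pd.DataFrame(
        {
            "diameter_um": d,
            "cells": cells,
            "ie_exact": ie,
            "cells_per_ie": cells / ie,
        }
    )


def write_report(payload: dict, out_dir: str | Path, stem: str) -> Path:
    """Write a machine-readable JSON run report; returns its path.

    The payload should carry every parameter, seed and model provenance
    needed to reproduce the run; rerunning with the same configuration
    reproduces the file byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s", path)
    return path
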