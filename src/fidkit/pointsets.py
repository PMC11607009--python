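"""Labelled point-set interchange: CSV and JSON, physical mm coordinates.

The CSV schema ``label,x_mm,y_mm,z_mm`` is the interchange format between
localization, configuration search and registration; candidate orbits use
``wheel,position_index,x_mm,y_mm,z_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .axis import CandidateSet

POINT_COLUMNS = ["label", "x_mm", "y_mm", "z_mm"]
CANDIDATE_COLUMNS = ["wheel", "position_index", "x_mm", "y_mm", "z_mm"]


def write_points_csv(path: str | Path, points: Mapping[str, np.ndarray]) -> None:
    rows = [
        {"label": lbl, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
        for lbl, p in points.items()
    ]
    pd.DataFrame(rows, columns=POINT_COLUMNS).to_csv(path, index=False)


def read_points_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    missing = set(POINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"point CSV {path} missing columns: {sorted(missing)}")
    return {
        str(r.label): np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float)
        for r in df.itertuples()
    }


def write_points_json(path: str | Path, points: Mapping[str, np.ndarray]) -> None:
    payload = [
        {"label": lbl, "x_mm": float(p[0]), "y_mm": float(p[1]), "z_mm": float(p[2])}
        for lbl, p in points.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_points_json(path: str | Path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {
        str(e["label"]): np.array([e["x_mm"], e["y_mm"], e["z_mm"]], dtype=float)
        for e in payload
    }


def read_points(path: str | Path) -> dict[str, np.ndarray]:
    """Dispatch on suffix: ``.json`` -> JSON, anything else -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_points_json(path)
    return read_points_csv(path)


def points_to_array(points: Mapping[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    """Split a labelled mapping into (labels, (N,3) array), preserving order."""
    labels = list(points)
    arr = np.vstack([points[l] for l in labels]) if labels else np.empty((0, 3))
    return labels, arr


def write_candidates_csv(path: str | Path, candidate_sets: Sequence[CandidateSet]) -> None:
    rows = []
    for cs in candidate_sets:
        for k in range(1, cs.n_positions + 1):
            p = cs.position(k)
            rows.append(
                {
                    "wheel": cs.wheel_id,
                    "position_index": k,
                    "x_mm": p[0],
                    "y_mm": p[1],
                    "z_mm": p[2],
                }
            )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, index=False)
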