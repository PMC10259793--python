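"""Stable file contracts: trace CSV, deformity CSV, demograph CSV, TIFF.

Trace CSV (also the import path for manually digitized polylines):
columns ``cell_id, trace_role, point_index, x_um, y_um``. Roles follow
:data:`hyphamorph.geometry.TRACE_ROLES`; a cell with a ``bud_path`` trace is
taken to have a bud (budding stage), one with a ``hypha`` but no bud is
``hypha_no_bud``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .cells import CellRecord, DeformitySet
from .demograph import Demograph, PeakDistance
from .exceptions import InvalidTraceError
from .geometry import PolylineTrace

__all__ = ["cells_to_trace_frame", "write_traces", "read_traces",
           "write_deformities", "write_demograph", "read_demograph",
           "write_peak_distances", "read_image", "write_image"]

TRACE_COLUMNS = ["cell_id", "trace_role", "point_index", "x_um", "y_um"]


def cells_to_trace_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        parts: list[tuple[str, PolylineTrace]] = [("body_axis", cell.body_axis)]
        parts += [("hypha", h) for h in cell.hyphae]
        if cell.bud_path is not None:
            parts.append(("bud_path", cell.bud_path))
        for role, trace in parts:
            for i, (x, y) in enumerate(trace.points):
                rows.append((cell.cell_id, role, i, x, y))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_traces(cells: Iterable[CellRecord], path: str | Path) -> None:
    cells_to_trace_frame(cells).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[CellRecord]:
    """Rebuild geometric cell records from a trace CSV.

    Stage and bud flags are inferred from the roles present per cell; cells
    with multiple ``hypha`` traces are preserved (they will be ineligible
    for deformity scoring by the inclusion rule).
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidTraceError(f"trace CSV lacks columns {sorted(missing)}")
    cells = []
    for cell_id, cdf in df.groupby("cell_id", sort=False):
        traces: dict[str, list[PolylineTrace]] = {}
        for (role,), tdf in cdf.groupby(["trace_role"]):
            # multiple hypha traces are stored with the same role; split on
            # point_index resets
            pts = tdf.sort_values("point_index")[["point_index", "x_um", "y_um"]]
            starts = np.flatnonzero(pts["point_index"].to_numpy() == 0)
            bounds = list(starts) + [len(pts)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                arr = pts.iloc[a:b][["x_um", "y_um"]].to_numpy(float)
                traces.setdefault(role, []).append(
                    PolylineTrace(arr, role=role))
        if "body_axis" not in traces:
            raise InvalidTraceError(f"cell {cell_id}: no body_axis trace")
        hyphae = tuple(traces.get("hypha", []))
        bud = traces.get("bud_path", [None])[0]
        if bud is not None:
            stage = "budding"
        elif hyphae:
            stage = "hypha_no_bud"
        else:
            stage = "no_hypha"
        cells.append(CellRecord(
            cell_id=str(cell_id), body_axis=traces["body_axis"][0],
            hyphae=hyphae, bud_path=bud, has_bud=bud is not None,
            stage=stage))
    return cells


def write_deformities(results: Mapping[str, tuple[str | None, DeformitySet]],
                      path: str | Path) -> pd.DataFrame:
    """Write the deformity CSV: cell_id, strain, n_angles, junction_deg,
    kink_degs (semicolon-joined), d_h. Returns the frame written."""
    rows = []
    for cell_id, (strain, ds) in results.items():
        rows.append({
            "cell_id": cell_id,
            "strain": strain if strain is not None else "",
            "n_angles": ds.n_angles,
            "junction_deg": ds.junction_angle_deg,
            "kink_degs": ";".join(f"{a:.6f}" for a in ds.kink_angles_deg),
            "d_h": ds.d_h,
        })
    df = pd.DataFrame(rows, columns=["cell_id", "strain", "n_angles",
                                     "junction_deg", "kink_degs", "d_h"])
    df.to_csv(path, index=False)
    return df


def write_demograph(demo: Demograph, path: str | Path) -> None:
    """Dense matrix CSV (header row = bin centers, µm) + sidecar metadata."""
    path = Path(path)
    demo.to_frame().to_csv(path, index_label="cell_id")
    meta = {"stage_group": demo.stage_group, "channel": demo.channel,
            "bin_step_um": demo.bin_step_um,
            "n_cells": int(demo.matrix.shape[0]),
            "cell_lengths_um": [float(v) for v in demo.cell_lengths_um]}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_demograph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


def write_peak_distances(dists: Sequence[PeakDistance],
                         path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([{"cell_id": d.cell_id, "channel": d.channel,
                        "distance_um": d.distance_um} for d in dists],
                      columns=["cell_id", "channel", "distance_um"])
    df.to_csv(path, index=False)
    return df


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(path: str | Path, data: np.ndarray,
                pixel_size_um: float | None = None) -> None:
    kwargs = {}
    if pixel_size_um is not None:
        per_cm = 1e4 / pixel_size_um
        kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(str(path), data, **kwargs)
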