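"""End-to-end stage orchestration shared by the CLI and the test-bench.

Stages communicate through the CSV contracts in :mod:`hyphamorph.io`; the
functions here take in-memory cell records so they are equally usable as a
library. No silent exclusions: every input cell ends up either measured or
listed with an exclusion reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cells import CellRecord, compute_deformity
from .config import RunConfig
from .demograph import build_demograph, paired_offsets, peak_to_tip
from .exceptions import (
    EmptyGroupError,
    HyphamorphError,
    IneligibleCellError,
    UnmeasurableTraceError,
)
from .geometry import arc_length
from .stats import ComparisonResult, group_table, kruskal_wallis

__all__ = ["run_deformity", "run_localization", "write_manifest"]

log = logging.getLogger(__name__)


def run_deformity(cells_by_group: Mapping[str, Sequence[CellRecord]],
                  config: RunConfig,
                  ) -> tuple[pd.DataFrame, ComparisonResult | None, pd.DataFrame]:
    """Score d_h for every eligible cell; compare groups when there are >=2.

    Returns (per-cell deformity frame, omnibus comparison or None, exclusion
    log). The deformity frame also carries the hyphal length so length
    comparisons share one pass.
    """
    rows = []
    excluded = []
    for group, cells in cells_by_group.items():
        for cell in cells:
            try:
                ds = compute_deformity(
                    cell, simplify_tol_um=config.simplify_tol_um,
                    min_kink_deg=config.min_kink_deg,
                    include_junction=config.include_junction)
            except (IneligibleCellError, UnmeasurableTraceError) as exc:
                excluded.append({"group": group, "cell_id": cell.cell_id,
                                 "reason": str(exc)})
                log.warning("excluded %s: %s", cell.cell_id, exc)
                continue
            rows.append({
                "cell_id": cell.cell_id, "strain": group,
                "n_angles": ds.n_angles,
                "junction_deg": ds.junction_angle_deg,
                "kink_degs": ";".join(f"{a:.6f}" for a in ds.kink_angles_deg),
                "d_h": ds.d_h,
                "hypha_length_um": arc_length(cell.hyphae[0]),
            })
            log.info("measured %s: d_h = %.4f", cell.cell_id, ds.d_h)
    deform = pd.DataFrame(rows, columns=["cell_id", "strain", "n_angles",
                                         "junction_deg", "kink_degs", "d_h",
                                         "hypha_length_um"])
    excl = pd.DataFrame(excluded, columns=["group", "cell_id", "reason"])
    n_in = sum(len(v) for v in cells_by_group.values())
    assert len(deform) + len(excl) == n_in, "cells lost without a reason"

    comparison = None
    groups_present = deform["strain"].unique()
    if len(groups_present) >= 2:
        samples = {g: deform.loc[deform["strain"] == g, "d_h"].to_numpy()
                   for g in groups_present}
        comparison = kruskal_wallis(samples, metric="d_h",
                                    thresholds=config.significance_thresholds)
    return deform, comparison, excl


def run_localization(cells: Sequence[CellRecord], config: RunConfig,
                     channels: Sequence[str] | None = None,
                     ) -> tuple[dict, pd.DataFrame, pd.DataFrame | None]:
    """Demographs per stage group and channel, peak distances, paired offsets.

    Returns (demographs keyed by (stage, channel), peak-distance frame,
    paired-offset frame for the first two channels or None). Empty stage
    groups are skipped with a log entry.
    """
    if channels is None:
        chans: list[str] = []
        for c in cells:
            for k in c.profiles:
                if k not in chans:
                    chans.append(k)
        channels = chans
    if not channels:
        raise EmptyGroupError("no channels with profiles")

    demographs = {}
    for stage in ("no_hypha", "hypha_no_bud", "budding"):
        for chan in channels:
            try:
                demographs[(stage, chan)] = build_demograph(
                    cells, stage, chan, bin_step_um=config.bin_step_um)
            except EmptyGroupError:
                log.info("stage %s / channel %s: no cells, skipped",
                         stage, chan)

    peak_rows = []
    for cell in cells:
        for chan in channels:
            try:
                pd_ = peak_to_tip(cell, chan,
                                  smooth_window_um=config.smooth_window_um,
                                  include_bud=config.include_bud_in_peak)
            except IneligibleCellError:
                continue
            peak_rows.append({"cell_id": cell.cell_id, "channel": chan,
                              "distance_um": pd_.distance_um})
    peaks = pd.DataFrame(peak_rows, columns=["cell_id", "channel",
                                             "distance_um"])
    paired = None
    if len(channels) >= 2:
        paired = paired_offsets(cells, channels[0], channels[1],
                                smooth_window_um=config.smooth_window_um,
                                include_bud=config.include_bud_in_peak)
    return demographs, peaks, paired


def write_manifest(outdir: str | Path, config: RunConfig,
                   inputs: Sequence[str | Path] = ()) -> Path:
    """Machine-readable run manifest: inputs with hashes, config, version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in inputs:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.is_file() else None
        entries.append({"path": str(p), "sha256": digest})
    cfg = asdict(config)
    cfg["significance_thresholds"] = [
        [t, lab] for t, lab in config.significance_thresholds]
    cfg["channels"] = list(config.channels)
    manifest = {"version": __version__, "inputs": entries, "config": cfg}
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(outdir / "effective_config.yaml")
    return path
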