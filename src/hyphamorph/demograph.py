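"""Population-level localization analysis: demographs and peak-to-tip distances.

A demograph stacks per-cell normalized fluorescence intensity profiles as
heatmap rows, cells sorted by length, so that population-wide localization
patterns (e.g. a signal tracking the hyphal tip) become visible. Profiles are
aligned at the non-hyphal body pole (column 0) and min-max normalized per
cell; absolute brightness is deliberately discarded. The peak-to-tip distance
is the arc distance from the hyphal tip to the maximum of a channel's
profile restricted to the hypha (plus bud), after light smoothing — terminal
signals give distances near zero, subterminal ones positive distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cells import STAGES, CellRecord
from .exceptions import (
    ConfigurationError,
    EmptyGroupError,
    IneligibleCellError,
    InvalidGeometryError,
)

__all__ = ["Demograph", "PeakDistance", "build_demograph", "peak_to_tip",
           "paired_offsets"]


@dataclass
class Demograph:
    """Stacked normalized profiles for one stage group and channel.

    ``matrix`` rows are cells sorted ascending by length; columns are
    arc-length bins of width ``bin_step_um`` measured from the non-hyphal
    body pole. Bins beyond a cell's length are NaN.
    """

    matrix: np.ndarray
    cell_ids: list[str]
    cell_lengths_um: np.ndarray
    bin_step_um: float
    stage_group: str
    channel: str

    @property
    def bin_centers_um(self) -> np.ndarray:
        return (np.arange(self.matrix.shape[1]) + 0.5) * self.bin_step_um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cell_ids,
                            columns=np.round(self.bin_centers_um, 6))


@dataclass(frozen=True)
class PeakDistance:
    """Arc distance (µm) from the hyphal tip to a channel's peak signal."""

    cell_id: str
    channel: str
    distance_um: float

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise InvalidGeometryError("peak distance cannot be negative")


def _normalize_row(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:  # constant profile: degenerate range maps to zeros
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def build_demograph(cells: Sequence[CellRecord], stage: str, channel: str,
                    bin_step_um: float = 0.05) -> Demograph:
    """Stack the profiles of all cells in one stage group.

    Each cell's profile is resampled onto pole-aligned bins of
    ``bin_step_um`` and min-max normalized; rows are sorted ascending by
    cell length (ties broken by cell id, so input order never matters).
    """
    if stage not in STAGES:
        raise ConfigurationError(
            f"stage must be one of {STAGES}, got {stage!r}")
    if bin_step_um <= 0:
        raise ConfigurationError("bin_step_um must be positive")
    group = [c for c in cells
             if c.stage == stage and channel in c.profiles
             and c.profile_arc_um is not None]
    if not group:
        raise EmptyGroupError(
            f"no cells of stage {stage!r} with channel {channel!r}")
    group.sort(key=lambda c: (c.cell_length_um, c.cell_id))
    lengths = np.array([c.cell_length_um for c in group])
    n_bins = int(np.ceil(lengths.max() / bin_step_um))
    matrix = np.full((len(group), n_bins), np.nan)
    for i, cell in enumerate(group):
        n_occ = int(np.ceil(cell.cell_length_um / bin_step_um))
        centers = (np.arange(n_occ) + 0.5) * bin_step_um
        centers = np.minimum(centers, cell.profile_arc_um[-1])
        row = np.interp(centers, cell.profile_arc_um, cell.profiles[channel])
        matrix[i, :n_occ] = _normalize_row(row)
    return Demograph(matrix=matrix, cell_ids=[c.cell_id for c in group],
                     cell_lengths_um=lengths, bin_step_um=bin_step_um,
                     stage_group=stage, channel=channel)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[pad:len(values) + pad]


def peak_to_tip(cell: CellRecord, channel: str,
                smooth_window_um: float = 0.15,
                include_bud: bool = True) -> PeakDistance:
    """Distance from the hyphal tip to the channel's peak signal, in µm.

    The profile is restricted to the hypha (and bud, unless
    ``include_bud=False``), smoothed with a moving average of width
    ``smooth_window_um``, and the arc position of its maximum is subtracted
    from the tip arc position. Ties are broken toward the tip.
    """
    if not cell.hyphae:
        raise IneligibleCellError(f"cell {cell.cell_id} has no hypha")
    if channel not in cell.profiles or cell.profile_arc_um is None:
        raise IneligibleCellError(
            f"cell {cell.cell_id} lacks a profile for channel {channel!r}")
    arc = cell.profile_arc_um
    prof = np.asarray(cell.profiles[channel], float)
    start = cell.hypha_start_um if cell.hypha_start_um is not None else 0.0
    if include_bud or cell.bud_start_um is None:
        stop = arc[-1]
    else:
        stop = cell.bud_start_um
    sel = (arc >= start) & (arc <= stop)
    if sel.sum() < 1:
        raise IneligibleCellError(
            f"cell {cell.cell_id}: no profile samples on the hypha")
    arc_h = arc[sel]
    step = np.median(np.diff(arc)) if arc.size > 1 else smooth_window_um
    window = max(int(round(smooth_window_um / step)), 1)
    sm = _smooth(prof[sel], window)
    peaks = np.flatnonzero(sm == sm.max())
    i = peaks[-1]  # tie toward the tip
    peak_arc = arc_h[i]
    if 0 < i < sm.size - 1:
        # parabolic sub-sample refinement removes the sampling-grid bias
        denom = sm[i - 1] - 2.0 * sm[i] + sm[i + 1]
        if denom < 0:
            delta = 0.5 * (sm[i - 1] - sm[i + 1]) / denom
            peak_arc = peak_arc + float(np.clip(delta, -0.5, 0.5)) * step
    tip_arc = arc[-1]
    return PeakDistance(cell_id=cell.cell_id, channel=channel,
                        distance_um=float(max(tip_arc - peak_arc, 0.0)))


def paired_offsets(cells: Sequence[CellRecord], channel_a: str,
                   channel_b: str, **kwargs) -> pd.DataFrame:
    """Per-cell peak-to-tip distances for two channels plus their difference.

    Returns a frame with columns ``cell_id``, ``dist_a_um``, ``dist_b_um``,
    ``offset_um`` (b minus a), skipping cells where either channel fails.
    """
    rows = []
    for cell in cells:
        try:
            a = peak_to_tip(cell, channel_a, **kwargs)
            b = peak_to_tip(cell, channel_b, **kwargs)
        except IneligibleCellError:
            continue
        rows.append({"cell_id": cell.cell_id,
                     "dist_a_um": a.distance_um,
                     "dist_b_um": b.distance_um,
                     "offset_um": b.distance_um - a.distance_um})
    return pd.DataFrame(rows)
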