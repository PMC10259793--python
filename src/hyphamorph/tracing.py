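"""From binary cell masks to cell geometry.

The tracer consumes label masks (segmentation itself is out of scope — any
segmenter, or manual outlining, may produce them) and recovers per-cell
medial-axis geometry: a topological skeleton with per-pixel local width from
the Euclidean distance transform, pruned of short spurs, partitioned into
body / hypha / bud by width thresholds, and classified into the three growth
stages. Cells touching the border, with ambiguous topology, or with genuine
branches are excluded with a recorded reason, never silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d, map_coordinates
from skimage.morphology import skeletonize

from .cells import CellRecord
from .exceptions import InvalidGeometryError, MissingLabelError
from .geometry import PolylineTrace, arc_length

__all__ = ["LabeledMask", "SkeletonGraph", "skeletonize_cell",
           "partition_cell", "extract_profiles", "trace_image"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledMask:
    """Integer label image (0 = background) with its pixel size in µm."""

    labels: np.ndarray
    pixel_size_um: float
    image_id: str = "image"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise InvalidGeometryError("label mask must be 2D")
        if self.pixel_size_um <= 0:
            raise InvalidGeometryError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", lab)


@dataclass
class SkeletonGraph:
    """Pruned medial-axis path of one cell.

    ``path_um`` is the ordered (x, y) polyline in micrometres (sub-pixel,
    smoothed, tips extended to the mask boundary); ``width_um`` the local
    tube width (twice the distance-transform value) at each path point.
    """

    label: int
    path_um: np.ndarray | None
    width_um: np.ndarray | None
    excluded_reason: str | None = None
    n_pruned_spurs: int = 0
    area_px: int = 0


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for rc in pix:
        g.add_node(rc)
    for (r, c) in pix:
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in pix:
                g.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    return g


def skeletonize_cell(mask: LabeledMask, label: int,
                     prune_len_um: float = 0.2,
                     min_area_px: int = 20,
                     tip_extension: bool = True) -> SkeletonGraph:
    """Skeletonize one labelled component into a simple medial path.

    The skeleton's longest endpoint-to-endpoint geodesic is the medial path;
    side branches shorter than ``prune_len_um`` are pruned as spurs, longer
    ones mark the cell as branched (excluded). Components below
    ``min_area_px`` or touching the image border are excluded with a reason.
    Path tips are extended along their local direction to the mask boundary
    to undo the end-retraction inherent to skeletonization.
    """
    lab = mask.labels
    binary = lab == label
    area = int(binary.sum())
    if area == 0:
        raise MissingLabelError(f"label {label} absent from {mask.image_id}")
    graph = SkeletonGraph(label=label, path_um=None, width_um=None,
                          area_px=area)
    if area < min_area_px:
        graph.excluded_reason = "area_below_minimum"
        return graph
    rows, cols = np.nonzero(binary)
    if (rows.min() == 0 or cols.min() == 0
            or rows.max() == lab.shape[0] - 1 or cols.max() == lab.shape[1] - 1):
        log.warning("label %d touches the image border; excluded", label)
        graph.excluded_reason = "touches_border"
        return graph

    pad = 2
    r0, r1 = rows.min() - pad, rows.max() + pad + 1
    c0, c1 = cols.min() - pad, cols.max() + pad + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    crop = binary[r0:r1, c0:c1]
    skel = skeletonize(crop)
    edt = distance_transform_edt(crop)
    if skel.sum() < 2:
        graph.excluded_reason = "degenerate_skeleton"
        return graph

    g = _pixel_graph(skel)
    endpoints = [n for n in g.nodes if g.degree[n] <= 1]
    if len(endpoints) < 2:
        graph.excluded_reason = "cyclic_skeleton"
        return graph

    # longest geodesic between endpoints = the medial path
    best = (-1.0, None, None)
    for i, src in enumerate(endpoints):
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints[i + 1:]:
            if dst in dist and dist[dst] > best[0]:
                best = (dist[dst], src, dst)
    if best[1] is None:
        graph.excluded_reason = "disconnected_skeleton"
        return graph
    main = nx.dijkstra_path(g, best[1], best[2], weight="weight")
    main_set = set(main)

    prune_px = prune_len_um / mask.pixel_size_um
    n_pruned = 0
    for ep in endpoints:
        if ep in main_set:
            continue
        spur_len = nx.multi_source_dijkstra(g, main_set, ep, weight="weight")[0]
        if spur_len > prune_px:
            graph.excluded_reason = "branched"
            return graph
        n_pruned += 1
    graph.n_pruned_spurs = n_pruned

    path = np.asarray(main, dtype=float)  # (n, 2) rows, cols in crop frame
    width_px = edt[tuple(np.asarray(main).T)] * 2.0

    if tip_extension:
        path, width_px = _extend_tips(path, width_px, crop)

    # sub-pixel smoothing of the staircase path; endpoints stay pinned
    if path.shape[0] > 7:
        sm = gaussian_filter1d(path, sigma=1.0, axis=0, mode="nearest")
        sm[0], sm[-1] = path[0], path[-1]
        path = sm
    path_um = np.column_stack([(path[:, 1] + c0) * mask.pixel_size_um,
                               (path[:, 0] + r0) * mask.pixel_size_um])
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(path_um, axis=0), axis=1) > 1e-9])
    graph.path_um = path_um[keep]
    graph.width_um = (width_px * mask.pixel_size_um)[keep]
    return graph


def _extend_tips(path: np.ndarray, width_px: np.ndarray,
                 binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continue each path end along its local direction until leaving the mask."""

    def extend(anchor_idx: slice, tip: np.ndarray) -> np.ndarray | None:
        seg = path[anchor_idx]
        d = tip - seg.mean(axis=0)
        norm = np.linalg.norm(d)
        if norm == 0:
            return None
        d = d / norm
        pos = tip.copy()
        last_inside = None
        for _ in range(200):
            pos = pos + d * 0.5
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < binary.shape[0] and 0 <= c < binary.shape[1]) \
                    or not binary[r, c]:
                break
            last_inside = pos.copy()
        return last_inside

    k = min(5, path.shape[0] - 1)
    head = extend(slice(1, 1 + k), path[0])
    tail = extend(slice(-1 - k, -1), path[-1])
    if head is not None:
        path = np.vstack([head, path])
        width_px = np.concatenate([[width_px[0]], width_px])
    if tail is not None:
        path = np.vstack([path, tail])
        width_px = np.concatenate([width_px, [width_px[-1]]])
    return path, width_px


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    out = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def _crossing_arc(arc: np.ndarray, w: np.ndarray, i: int, thr: float,
                  rising: bool = False) -> float:
    """Sub-index arc position where the width profile crosses ``thr``
    between samples i and i+1 (falling by default)."""
    if i < 0 or i + 1 >= len(arc):
        return float(arc[max(min(i, len(arc) - 1), 0)])
    w0, w1 = float(w[i]), float(w[i + 1])
    if w0 == w1:
        return float(arc[i])
    t = (thr - w0) / (w1 - w0)
    t = min(max(t, 0.0), 1.0)
    return float(arc[i] + t * (arc[i + 1] - arc[i]))


def partition_cell(skel: SkeletonGraph,
                   body_width_ratio: float = 0.6,
                   bud_width_ratio: float = 0.5,
                   min_hypha_len_um: float = 0.5,
                   min_bud_len_um: float = 0.2) -> CellRecord:
    """Split a medial path into body / hypha / bud and classify the stage.

    The widest contiguous region (local width >= ``body_width_ratio`` times
    the maximum width) is the cell body; a thin terminal path is the hypha; a
    terminal thick region at the hypha's distal end (width >=
    ``bud_width_ratio`` times the body width) is a bud. Thin paths on both
    body sides mark a second hypha and exclude the cell. Deterministic:
    partitioning the same skeleton twice yields identical records.
    """
    cid = f"cell_{skel.label:04d}"
    if skel.path_um is None:
        raise InvalidGeometryError(
            f"{cid}: no medial path ({skel.excluded_reason})")
    path = skel.path_um
    width = skel.width_um.astype(float)
    # light smoothing of the width profile stabilises threshold crossings
    wsm = gaussian_filter1d(width, sigma=1.0, mode="nearest")
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(path, axis=0), axis=1))])

    thr_body = body_width_ratio * wsm.max()
    wide = wsm >= thr_body
    runs = _runs(wide)
    imax = int(np.argmax(wsm))
    body_run = next((s, e) for s, e in runs if s <= imax < e)
    other_wide = [r for r in runs
                  if r != body_run and arc[r[1] - 1] - arc[r[0]] > min_bud_len_um]

    # orient: index 0 becomes the non-hyphal pole (shorter side beyond body)
    left_len = arc[body_run[0]]
    right_len = arc[-1] - arc[body_run[1] - 1]
    if left_len > right_len:
        path = path[::-1].copy()
        width = width[::-1].copy()
        wsm = wsm[::-1].copy()
        arc = arc[-1] - arc[::-1]
        n = len(wsm)
        body_run = (n - body_run[1], n - body_run[0])
        other_wide = [(n - e, n - s) for s, e in other_wide]
        left_len, right_len = right_len, left_len

    body_r = wsm.max() / 2.0
    body_width = float(np.median(wsm[body_run[0]:body_run[1]]))

    # Past the pole center the medial-line distance transform falls linearly
    # (r - t to the spherical cap), so the width threshold is crossed
    # r - thr/2 before the cell surface; shift the attachment accordingly.
    i_cross = body_run[1] - 1
    s_cross = _crossing_arc(arc, wsm, i_cross, thr_body)
    cap_off = max(body_r - thr_body / 2.0, 0.0)
    s_attach = s_cross + cap_off
    i1 = int(np.searchsorted(arc, s_attach))
    i1 = min(max(i1, body_run[0] + 1), len(arc) - 2)

    excluded = None
    if left_len > min_hypha_len_um:
        excluded = "second_hypha"

    tail_len = arc[-1] - arc[i1]
    hyphae: tuple[PolylineTrace, ...] = ()
    bud_trace = None
    has_bud = False
    hypha_start = None
    bud_start = None
    j = len(arc) - 1
    if tail_len > min_hypha_len_um:
        # bud = last wide run in the tail reaching close to the tip
        thr_bud = bud_width_ratio * body_width
        tail_wide = wsm >= thr_bud
        tail_wide[:i1 + 1] = False
        bruns = [r for r in _runs(tail_wide)
                 if arc[r[1] - 1] - arc[r[0]] >= min_bud_len_um]
        if bruns:
            s, e = bruns[-1]
            gap_to_tip = arc[-1] - arc[e - 1]
            if gap_to_tip <= max(body_width, 1.0):
                has_bud = True
                # entering the bud sphere the medial-line width rises
                # linearly, so the crossing lies r_bud - thr/2 past the
                # neck; walk it back toward the hypha
                bud_r = float(wsm[s:e].max()) / 2.0
                s_cross_bud = _crossing_arc(arc, wsm, s - 1, thr_bud,
                                            rising=True)
                cap_bud = max(bud_r - thr_bud / 2.0, 0.0)
                s_neck = s_cross_bud - cap_bud
                j = int(np.searchsorted(arc, s_neck))
                j = min(max(j, i1 + 1), len(arc) - 2)
        if not has_bud:
            # round tube cap: the extended tip overshoots the medial tip by
            # the local half-width; trim it for the hypha trace
            tip_w = float(np.median(wsm[min(i1 + 1, len(arc) - 1):]))
            s_tip = arc[-1] - tip_w / 2.0
            j = int(np.clip(np.searchsorted(arc, s_tip), i1 + 1, len(arc) - 1))
        hypha_pts = path[i1:j + 1]
        if hypha_pts.shape[0] >= 2 and arc[j] - arc[i1] > min_hypha_len_um:
            hyphae = (PolylineTrace(hypha_pts, role="hypha"),)
            hypha_start = float(arc[i1])
        else:
            hyphae = ()
            has_bud = False
            j = len(arc) - 1
        if has_bud and j < len(arc) - 1:
            bud_trace = PolylineTrace(path[j:], role="bud_path")
            bud_start = float(arc[j])
    if other_wide and not has_bud and excluded is None:
        excluded = "ambiguous_topology"

    if not hyphae:
        stage = "no_hypha"
        has_bud = False
        bud_trace = None
    else:
        stage = "budding" if has_bud else "hypha_no_bud"

    body_pts = path[:i1 + 1]
    if body_pts.shape[0] < 2:
        body_pts = path[:2]
    record = CellRecord(
        cell_id=cid,
        body_axis=PolylineTrace(body_pts, role="body_axis"),
        hyphae=hyphae,
        bud_path=bud_trace,
        has_bud=has_bud,
        stage=stage,
        excluded_reason=excluded or skel.excluded_reason,
        medial_path=PolylineTrace(path, role="medial_path"),
        hypha_start_um=hypha_start,
        bud_start_um=bud_start,
    )
    return record


def extract_profiles(images: Mapping[str, np.ndarray], cell: CellRecord,
                     pixel_size_um: float,
                     sample_step_um: float = 0.05,
                     normal_halfwidth_px: int = 1) -> CellRecord:
    """Sample per-channel intensity along the cell's medial path.

    Intensity is bilinearly interpolated at uniform arc-length steps and
    averaged across a (2*halfwidth+1)-pixel window perpendicular to the
    path. Fills ``cell.profiles`` and ``cell.profile_arc_um`` in place and
    returns the cell. Paths leaving the image bounds flag the cell as
    truncated.
    """
    if sample_step_um <= 0:
        raise InvalidGeometryError("sample_step_um must be positive")
    if cell.medial_path is None:
        raise InvalidGeometryError(f"{cell.cell_id}: no medial path")
    pts = cell.medial_path.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    arc = np.arange(0.0, total + sample_step_um / 2.0, sample_step_um)
    x = np.interp(arc, s, pts[:, 0]) / pixel_size_um
    y = np.interp(arc, s, pts[:, 1]) / pixel_size_um
    dx = np.gradient(x)
    dy = np.gradient(y)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    nx_, ny_ = -dy / norm, dx / norm

    first = next(iter(images.values()))
    h, w = first.shape
    if (x.min() < -0.5 or y.min() < -0.5 or x.max() > w - 0.5
            or y.max() > h - 0.5):
        cell.excluded_reason = cell.excluded_reason or "profile_truncated"
        log.warning("%s: medial path leaves image bounds; profile truncated",
                    cell.cell_id)
    offsets = range(-normal_halfwidth_px, normal_halfwidth_px + 1)
    for chan, img in images.items():
        acc = np.zeros_like(arc)
        for o in offsets:
            cols = np.clip(x + o * nx_, 0, w - 1)
            rows = np.clip(y + o * ny_, 0, h - 1)
            acc += map_coordinates(img.astype(float), [rows, cols], order=1)
        cell.profiles[chan] = acc / len(list(offsets))
    cell.profile_arc_um = arc
    cell.cell_length_um = float(total)
    return cell


def trace_image(images: Mapping[str, np.ndarray], mask: LabeledMask,
                labels: list[int] | None = None,
                prune_len_um: float = 0.2,
                min_area_px: int = 20,
                body_width_ratio: float = 0.6,
                bud_width_ratio: float = 0.5,
                sample_step_um: float = 0.05,
                ) -> tuple[list[CellRecord], list[dict]]:
    """Trace every labelled cell of one image.

    Returns measured cell records and a QC table (one dict per label with
    area, widths and exclusion reason). Excluded cells appear in the QC table
    only, so input count = measured + excluded-with-reason.
    """
    if labels is None:
        labels = sorted(int(v) for v in np.unique(mask.labels) if v != 0)
    cells: list[CellRecord] = []
    qc: list[dict] = []
    for label in labels:
        skel = skeletonize_cell(mask, label, prune_len_um=prune_len_um,
                                min_area_px=min_area_px)
        entry = {"image_id": mask.image_id, "label": label,
                 "area_px": skel.area_px, "n_pruned_spurs": skel.n_pruned_spurs,
                 "excluded_reason": skel.excluded_reason,
                 "max_width_um": (float(skel.width_um.max())
                                  if skel.width_um is not None else np.nan)}
        if skel.excluded_reason is not None:
            qc.append(entry)
            continue
        try:
            cell = partition_cell(skel, body_width_ratio=body_width_ratio,
                                  bud_width_ratio=bud_width_ratio)
        except InvalidGeometryError as exc:
            entry["excluded_reason"] = str(exc)
            qc.append(entry)
            continue
        cell.cell_id = f"{mask.image_id}_{label:04d}"
        if images:
            extract_profiles(images, cell, mask.pixel_size_um,
                             sample_step_um=sample_step_um)
        entry["excluded_reason"] = cell.excluded_reason
        entry["stage"] = cell.stage
        qc.append(entry)
        cells.append(cell)
    return cells, qc
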