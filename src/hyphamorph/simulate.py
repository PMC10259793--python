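"""Ground-truthed synthetic budding cells: geometry, profiles, and images.

The generator emulates the morphotypes the analysis assumes: a single
ellipsoid-ish mother cell (drawn as a capsule) with one polar hypha whose
kink angles follow a half-normal distribution, optionally terminated by a
spherical bud. A small spread parameter sigma produces near-straight,
wild-type-like hyphae; a large sigma produces the kinked-and-buckled
mutant-like morphotype. Every quantity the pipeline later measures (kink
angles, analytic d_h, hyphal length, peak-to-tip distances, stage) is
recorded as ground truth, and all randomness flows from the single spec seed.

Generated tubes are kept simple (non-self-overlapping): a hypha folding back
onto itself or the cell body within one tube width would rasterize to a
merged mask whose medial axis is no longer a simple path, which the tracer
would then reject as branched. Cells violating this are regenerated with a
logged retry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree

from .cells import CellRecord, _dh_formula
from .exceptions import ConfigurationError, InvalidGeometryError
from .geometry import PolylineTrace, arc_length

__all__ = ["PhenotypeSpec", "TruthRecord", "generate_cells", "rasterize",
           "truth_to_frame", "measure_snr"]

log = logging.getLogger(__name__)

_MAX_RETRIES = 100


@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters of one synthetic phenotype (strain-like condition).

    Angles are in degrees, lengths in micrometres. ``deflection_sigma_deg``
    is the half-normal scale of both kink and junction deflections, truncated
    to [0, 180]: ~5 for straight wild-type-like hyphae, ~40 for buckled
    mutant-like ones. ``stage_weights`` gives the sampling probabilities of
    the three growth stages (no hypha / one hypha without bud / budding);
    the default generates budding cells only, the stage the deformity
    measurement is restricted to.
    """

    name: str = "synthetic"
    n_cells: int = 100
    kink_count_mean: float = 3.0
    deflection_sigma_deg: float = 5.0
    junction_sigma_deg: float | None = None
    hypha_length_um: tuple[float, float] = (4.0, 0.8)
    body_length_um: float = 2.0
    body_width_um: float = 1.0
    hypha_width_um: float = 0.25
    bud_diameter_um: float = 0.9
    min_segment_um: float = 0.2
    min_kink_deg: float = 10.0
    stage_weights: tuple[float, float, float] = (0.0, 0.0, 1.0)
    peak_offsets_um: Mapping[str, float] = field(default_factory=dict)
    profile_step_um: float = 0.05
    spot_sigma_um: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kink_count_mean", "body_length_um", "body_width_um",
                     "hypha_width_um", "bud_diameter_um", "min_segment_um",
                     "profile_step_um", "spot_sigma_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.hypha_length_um[0] <= 0:
            raise ConfigurationError("mean hyphal length must be positive")
        if self.deflection_sigma_deg < 0:
            raise ConfigurationError("deflection_sigma_deg must be >= 0")
        w = np.asarray(self.stage_weights, float)
        if w.min() < 0 or w.sum() <= 0:
            raise ConfigurationError("stage_weights must be non-negative, sum > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth for one cell."""

    cell_id: str
    group: str
    stage: str
    junction_deg: float | None
    kink_angles_deg: tuple[float, ...]
    analytic_dh: float | None
    hypha_length_um: float | None
    cell_length_um: float
    peak_to_tip_um: dict[str, float]
    seed: int


def truth_to_frame(truths: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = asdict(t)
        row["kink_angles_deg"] = ";".join(f"{a:.6f}" for a in t.kink_angles_deg)
        for chan, d in row.pop("peak_to_tip_um").items():
            row[f"peak_to_tip_um_{chan}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s], [s, c]])


def _half_normal_angle(rng: np.random.Generator, sigma: float) -> float:
    """|N(0, sigma)| truncated to [0, 180]."""
    if sigma == 0.0:
        return 0.0
    for _ in range(1000):
        a = abs(rng.normal(0.0, sigma))
        if a <= 180.0:
            return a
    return 180.0


def _segment_lengths(rng: np.random.Generator, total: float, n: int,
                     minimum: float) -> np.ndarray:
    free = total - n * minimum
    u = rng.dirichlet(np.ones(n))
    return minimum + u * free


def _tube_is_simple(path_pts: np.ndarray, arc: np.ndarray,
                    clearance_um: float, arc_gap_um: float) -> bool:
    """True if no two path points farther than arc_gap_um along the path
    come within clearance_um of each other in the plane."""
    tree = cKDTree(path_pts)
    pairs = tree.query_pairs(clearance_um, output_type="ndarray")
    if pairs.size == 0:
        return True
    return bool(np.all(np.abs(arc[pairs[:, 0]] - arc[pairs[:, 1]]) < arc_gap_um))


def _dense_path(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~uniform arc steps; returns (points, arcs)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(math.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y]), si


def _point_at_arc(pts: np.ndarray, arc_pos: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    arc_pos = min(max(arc_pos, 0.0), s[-1])
    x = np.interp(arc_pos, s, pts[:, 0])
    y = np.interp(arc_pos, s, pts[:, 1])
    return np.array([x, y])


def _sample_stage(rng: np.random.Generator, weights: Sequence[float]) -> str:
    from .cells import STAGES
    w = np.asarray(weights, float)
    return STAGES[int(rng.choice(3, p=w / w.sum()))]


def _build_geometry(spec: PhenotypeSpec, rng: np.random.Generator,
                    stage: str) -> dict:
    """One attempt at a cell geometry; raises InvalidGeometryError on
    impossible or self-overlapping layouts."""
    theta = rng.uniform(0.0, 360.0)
    d0 = _rot(theta) @ np.array([1.0, 0.0])
    half_w = spec.body_width_um / 2.0
    axis_len = max(spec.body_length_um - spec.body_width_um, 0.2)
    pole0 = np.zeros(2)
    pole1 = pole0 + d0 * axis_len
    body_axis = np.vstack([pole0, pole1])

    out = {
        "body_axis": body_axis,
        "hypha": None,
        "bud": None,
        "junction_deg": None,
        "kinks": (),
    }
    if stage == "no_hypha":
        return out

    length = rng.normal(*spec.hypha_length_um)
    k = int(rng.poisson(spec.kink_count_mean))
    min_len = (k + 1) * spec.min_segment_um
    if length < min_len:
        raise InvalidGeometryError(
            f"hypha length {length:.2f} um cannot hold {k} kinks at "
            f"minimum segment {spec.min_segment_um} um"
        )
    sig_j = (spec.junction_sigma_deg if spec.junction_sigma_deg is not None
             else spec.deflection_sigma_deg)
    junction = _half_normal_angle(rng, sig_j)
    kinks = tuple(_half_normal_angle(rng, spec.deflection_sigma_deg)
                  for _ in range(k))
    signs = rng.choice([-1.0, 1.0], size=k + 1)
    seg_lens = _segment_lengths(rng, length, k + 1, spec.min_segment_um)

    attach = pole1 + d0 * half_w
    direction = _rot(signs[0] * junction) @ d0
    pts = [attach]
    for i in range(k + 1):
        pts.append(pts[-1] + direction * seg_lens[i])
        if i < k:
            direction = _rot(signs[i + 1] * kinks[i]) @ direction
    hypha = np.asarray(pts)

    bud = None
    if stage == "budding":
        bud_r = spec.bud_diameter_um / 2.0
        bud = np.vstack([hypha[-1], hypha[-1] + direction * spec.bud_diameter_um])

    # reject tubes that would merge with themselves or the body when drawn
    dense, darc = _dense_path(hypha, 0.05)
    clearance = 1.5 * spec.hypha_width_um
    if not _tube_is_simple(dense, darc, clearance, arc_gap_um=3 * clearance):
        raise InvalidGeometryError("hypha self-overlap")
    body_dense, _ = _dense_path(np.vstack([pole0 - d0 * half_w, attach]), 0.05)
    far = darc > (spec.body_width_um + spec.hypha_width_um)
    if np.any(far):
        dmat = cKDTree(body_dense).query(dense[far])[0]
        if dmat.min() < half_w + spec.hypha_width_um:
            raise InvalidGeometryError("hypha folds back onto the cell body")
    if bud is not None:
        bud_r = spec.bud_diameter_um / 2.0
        center = (bud[0] + bud[1]) / 2.0
        near_tip = darc > darc[-1] - (bud_r + spec.hypha_width_um)
        if np.any(~near_tip):
            if np.linalg.norm(dense[~near_tip] - center, axis=1).min() \
                    < bud_r + spec.hypha_width_um:
                raise InvalidGeometryError("bud overlaps the hypha")
        if np.linalg.norm(body_dense - center, axis=1).min() < bud_r + half_w:
            raise InvalidGeometryError("bud overlaps the cell body")

    out.update(hypha=hypha, bud=bud, junction_deg=junction, kinks=kinks)
    return out


def generate_cells(spec: PhenotypeSpec,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[CellRecord], list[TruthRecord]]:
    """Draw ``spec.n_cells`` synthetic cells with full ground truth.

    Returns cell records (geometry in micrometres, origin-anchored per cell,
    analytic intensity profiles filled for every channel in
    ``spec.peak_offsets_um``) and matching truth records. Deterministic for
    a given spec seed; pass ``rng`` to override the seed stream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cells: list[CellRecord] = []
    truths: list[TruthRecord] = []
    half_w = spec.body_width_um / 2.0
    for i in range(spec.n_cells):
        stage = _sample_stage(rng, spec.stage_weights)
        geom = None
        for attempt in range(_MAX_RETRIES):
            try:
                geom = _build_geometry(spec, rng, stage)
                break
            except InvalidGeometryError as exc:
                log.debug("cell %s attempt %d regenerated: %s", i, attempt, exc)
        if geom is None:
            raise InvalidGeometryError(
                f"could not generate a valid cell after {_MAX_RETRIES} retries "
                f"(spec {spec.name!r})"
            )
        cell_id = f"{spec.name}_{i:04d}"
        body_axis = PolylineTrace(geom["body_axis"], role="body_axis")
        d0 = geom["body_axis"][1] - geom["body_axis"][0]
        d0 = d0 / np.linalg.norm(d0)
        pole_surface = geom["body_axis"][0] - d0 * half_w

        path_parts = [pole_surface[None, :], geom["body_axis"]]
        hyphae: tuple[PolylineTrace, ...] = ()
        bud_trace = None
        hypha_start = None
        bud_start = None
        hypha_len = None
        if geom["hypha"] is not None:
            hyphae = (PolylineTrace(geom["hypha"], role="hypha"),)
            hypha_len = arc_length(geom["hypha"])
            path_parts.append(geom["hypha"])  # first point extends body axis
            hypha_start = half_w + arc_length(geom["body_axis"]) + half_w
        if geom["bud"] is not None:
            bud_trace = PolylineTrace(geom["bud"], role="bud_path")
            path_parts.append(geom["bud"][1:])
            bud_start = hypha_start + hypha_len
        path_pts = np.vstack(path_parts)
        # drop consecutive duplicates introduced by concatenation
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(path_pts, axis=0), axis=1) > 1e-12])
        medial = PolylineTrace(path_pts[keep], role="medial_path")
        cell_len = arc_length(medial)

        dh = None
        if geom["junction_deg"] is not None:
            # truth at the measurement convention: turns below the kink
            # threshold are micro-bends, not kinks, and do not enter d_h
            scored = tuple(a for a in geom["kinks"] if a >= spec.min_kink_deg)
            dh = _dh_formula(geom["junction_deg"], scored, 1 + len(scored))

        cell = CellRecord(
            cell_id=cell_id,
            body_axis=body_axis,
            hyphae=hyphae,
            bud_path=bud_trace,
            has_bud=geom["bud"] is not None,
            stage=stage,
            medial_path=medial,
            hypha_start_um=hypha_start,
            bud_start_um=bud_start,
            group=spec.name,
        )

        peak_truth: dict[str, float] = {}
        if spec.peak_offsets_um:
            arc = np.arange(0.0, cell_len + spec.profile_step_um / 2,
                            spec.profile_step_um)
            cell.profile_arc_um = arc
            for chan, offset in spec.peak_offsets_um.items():
                if stage == "no_hypha":
                    pos = rng.uniform(0.0, cell_len)
                else:
                    pos = cell_len - offset
                    peak_truth[chan] = float(offset)
                prof = 1.0 + 3.0 * np.exp(
                    -0.5 * ((arc - pos) / spec.spot_sigma_um) ** 2)
                cell.profiles[chan] = prof

        cells.append(cell)
        truths.append(TruthRecord(
            cell_id=cell_id, group=spec.name, stage=stage,
            junction_deg=geom["junction_deg"],
            kink_angles_deg=tuple(geom["kinks"]),
            analytic_dh=dh, hypha_length_um=hypha_len,
            cell_length_um=cell_len, peak_to_tip_um=peak_truth,
            seed=spec.seed,
        ))
    return cells, truths


# ---------------------------------------------------------------------------
# rasterization


def _cell_parts(cell: CellRecord, spec: PhenotypeSpec):
    """(polyline, radius) pairs describing the cell's tube support."""
    half_w = spec.body_width_um / 2.0
    parts = [(cell.body_axis.points, half_w)]
    for hy in cell.hyphae:
        parts.append((hy.points, spec.hypha_width_um / 2.0))
    if cell.bud_path is not None:
        center = cell.bud_path.points.mean(axis=0)
        parts.append((np.vstack([center, center + 1e-6]),
                      spec.bud_diameter_um / 2.0))
    return parts


def rasterize(cells: Sequence[CellRecord], spec: PhenotypeSpec,
              pixel_size_um: float = 0.065,
              psf_sigma_um: float = 0.08,
              noise: tuple[float, float] = (10.0, 1.0),
              background: float = 100.0,
              cytoplasm_intensity: float = 150.0,
              spot_amplitude: float = 400.0,
              margin_um: float = 1.0,
              rng: np.random.Generator | None = None,
              ) -> tuple[dict[str, np.ndarray], np.ndarray, list[CellRecord]]:
    """Draw cells as fluorescence images plus a label mask.

    Cells are placed on a non-overlapping grid. Each channel image contains a
    uniform cytoplasmic fill over the tube support plus one Gaussian spot per
    cell at the channel's true arc offset from the tip, blurred with a
    Gaussian PSF and corrupted with Poisson-scaled shot noise and additive
    Gaussian read noise (``noise = (gaussian_sd, poisson_scale)``; a
    ``poisson_scale`` of 0 disables shot noise). The label mask is the exact
    noiseless tube support (label = cell index + 1).

    Returns ``(channel_images, label_mask, placed_cells)`` where
    ``placed_cells`` are copies of the inputs translated into image
    coordinates (µm).
    """
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be positive")
    if psf_sigma_um < 0:
        raise ConfigurationError("psf_sigma_um must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    gaussian_sd, poisson_scale = noise

    # bounding boxes and grid placement
    boxes = []
    for cell in cells:
        pts = [p for p, _ in _cell_parts(cell, spec)]
        radius = max(r for _, r in _cell_parts(cell, spec))
        allpts = np.vstack(pts)
        lo = allpts.min(axis=0) - radius - margin_um
        hi = allpts.max(axis=0) + radius + margin_um
        boxes.append((lo, hi))
    widths = np.array([hi[0] - lo[0] for lo, hi in boxes])
    heights = np.array([hi[1] - lo[1] for lo, hi in boxes])
    n = len(cells)
    ncol = max(int(math.ceil(math.sqrt(n))), 1)
    col_w = widths.max() if n else 1.0
    row_h = heights.max() if n else 1.0
    nrow = int(math.ceil(n / ncol))
    canvas_w = ncol * col_w
    canvas_h = nrow * row_h
    shape = (int(math.ceil(canvas_h / pixel_size_um)) + 1,
             int(math.ceil(canvas_w / pixel_size_um)) + 1)

    labels = np.zeros(shape, dtype=np.int32)
    channels = {chan: np.zeros(shape, float) for chan in spec.peak_offsets_um}
    if not channels:
        channels = {"chan0": np.zeros(shape, float)}
    placed: list[CellRecord] = []

    for idx, cell in enumerate(cells):
        r, c = divmod(idx, ncol)
        lo, _ = boxes[idx]
        offset = np.array([c * col_w, r * row_h]) - lo
        moved = _translate_cell(cell, offset)
        placed.append(moved)
        _draw_cell(moved, spec, labels, channels, idx + 1, pixel_size_um,
                   cytoplasm_intensity, spot_amplitude)

    for chan, img in channels.items():
        if psf_sigma_um > 0:
            img = gaussian_filter(img, sigma=psf_sigma_um / pixel_size_um)
        img = img + background
        if poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
        if gaussian_sd > 0:
            img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
        channels[chan] = img
    return channels, labels, placed


def _translate_cell(cell: CellRecord, offset: np.ndarray) -> CellRecord:
    def mv(tr: PolylineTrace | None) -> PolylineTrace | None:
        return None if tr is None else tr.transformed(offset=offset)

    return CellRecord(
        cell_id=cell.cell_id,
        body_axis=mv(cell.body_axis),
        hyphae=tuple(mv(h) for h in cell.hyphae),
        bud_path=mv(cell.bud_path),
        has_bud=cell.has_bud,
        stage=cell.stage,
        branched=cell.branched,
        excluded_reason=cell.excluded_reason,
        medial_path=mv(cell.medial_path),
        profile_arc_um=None if cell.profile_arc_um is None
        else cell.profile_arc_um.copy(),
        profiles={k: v.copy() for k, v in cell.profiles.items()},
        hypha_start_um=cell.hypha_start_um,
        bud_start_um=cell.bud_start_um,
        group=cell.group,
    )


def _draw_cell(cell: CellRecord, spec: PhenotypeSpec, labels: np.ndarray,
               channels: dict[str, np.ndarray], label: int,
               px: float, fill: float, spot_amp: float) -> None:
    parts = _cell_parts(cell, spec)
    allpts = np.vstack([p for p, _ in parts])
    rmax = max(r for _, r in parts)
    pad = rmax + 4 * px
    lo = np.floor((allpts.min(axis=0) - pad) / px).astype(int)
    hi = np.ceil((allpts.max(axis=0) + pad) / px).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [labels.shape[1] - 1, labels.shape[0] - 1])
    w = hi[0] - lo[0] + 1
    h = hi[1] - lo[1] + 1
    support = np.zeros((h, w), bool)
    for pts, radius in parts:
        dense, _ = _dense_path(pts, px / 4.0)
        seed_img = np.ones((h, w), bool)
        cols = np.round(dense[:, 0] / px).astype(int) - lo[0]
        rows = np.round(dense[:, 1] / px).astype(int) - lo[1]
        ok = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
        seed_img[rows[ok], cols[ok]] = False
        dist = distance_transform_edt(seed_img) * px
        support |= dist <= radius
    sl = (slice(lo[1], lo[1] + h), slice(lo[0], lo[0] + w))
    labels[sl][support] = label

    yy, xx = np.mgrid[lo[1]:lo[1] + h, lo[0]:lo[0] + w]
    xum = xx * px
    yum = yy * px
    cell_len = arc_length(cell.medial_path) if cell.medial_path else 0.0
    for chan, img in channels.items():
        img[sl][support] += fill
        offset = spec.peak_offsets_um.get(chan)
        if offset is None or cell.medial_path is None:
            continue
        if cell.stage == "no_hypha":
            # random body position mirrors the dispersed pattern of
            # hypha-less cells; reuse the analytic profile peak if present
            continue
        pos = _point_at_arc(cell.medial_path.points, cell_len - offset)
        d2 = (xum - pos[0]) ** 2 + (yum - pos[1]) ** 2
        img[sl] += spot_amp * np.exp(-0.5 * d2 / spec.spot_sigma_um ** 2)


def measure_snr(image: np.ndarray, labels: np.ndarray) -> float:
    """Mean in-mask signal above background, over the background SD."""
    bg = image[labels == 0]
    fg = image[labels > 0]
    sd = bg.std()
    if sd == 0:
        return math.inf
    return float((fg.mean() - bg.mean()) / sd)
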