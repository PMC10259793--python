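"""Per-cell records and the hyphal deformity statistic d_h.

The deformity of a hypha is scored from the turn angles along its medial
axis: the emergence (junction) angle between the mother cell's long axis and
the initial hypha direction, plus the deflection of every kink. The sines of
all angles are summed and divided by the number of angles,

    d_h = (sin(junction) + sum_i sin(alpha_i)) / N,   N = 1 + #kinks,

giving 0 for a perfectly straight, collinearly emerging hypha and values
approaching 1 for heavily buckled ones. Only cells with initiated or finished
bud formation and exactly one unbranched hypha are eligible: budding marks
the stage at which hyphal growth has completed, and branched cells or cells
with a second hypha are disregarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    IneligibleCellError,
    InvalidGeometryError,
    UnmeasurableTraceError,
)
from .geometry import PolylineTrace, arc_length, detect_kinks, junction_angle

__all__ = ["STAGES", "CellRecord", "DeformitySet", "compute_deformity"]

STAGES = ("no_hypha", "hypha_no_bud", "budding")


@dataclass(frozen=True)
class DeformitySet:
    """All measured angles of one hypha and the resulting d_h value."""

    junction_angle_deg: float
    kink_angles_deg: tuple[float, ...]
    n_angles: int
    d_h: float
    junction_included: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.junction_angle_deg <= 180.0):
            raise InvalidGeometryError("junction angle outside [0, 180]")
        if any(not (0.0 <= a <= 180.0) for a in self.kink_angles_deg):
            raise InvalidGeometryError("kink angle outside [0, 180]")
        if self.n_angles < 1:
            raise InvalidGeometryError("n_angles must be positive")
        n_expected = len(self.kink_angles_deg) + (1 if self.junction_included else 0)
        if self.n_angles != n_expected:
            raise InvalidGeometryError(
                f"n_angles={self.n_angles} inconsistent with "
                f"{len(self.kink_angles_deg)} kinks "
                f"(junction_included={self.junction_included})"
            )
        junc = self.junction_angle_deg if self.junction_included else 0.0
        expected = _dh_formula(junc, self.kink_angles_deg, self.n_angles)
        if abs(self.d_h - expected) > 1e-12:
            raise InvalidGeometryError(
                f"d_h={self.d_h!r} inconsistent with angles (expected {expected!r})"
            )


def _dh_formula(junction_deg: float, kinks_deg: Sequence[float], n: int) -> float:
    sines = math.sin(math.radians(junction_deg))
    sines += sum(math.sin(math.radians(a)) for a in kinks_deg)
    return sines / n


@dataclass
class CellRecord:
    """One cell's decomposed geometry and (optionally) intensity profiles.

    Attributes
    ----------
    body_axis:
        Medial axis of the mother-cell body, ordered from the non-hyphal pole
        toward the hyphal pole.
    hyphae:
        Zero or more hypha traces, each ordered from attachment to tip (or to
        the bud neck when a bud is present).
    bud_path:
        Medial path through the nascent bud, from the bud neck outward, or
        ``None``.
    medial_path:
        The concatenated pole -> body -> hypha -> bud path used as the
        arc-length coordinate for intensity profiles. Optional for purely
        geometric records.
    profiles:
        Mapping channel name -> intensity values sampled along
        ``profile_arc_um``.
    hypha_start_um / bud_start_um:
        Arc positions (along the medial path) where the hypha and the bud
        begin; ``bud_start_um`` is None when there is no bud.
    """

    cell_id: str
    body_axis: PolylineTrace
    hyphae: tuple[PolylineTrace, ...] = ()
    bud_path: PolylineTrace | None = None
    has_bud: bool = False
    stage: str = "no_hypha"
    branched: bool = False
    excluded_reason: str | None = None
    cell_length_um: float = 0.0
    medial_path: PolylineTrace | None = None
    profile_arc_um: np.ndarray | None = None
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    hypha_start_um: float | None = None
    bud_start_um: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InvalidGeometryError(f"unknown stage {self.stage!r}")
        n_hyphae = len(self.hyphae)
        if self.stage == "no_hypha" and n_hyphae > 0:
            raise InvalidGeometryError("stage no_hypha but hyphae present")
        if self.stage in ("hypha_no_bud", "budding") and n_hyphae == 0:
            raise InvalidGeometryError(f"stage {self.stage} requires a hypha")
        if self.stage == "budding" and not self.has_bud:
            raise InvalidGeometryError("stage budding requires has_bud")
        if self.stage == "hypha_no_bud" and self.has_bud:
            raise InvalidGeometryError("stage hypha_no_bud but has_bud set")
        if self.cell_length_um == 0.0 and self.medial_path is not None:
            self.cell_length_um = arc_length(self.medial_path)

    @property
    def included_for_deformity(self) -> bool:
        """Inclusion rule: budding cells with exactly one unbranched hypha."""
        return (
            self.has_bud
            and len(self.hyphae) == 1
            and not self.branched
            and self.excluded_reason is None
        )

    @property
    def hypha(self) -> PolylineTrace:
        if not self.hyphae:
            raise IneligibleCellError(f"cell {self.cell_id} has no hypha")
        return self.hyphae[0]


def compute_deformity(cell: CellRecord, simplify_tol_um: float = 0.1,
                      min_kink_deg: float = 10.0,
                      include_junction: bool = True) -> DeformitySet:
    """Score the hyphal deformity d_h of one eligible cell.

    Kinks are detected on the simplified hypha trace; the junction angle is
    measured against the body long axis and, by default, counted as one of
    the N angles (a kink-free hypha then has N = 1 and d_h = sin(junction)).
    Setting ``include_junction=False`` divides by the kink count only and
    raises for kink-free hyphae.
    """
    if not cell.included_for_deformity:
        if not cell.has_bud:
            why = "no initiated or finished bud"
        elif len(cell.hyphae) != 1:
            why = f"{len(cell.hyphae)} hyphae (exactly one required)"
        elif cell.branched:
            why = "branched hypha"
        else:
            why = cell.excluded_reason or "excluded"
        raise IneligibleCellError(
            f"cell {cell.cell_id} not eligible for deformity scoring: {why}"
        )
    hypha = cell.hyphae[0]
    if arc_length(hypha) < 2.0 * simplify_tol_um:
        raise UnmeasurableTraceError(
            f"cell {cell.cell_id}: hypha shorter than twice the "
            f"simplification tolerance ({simplify_tol_um} um)"
        )
    junc = junction_angle(cell.body_axis, hypha, simplify_tol_um=simplify_tol_um)
    kinks = detect_kinks(hypha, simplify_tol_um=simplify_tol_um,
                         min_kink_deg=min_kink_deg)
    kink_angles = tuple(a for _, a in kinks)
    if include_junction:
        n = 1 + len(kink_angles)
        d_h = _dh_formula(junc, kink_angles, n)
    else:
        if not kink_angles:
            raise UnmeasurableTraceError(
                f"cell {cell.cell_id}: no kinks and junction excluded"
            )
        n = len(kink_angles)
        d_h = _dh_formula(0.0, kink_angles, n)
    return DeformitySet(junction_angle_deg=junc, kink_angles_deg=kink_angles,
                        n_angles=n, d_h=d_h,
                        junction_included=include_junction)
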