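import math

import numpy as np
import pytest

from hyphamorph.cells import CellRecord, DeformitySet, compute_deformity
from hyphamorph.exceptions import (
    IneligibleCellError,
    InvalidGeometryError,
    UnmeasurableTraceError,
)
from hyphamorph.geometry import PolylineTrace, deflection_angle, junction_angle

from helpers import make_hypha_cell


def brute_force_dh(cell):
    """Direct evaluation of the deformity formula from the raw polyline:
    mean sine of the junction angle and every interior-vertex deflection."""
    body = cell.body_axis.points
    hy = cell.hyphae[0].points
    attach = hy[0]
    if np.linalg.norm(attach - body[-1]) <= np.linalg.norm(attach - body[0]):
        axis_dir = body[-1] - body[0]
    else:
        axis_dir = body[0] - body[-1]
    angles = [deflection_angle(attach - axis_dir, attach, hy[1])]
    for i in range(1, len(hy) - 1):
        angles.append(deflection_angle(hy[i - 1], hy[i], hy[i + 1]))
    return sum(math.sin(math.radians(a)) for a in angles) / len(angles)


class TestAnalyticCases:
    def test_straight_collinear_hypha_scores_zero(self):
        cell = make_hypha_cell(junction_deg=0.0, kink_degs=())
        ds = compute_deformity(cell)
        assert ds.d_h == pytest.approx(0.0, abs=1e-12)
        assert ds.n_angles == 1

    def test_single_right_angle_kink_scores_half(self):
        cell = make_hypha_cell(junction_deg=0.0, kink_degs=(90.0,))
        ds = compute_deformity(cell)
        assert ds.d_h == pytest.approx(0.5, abs=1e-12)
        assert ds.n_angles == 2

    def test_supplementary_kinks_score_one_third(self):
        cell = make_hypha_cell(junction_deg=0.0, kink_degs=(30.0, 150.0))
        ds = compute_deformity(cell)
        assert ds.d_h == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert ds.n_angles == 3

    def test_kink_free_hypha_scores_sine_of_junction(self):
        cell = make_hypha_cell(junction_deg=35.0, kink_degs=())
        ds = compute_deformity(cell)
        assert ds.d_h == pytest.approx(math.sin(math.radians(35.0)), abs=1e-9)


class TestBruteForceOracle:
    def test_small_random_traces_match_direct_formula(self, rng):
        """<=8-vertex hyphae, tol=0: pipeline equals the raw-polyline formula."""
        for i in range(60):
            n_kinks = int(rng.integers(0, 6))
            kinks = rng.uniform(12.0, 168.0, size=n_kinks)
            junc = float(rng.uniform(0.0, 168.0))
            cell = make_hypha_cell(junction_deg=junc, kink_degs=tuple(kinks),
                                   seg_len=float(rng.uniform(0.5, 2.0)),
                                   cell_id=f"r{i}")
            ds = compute_deformity(cell, simplify_tol_um=0.0,
                                   min_kink_deg=10.0)
            assert ds.d_h == pytest.approx(brute_force_dh(cell), abs=1e-9)


class TestInvariances:
    def random_cell(self, rng, i):
        kinks = tuple(rng.uniform(12.0, 168.0, size=int(rng.integers(0, 5))))
        return make_hypha_cell(junction_deg=float(rng.uniform(0, 160)),
                               kink_degs=kinks, cell_id=f"v{i}")

    @staticmethod
    def transform_cell(cell, matrix, offset, scale=1.0):
        m = np.asarray(matrix, float) * scale

        def tx(tr, role):
            return tr.transformed(matrix=m, offset=offset)

        return CellRecord(
            cell_id=cell.cell_id,
            body_axis=tx(cell.body_axis, "body_axis"),
            hyphae=tuple(tx(h, "hypha") for h in cell.hyphae),
            bud_path=None if cell.bud_path is None else tx(cell.bud_path, "b"),
            has_bud=cell.has_bud, stage=cell.stage)

    def test_rigid_motion_and_scale_invariance(self, rng):
        for i in range(40):
            cell = self.random_cell(rng, i)
            ref = compute_deformity(cell).d_h
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            refl = np.array([[1.0, 0.0], [0.0, -1.0]])
            offset = rng.uniform(-50, 50, 2)
            scale = float(rng.uniform(0.2, 5.0))
            rotated = self.transform_cell(cell, rot, offset)
            assert compute_deformity(rotated).d_h == pytest.approx(ref, abs=1e-9)
            mirrored = self.transform_cell(cell, rot @ refl, offset)
            assert compute_deformity(mirrored).d_h == pytest.approx(ref, abs=1e-9)
            scaled = self.transform_cell(cell, np.eye(2), (0, 0), scale=scale)
            ds = compute_deformity(scaled, simplify_tol_um=0.1 * scale)
            assert ds.d_h == pytest.approx(ref, abs=1e-9)

    def test_supplement_symmetry_of_angles(self, rng):
        # sin(180 - a) = sin(a): interior-angle and deflection conventions agree
        for i in range(40):
            kinks = rng.uniform(12.0, 90.0, size=int(rng.integers(1, 5)))
            junc = float(rng.uniform(0, 90))
            a = compute_deformity(make_hypha_cell(junc, tuple(kinks)))
            b = compute_deformity(
                make_hypha_cell(180.0 - junc, tuple(180.0 - kinks)))
            assert a.d_h == pytest.approx(b.d_h, abs=1e-9)

    def test_monotone_in_single_kink_deflection(self):
        values = [compute_deformity(
            make_hypha_cell(0.0, (a,))).d_h for a in np.arange(12, 91, 6)]
        assert all(x2 >= x1 for x1, x2 in zip(values, values[1:]))

    def test_dh_bounded_to_unit_interval(self, rng):
        for i in range(60):
            cell = self.random_cell(rng, i)
            assert 0.0 <= compute_deformity(cell).d_h <= 1.0


class TestEligibility:
    def test_cell_without_bud_rejected(self):
        cell = make_hypha_cell(has_bud=False)
        with pytest.raises(IneligibleCellError, match="bud"):
            compute_deformity(cell)

    def test_cell_with_second_hypha_rejected(self):
        cell = make_hypha_cell()
        extra = PolylineTrace(np.array([[0.0, 0.0], [-2.0, 0.5]]),
                              role="hypha")
        cell.hyphae = cell.hyphae + (extra,)
        with pytest.raises(IneligibleCellError, match="hyphae"):
            compute_deformity(cell)

    def test_branched_cell_rejected(self):
        cell = make_hypha_cell()
        cell.branched = True
        with pytest.raises(IneligibleCellError, match="branched"):
            compute_deformity(cell)

    def test_hypha_below_resolution_unmeasurable(self):
        cell = make_hypha_cell(seg_len=0.05)
        with pytest.raises(UnmeasurableTraceError):
            compute_deformity(cell, simplify_tol_um=0.1)


class TestDeformitySet:
    def test_inconsistent_dh_rejected(self):
        with pytest.raises(InvalidGeometryError):
            DeformitySet(junction_angle_deg=0.0, kink_angles_deg=(90.0,),
                         n_angles=2, d_h=0.9)

    def test_n_angles_counts_junction(self):
        ds = DeformitySet(junction_angle_deg=0.0, kink_angles_deg=(90.0,),
                          n_angles=2, d_h=0.5)
        assert ds.n_angles == 1 + len(ds.kink_angles_deg)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(InvalidGeometryError):
            DeformitySet(junction_angle_deg=200.0, kink_angles_deg=(),
                         n_angles=1, d_h=0.0)
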