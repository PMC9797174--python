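"""Mean-dose computation and percent differences, checked against
independent brute-force oracles (voxel loops, ray-casting point-in-polygon)."""

import numpy as np
import pytest

from rtspc.dose_metrics import (
    DoseComparison,
    DoseMetricsError,
    VoxelMask,
    mean_dose,
    percent_difference,
    rasterize_structure,
    read_comparisons,
    resample_dose,
    summarize_plan,
    write_comparisons,
)
from rtspc.dose_model import (
    Contour,
    DoseGrid,
    MachineParameters,
    PlanDoseSummary,
    Structure,
    StructureSet,
)

from conftest import square_contour


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def point_in_polygon(x, y, pts):
    """Even-odd ray casting, coded independently of the implementation."""
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def oracle_mask(structure, grid):
    """Triple voxel loop + per-plane even-odd parity over polygons."""
    nx, ny, nz = grid.shape
    xs, ys, zs = (grid.axis_coords(a) for a in range(3))
    out = np.zeros((nx, ny, nz), bool)
    for k in range(nz):
        for i in range(nx):
            for j in range(ny):
                parity = 0
                for c in structure.contours:
                    if abs(zs[k] - c.z) <= 0.5 * grid.spacing[2] + 1e-9:
                        if point_in_polygon(xs[i], ys[j], c.points.tolist()):
                            parity ^= 1
                out[i, j, k] = bool(parity)
    return out


def oracle_mean(values, included):
    total, count = 0.0, 0
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if included[i, j, k] and np.isfinite(values[i, j, k]):
                    total += values[i, j, k]
                    count += 1
    return total / count


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


class TestRasterize:
    def test_square_contour_includes_100_voxels(self, constant_grid, square_structure):
        mask = rasterize_structure(square_structure, constant_grid)
        # centers at 1,3,...,19 in x and y all inside [0,20]; one slice
        assert mask.count == 100
        assert mask.included[:, :, 0].sum() == 100
        np.testing.assert_array_equal(mask.included, oracle_mask(square_structure, constant_grid))

    def test_contour_outside_grid_is_empty_mask_error(self, constant_grid):
        far = Structure(name="far", contours=(square_contour(1.0, 100, 120, 100, 120),))
        with pytest.raises(DoseMetricsError, match="empty mask.*far"):
            rasterize_structure(far, constant_grid)

    def test_concentric_squares_make_ring_by_even_odd(self, constant_grid):
        ring = Structure(
            name="ring",
            contours=(square_contour(1.0, 0, 20, 0, 20), square_contour(1.0, 6, 14, 6, 14)),
        )
        outer_only = Structure(name="o", contours=(square_contour(1.0, 0, 20, 0, 20),))
        inner_only = Structure(name="i", contours=(square_contour(1.0, 6, 14, 6, 14),))
        n_ring = rasterize_structure(ring, constant_grid).count
        n_outer = rasterize_structure(outer_only, constant_grid).count
        n_inner = rasterize_structure(inner_only, constant_grid).count
        assert n_ring == n_outer - n_inner == 100 - 16
        np.testing.assert_array_equal(
            rasterize_structure(ring, constant_grid).included, oracle_mask(ring, constant_grid)
        )

    def test_random_polygons_match_ray_casting_oracle(self, rng):
        """Star-shaped random polygons on a small grid vs the independent
        even-odd oracle, 100 polygons."""
        from shapely.geometry import Polygon

        grid = DoseGrid(origin=(0.5, 0.5, 0.0), spacing=(1, 1, 1), values=np.zeros((12, 12, 1)))
        checked = 0
        while checked < 100:
            n = rng.integers(3, 9)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radii = rng.uniform(2.0, 5.5, n)
            cx, cy = rng.uniform(4, 8, 2)
            pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
            if not Polygon(pts).is_valid:  # reject self-intersecting draws
                continue
            struct = Structure(name="p", contours=(Contour(z=0.0, points=pts),))
            expected = oracle_mask(struct, grid)
            if not expected.any():
                continue
            got = rasterize_structure(struct, grid).included
            np.testing.assert_array_equal(got, expected)
            checked += 1

    def test_slice_association_within_half_pitch(self, square_structure):
        # contour at z=2 with slice centers at 1,3,...: both neighbors are
        # exactly half a pitch away -> included (closed tolerance), others not
        grid = DoseGrid(origin=(1, 1, 1), spacing=(2, 2, 2), values=np.zeros((10, 10, 4)))
        struct = Structure(name="s", contours=(square_contour(1.6),))
        mask = rasterize_structure(struct, grid)
        assert mask.included[:, :, 0].any()  # z=1, distance 0.6 < 1
        assert not mask.included[:, :, 1].any()  # z=3, distance 1.4 > 1


# ---------------------------------------------------------------------------
# mean dose and resampling
# ---------------------------------------------------------------------------


class TestMeanDose:
    def test_constant_grid_any_mask(self, constant_grid, rng):
        inc = rng.random(constant_grid.shape) < 0.3
        inc[0, 0, 0] = True
        assert mean_dose(constant_grid, VoxelMask(constant_grid.shape, inc)) == 2.0

    def test_linear_field_symmetric_mask_gives_center_value(self):
        xs = np.arange(10) * 2.0 + 1.0
        vals = np.broadcast_to(xs[:, None, None], (10, 10, 10)).copy()
        grid = DoseGrid(origin=(1, 1, 1), spacing=(2, 2, 2), values=vals)
        inc = np.zeros((10, 10, 10), bool)
        inc[2:8, :, :] = True  # symmetric about x index 4.5 -> x = 10
        assert mean_dose(grid, VoxelMask(grid.shape, inc)) == pytest.approx(10.0)

    def test_random_grids_match_voxel_loop_oracle(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(2, 6, 3))
            vals = rng.uniform(0, 70, shape)
            inc = rng.random(shape) < 0.5
            if not inc.any():
                continue
            grid = DoseGrid(origin=(0, 0, 0), spacing=(1, 1, 1), values=vals)
            assert mean_dose(grid, VoxelMask(shape, inc)) == pytest.approx(
                oracle_mean(vals, inc), rel=1e-12
            )

    def test_empty_mask_is_error(self, constant_grid):
        with pytest.raises(DoseMetricsError, match="empty mask"):
            mean_dose(constant_grid, VoxelMask(constant_grid.shape, np.zeros((10, 10, 10), bool)))

    def test_translation_invariance(self, rng):
        """Translating grid and structure by the same vector leaves the
        mean dose unchanged."""
        vals = rng.uniform(0, 50, (8, 8, 4))
        shift = np.array([7.3, -4.1, 6.0])
        g0 = DoseGrid(origin=(0, 0, 0), spacing=(2, 2, 2), values=vals)
        g1 = DoseGrid(origin=tuple(shift), spacing=(2, 2, 2), values=vals)
        pts = np.array([[1.0, 1.0], [11.0, 2.0], [9.0, 12.0], [2.0, 10.0]])
        s0 = Structure(name="s", contours=(Contour(z=2.0, points=pts),))
        s1 = Structure(name="s", contours=(Contour(z=2.0 + shift[2], points=pts + shift[:2]),))
        m0 = mean_dose(g0, rasterize_structure(s0, g0))
        m1 = mean_dose(g1, rasterize_structure(s1, g1))
        assert m1 == pytest.approx(m0, rel=1e-12)


class TestResample:
    def test_identity_geometry_bitwise_equal(self, rng):
        grid = DoseGrid(origin=(1, 2, 3), spacing=(2, 2, 2), values=rng.uniform(0, 60, (5, 6, 7)))
        out = resample_dose(grid, grid.origin, grid.spacing, grid.shape)
        np.testing.assert_array_equal(out.values, grid.values)

    def test_linear_field_reproduced_exactly_at_interior_points(self):
        xs = np.arange(10) * 2.0
        vals = np.broadcast_to(3.0 * xs[:, None, None] + 5.0, (10, 10, 10)).copy()
        grid = DoseGrid(origin=(0, 0, 0), spacing=(2, 2, 2), values=vals)
        out = resample_dose(grid, (1.0, 2.0, 2.0), (1.7, 2.0, 2.0), (8, 8, 8))
        expect = 3.0 * (1.0 + 1.7 * np.arange(8)) + 5.0
        np.testing.assert_allclose(
            out.values, np.broadcast_to(expect[:, None, None], (8, 8, 8)), rtol=1e-12
        )

    def test_outside_points_get_nan_and_are_excluded_from_means(self, constant_grid):
        out = resample_dose(constant_grid, (-9.0, 1.0, 1.0), (2, 2, 2), (10, 10, 10))
        assert np.isnan(out.values[0, 0, 0])  # x=-9 outside [1, 19]
        finite = out.values[np.isfinite(out.values)]
        np.testing.assert_allclose(finite, 2.0)
        inc = np.ones(out.shape, bool)
        assert mean_dose(out, VoxelMask(out.shape, inc)) == 2.0

    def test_entirely_outside_is_error(self, constant_grid):
        with pytest.raises(DoseMetricsError, match="outside source grid"):
            resample_dose(constant_grid, (1000.0, 1000.0, 1000.0), (2, 2, 2), (3, 3, 3))


# ---------------------------------------------------------------------------
# plan summaries and percent differences
# ---------------------------------------------------------------------------


class TestSummarizePlan:
    def test_constant_field_two_structures(self, constant_grid):
        ss = StructureSet(
            structures=(
                Structure(name="A", contours=(square_contour(1.0),)),
                Structure(name="B", contours=(square_contour(3.0, 4, 16, 4, 16),)),
            ),
            frame_id="F1",
        )
        s = summarize_plan(constant_grid, ss, case_id="c1", source="reference")
        assert s.mean_dose_by_structure == {"A": 2.0, "B": 2.0}

    def test_structure_outside_grid_omitted_with_warning(self, constant_grid, caplog):
        ss = StructureSet(
            structures=(
                Structure(name="in", contours=(square_contour(1.0),)),
                Structure(name="out", contours=(square_contour(1.0, 500, 520, 500, 520),)),
            ),
            frame_id="F1",
        )
        with caplog.at_level("WARNING"):
            s = summarize_plan(constant_grid, ss, case_id="c1", source="local")
        assert "out" not in s.mean_dose_by_structure
        assert any("omitted" in r.message for r in caplog.records)

    def test_matches_individual_mean_dose_calls(self, rng):
        vals = rng.uniform(0, 60, (10, 10, 10))
        grid = DoseGrid(origin=(1, 1, 1), spacing=(2, 2, 2), values=vals, frame_id="F1")
        a = Structure(name="A", contours=(square_contour(1.0),))
        b = Structure(name="B", contours=(square_contour(5.0, 2, 18, 2, 18),))
        ss = StructureSet(structures=(a, b), frame_id="F1")
        s = summarize_plan(grid, ss, case_id="c", source="local")
        for struct in (a, b):
            expected = mean_dose(grid, rasterize_structure(struct, grid))
            assert s.mean_dose_by_structure[struct.name] == pytest.approx(expected, rel=1e-14)

    def test_frame_mismatch_rejected(self, constant_grid, square_structure):
        ss = StructureSet(structures=(square_structure,), frame_id="OTHER")
        with pytest.raises(DoseMetricsError, match="frame-of-reference"):
            summarize_plan(constant_grid, ss, case_id="c", source="local")


class TestPercentDifference:
    def test_hand_arithmetic(self):
        ref = PlanDoseSummary("A", "reference", {"brain": 2.0})
        loc = PlanDoseSummary("A", "local", {"brain": 2.2})
        comp = percent_difference(loc, ref)
        assert comp.pct_diff_by_structure["brain"] == pytest.approx(10.0)

    def test_identity_is_zero(self):
        ref = PlanDoseSummary("A", "reference", {"a": 3.0, "b": 50.0})
        loc = PlanDoseSummary("A", "local", dict(ref.mean_dose_by_structure))
        comp = percent_difference(loc, ref)
        assert all(v == 0.0 for v in comp.pct_diff_by_structure.values())

    def test_reference_below_floor_skipped_with_warning(self, caplog):
        ref = PlanDoseSummary("A", "reference", {"a": 0.0, "b": 10.0})
        loc = PlanDoseSummary("A", "local", {"a": 1.0, "b": 11.0})
        with caplog.at_level("WARNING"):
            comp = percent_difference(loc, ref)
        assert "a" not in comp.pct_diff_by_structure
        assert comp.pct_diff_by_structure["b"] == pytest.approx(10.0)
        assert any("floor" in r.message for r in caplog.records)

    def test_swap_identity(self, rng):
        """Exact role-swap relation: d_swapped = -100 d / (100 + d)."""
        for _ in range(25):
            r, l = rng.uniform(1, 60, 2)
            ref = PlanDoseSummary("A", "reference", {"s": r})
            loc = PlanDoseSummary("A", "local", {"s": l})
            d = percent_difference(loc, ref).pct_diff_by_structure["s"]
            loc_as_ref = PlanDoseSummary("A", "reference", {"s": l})
            ref_as_loc = PlanDoseSummary("A", "local", {"s": r})
            d_swap = percent_difference(ref_as_loc, loc_as_ref).pct_diff_by_structure["s"]
            assert d_swap == pytest.approx(-100.0 * d / (100.0 + d), rel=1e-10)

    def test_case_mismatch_and_no_shared_structures(self):
        ref = PlanDoseSummary("A", "reference", {"a": 1.0})
        with pytest.raises(DoseMetricsError, match="case mismatch"):
            percent_difference(PlanDoseSummary("B", "local", {"a": 1.0}), ref)
        with pytest.raises(DoseMetricsError, match="no shared structures"):
            percent_difference(PlanDoseSummary("A", "local", {"z": 1.0}), ref)


class TestComparisonIO:
    def test_roundtrip_with_params(self, tmp_path):
        params = MachineParameters(dlg_cm=0.17, mlc_tf=0.02, algorithm="Acuros")
        comps = [
            DoseComparison("c1", {"a": 1.5, "b": -0.3}, params=params),
            DoseComparison("c2", {"a": 0.7}, params=params),
        ]
        p = tmp_path / "c.csv"
        write_comparisons(comps, p)
        back = read_comparisons(p)
        assert len(back) == 2
        for a, b in zip(comps, back):
            assert a.case_id == b.case_id
            assert a.pct_diff_by_structure == pytest.approx(b.pct_diff_by_structure)
            assert a.params == b.params

    def test_crossed_sweep_cases_not_merged_across_levels(self, tmp_path):
        """The same plan recalculated at two parameter levels stays two rows."""
        comps = [
            DoseComparison("p1", {"a": -2.5}, params=MachineParameters(0.1, 0.02)),
            DoseComparison("p1", {"a": 0.7}, params=MachineParameters(0.23, 0.02)),
        ]
        p = tmp_path / "c.csv"
        write_comparisons(comps, p)
        back = read_comparisons(p)
        assert len(back) == 2
        assert {b.params.dlg_cm for b in back} == {0.1, 0.23}
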