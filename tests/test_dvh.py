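import numpy as np
import pytest

from conftest import random_phantom_and_field
from oracles import brute_force_dvh, brute_force_mask
from rtqa.dicom_rt_io import Structure
from rtqa.dvh import (
    DVHCurve,
    MetricSpec,
    compute_dvh,
    evaluate_metric,
    parse_metric,
    rasterize,
)
from rtqa.errors import DegenerateStructureError, DomainError, OutOfGridError
from rtqa.synthetic import DoseFieldSpec, PhantomSpec, make_dose_grid, make_structure


def _oracle_mask_and_dvh(structure, grid, dose_points):
    contours = [(c[:, :2].tolist(), float(c[0, 2])) for c in structure.contours]
    zc = grid.z_centers().tolist()
    z_tol = 0.5 * float(np.median(np.diff(zc))) if len(zc) > 1 else float("inf")
    mask = brute_force_mask(
        contours, grid.x_centers().tolist(), grid.y_centers().tolist(), zc, z_tol
    )
    dz = float(np.median(np.diff(zc))) if len(zc) > 1 else 1.0
    vv = grid.spacing[0] * grid.spacing[1] * dz
    return brute_force_dvh(mask, grid.values.tolist(), vv, dose_points)


class TestRasterize:
    def test_box_volume_within_one_voxel_layer(self, box_structure, uniform_grid):
        mask = rasterize(box_structure, uniform_grid)
        face_layer = 20.0 * 20.0 * 1.0  # one voxel layer per face, mm^3
        assert abs(mask.volume_mm3 - 8000.0) <= 6 * face_layer

    def test_box_matches_brute_force_mask(self, box_structure, uniform_grid):
        mask = rasterize(box_structure, uniform_grid)
        (v_curve, total) = _oracle_mask_and_dvh(box_structure, uniform_grid, [0.0])
        assert mask.volume_mm3 == pytest.approx(total, abs=1e-9)

    def test_annulus_even_odd_rule(self):
        outer = np.array([[-10, -10, 0], [10, -10, 0], [10, 10, 0], [-10, 10, 0.0]])
        inner = np.array([[-5, -5, 0], [5, -5, 0], [5, 5, 0], [-5, 5, 0.0]])
        annulus = Structure("Ring", 1, [outer, inner])
        grid = make_dose_grid(DoseFieldSpec("UNIFORM", {"level": 1.0}),
                              (-12.25, -12.25, 0.0), (0.5, 0.5), (1, 50, 50),
                              z_spacing=1.0)
        mask = rasterize(annulus, grid)
        xs, ys = grid.x_centers(), grid.y_centers()
        strictly_inside = (np.abs(xs[None, :]) < 5 - 0.25) & (np.abs(ys[:, None]) < 5 - 0.25)
        assert np.all(mask.occupancy[0][strictly_inside] == 0.0)
        outside_ring = (np.abs(xs[None, :]) > 10.25) | (np.abs(ys[:, None]) > 10.25)
        assert np.all(mask.occupancy[0][outside_ring] == 0.0)
        in_ring = (np.abs(xs[None, :]) > 5.25) & (np.abs(xs[None, :]) < 9.75) \
            & (np.abs(ys[:, None]) < 9.75)
        assert np.all(mask.occupancy[0][in_ring & ~outside_ring] == 1.0)

    def test_sphere_volume_converges_at_supersample_4(self):
        sphere = make_structure(PhantomSpec("SPHERE", (0, 0, 0), (10.0,), 1.0))
        grid = make_dose_grid(DoseFieldSpec("UNIFORM", {"level": 1.0}),
                              (-14.0, -14.0, -9.5), (1.0, 1.0), (20, 29, 29),
                              z_spacing=1.0)
        mask = rasterize(sphere, grid, supersample=4)
        analytic = sphere.meta["analytic_volume_mm3"]
        assert abs(mask.volume_mm3 - analytic) / analytic < 0.02

    def test_contour_off_grid_raises(self, box_structure):
        grid = make_dose_grid(DoseFieldSpec("UNIFORM", {"level": 1.0}),
                              (0, 0, 100.0), (1, 1), (3, 5, 5), z_spacing=2.0)
        with pytest.raises(OutOfGridError):
            rasterize(box_structure, grid)

    def test_zero_occupancy_is_degenerate(self):
        tiny = Structure("T", 1, [np.array([[50, 50, 0], [50.1, 50, 0],
                                            [50.1, 50.1, 0.0]])])
        grid = make_dose_grid(DoseFieldSpec("UNIFORM", {"level": 1.0}),
                              (0, 0, 0), (1, 1), (1, 5, 5), z_spacing=1.0)
        with pytest.raises(DegenerateStructureError):
            rasterize(tiny, grid)


class TestComputeDvh:
    def test_uniform_field_step_function(self, box_structure, uniform_grid):
        mask = rasterize(box_structure, uniform_grid)
        curve = compute_dvh(mask, uniform_grid)
        at = lambda d: np.interp(d, curve.dose_edges, curve.cum_volume_pct)
        assert at(0.0) == 100.0
        assert at(19.99) == 100.0
        assert at(20.01) == 0.0
        assert evaluate_metric(curve, parse_metric("Dmean")) == pytest.approx(20.0)

    def test_linear_gradient_dvh_is_linear(self):
        # box spanning x in [0, 20] under dose = 5 + 0.5 * x: V(d) falls
        # linearly from 100% at 5 Gy to 0% at 15 Gy
        box = make_structure(PhantomSpec("BOX", (10.0, 0, 0), (20, 10, 8), 2.0))
        grid = make_dose_grid(
            DoseFieldSpec("LINEAR_X", {"gradient": 0.5, "intercept": 5.0}),
            (-2.25, -7.25, -3.0), (0.5, 0.5), (4, 30, 50), z_spacing=2.0,
        )
        mask = rasterize(box, grid)
        curve = compute_dvh(mask, grid)
        layer_pct = 100.0 * grid.spacing[0] / 20.0  # one voxel column
        for d in np.arange(5.5, 14.51, 0.5):
            expected = 100.0 * (1 - (d - 5.0) / 10.0)
            got = float(np.interp(d, curve.dose_edges, curve.cum_volume_pct))
            assert abs(got - expected) <= layer_pct + 1e-9

    def test_volume_conservation_exact(self, box_structure, uniform_grid):
        mask = rasterize(box_structure, uniform_grid, supersample=2)
        curve = compute_dvh(mask, uniform_grid)
        assert curve.total_volume_cc * 1000.0 == pytest.approx(
            float((mask.occupancy * mask.voxel_volume).sum()), rel=1e-12
        )

    def test_monotone_non_increasing_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            structure, grid = random_phantom_and_field(rng)
            curve = compute_dvh(rasterize(structure, grid), grid)
            assert np.all(np.diff(curve.cum_volume_pct) <= 1e-12)
            assert curve.cum_volume_pct[0] == 100.0


class TestOracleEquivalence:
    def test_random_pairs_match_brute_force(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(20):
            structure, grid = random_phantom_and_field(rng)
            mask = rasterize(structure, grid, supersample=1)
            curve = compute_dvh(mask, grid)
            dmax = float(grid.values.max())
            points = np.linspace(0, dmax * 1.05, 25).tolist()
            expected, total = _oracle_mask_and_dvh(structure, grid, points)
            assert mask.volume_mm3 == pytest.approx(total, abs=1e-9)
            got = np.interp(points, curve.dose_edges, curve.cum_volume_pct)
            # compare on the exact distribution, not interpolated bins
            got_exact = [
                100.0 * float(curve.weights[curve.sorted_doses >= d].sum())
                / (curve.total_volume_cc * 1000.0)
                for d in points
            ]
            worst = max(worst, float(np.abs(np.array(got_exact) - expected).max()))
        assert worst <= 1e-9


def _two_atom_curve():
    return DVHCurve(
        structure_name="X",
        dose_edges=np.array([0.0]),
        cum_volume_pct=np.array([100.0]),
        total_volume_cc=0.002,
        sorted_doses=np.array([10.0, 30.0]),
        weights=np.array([1.0, 1.0]),
    )


class TestMetrics:
    def test_uniform_metrics(self, box_structure, uniform_grid):
        curve = compute_dvh(rasterize(box_structure, uniform_grid), uniform_grid)
        assert evaluate_metric(curve, parse_metric("D50%")) == pytest.approx(20.0)
        assert evaluate_metric(curve, parse_metric("V20Gy")) == pytest.approx(100.0)
        assert evaluate_metric(curve, parse_metric("V20.1Gy")) == 0.0
        assert evaluate_metric(curve, parse_metric("V0Gy")) == 100.0

    def test_two_atom_distribution_hand_enumerated(self):
        curve = _two_atom_curve()
        assert evaluate_metric(curve, parse_metric("Dmean")) == pytest.approx(20.0)
        # hottest 50% is exactly the 30 Gy half (step convention at boundary)
        assert evaluate_metric(curve, parse_metric("D50%")) == 30.0
        assert evaluate_metric(curve, parse_metric("D50.1%")) == 10.0
        assert evaluate_metric(curve, parse_metric("D100%")) == 10.0
        assert evaluate_metric(curve, parse_metric("Dmax")) == 30.0
        assert evaluate_metric(curve, parse_metric("Dmin")) == 10.0

    def test_dcc_converts_and_bounds(self):
        curve = _two_atom_curve()  # total 0.002 cc
        assert evaluate_metric(
            curve, parse_metric("D0.001cc")) == 30.0  # hottest half
        with pytest.raises(DomainError):
            evaluate_metric(curve, parse_metric("D5cc"))

    def test_metric_order_properties_random_cases(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            structure, grid = random_phantom_and_field(rng)
            curve = compute_dvh(rasterize(structure, grid), grid)
            dmin = evaluate_metric(curve, parse_metric("Dmin"))
            dmean = evaluate_metric(curve, parse_metric("Dmean"))
            dmax = evaluate_metric(curve, parse_metric("Dmax"))
            assert dmin <= dmean + 1e-12 <= dmax + 1e-12
            xs = [1, 5, 20, 50, 80, 99]
            dx = [evaluate_metric(curve, MetricSpec("D_PCT", x)) for x in xs]
            assert all(a >= b - 1e-12 for a, b in zip(dx, dx[1:]))
            vs = np.linspace(0, dmax * 1.1, 12)
            vg = [evaluate_metric(curve, MetricSpec("V_GY", v)) for v in vs]
            assert all(a >= b - 1e-12 for a, b in zip(vg, vg[1:]))

    @pytest.mark.parametrize("text,kind,arg", [
        ("D2%", "D_PCT", 2.0), ("V70Gy", "V_GY", 70.0),
        ("D0.03cc", "D_CC", 0.03), ("Dmean", "DMEAN", None),
    ])
    def test_parse_metric(self, text, kind, arg):
        spec = parse_metric(text)
        assert spec.kind == kind
        assert spec.argument == arg

    def test_parse_metric_rejects_garbage(self):
        with pytest.raises(DomainError):
            parse_metric("Q5x")
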