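import numpy as np
import pytest

from arcqa.detector_geometry import PhantomModel, radiological_depths
from arcqa.rt_io import read_dose, read_plan
from arcqa.synthetic_dose import (
    AngularResponse,
    BeamModel,
    RigidTransform,
    apply_misalignment,
    beam_axes,
    compute_dose_grid,
    compute_point_doses,
    diode_dose_from_center,
    generate_arc_plan,
    make_fixtures,
    plan_projections,
    read_readings,
    virtual_diode_readings,
)
from arcqa.qa_pipeline import _open_field_projection


WATER = PhantomModel(shell_density=1.0, plug_present=True, plug_density=1.0,
                     cavity_density=1.0, exterior_density=1.0)


class TestBeamModel:
    def test_tmr_is_one_at_dmax(self):
        for energy in ("6X", "10X"):
            beam = BeamModel.for_energy(energy)
            assert beam.tmr(beam.dmax) == pytest.approx(1.0)

    def test_tmr_nonincreasing_beyond_dmax(self, beam_6x):
        d = np.linspace(beam_6x.dmax, 40, 200)
        t = beam_6x.tmr(d)
        assert np.all(np.diff(t) <= 0)

    def test_tabulated_tmr(self):
        table = (np.array([0.0, 1.5, 10.0, 20.0]),
                 np.array([0.5, 1.0, 0.7, 0.45]))
        beam = BeamModel(tmr_table=table)
        assert beam.tmr(1.5) == pytest.approx(1.0)
        assert beam.tmr(15.0) == pytest.approx(0.575)

    def test_default_calibration_one_cgy_per_mu(self, beam_6x):
        assert beam_6x.calibration == 1.0
        assert beam_6x.source_axis_distance == 100.0


class TestDiodeDoseFromCenter:
    def test_inverse_square_only_entrance_factor(self, layout):
        # attenuation disabled: entrance diode at 89.5 cm from the source
        beam = BeamModel.no_attenuation()
        res = diode_dose_from_center(100.0, beam, WATER, layout, 0.0)
        k = int(np.argmin(np.linalg.norm(
            layout.positions - np.array([0.0, 10.5, 0.0]), axis=1)))
        r = np.linalg.norm(layout.positions[k] - np.array([0.0, 100.0, 0.0]))
        assert res.dose[k] == pytest.approx(100.0 * (100.0 / r) ** 2, rel=1e-12)
        assert r == pytest.approx(89.5, abs=0.02)

    def test_entrance_factor_formula(self, layout, beam_6x, phantom):
        res = diode_dose_from_center(50.0, beam_6x, phantom, layout, 0.0)
        src = np.array([0.0, 100.0, 0.0])
        k = int(np.argmin(np.linalg.norm(
            layout.positions - np.array([0.0, 10.5, 0.0]), axis=1)))
        p = layout.positions[k]
        d_diode = radiological_depths(phantom, src, p[None, :])[0]
        d_center = radiological_depths(phantom, src, np.zeros((1, 3)))[0]
        r = np.linalg.norm(p - src)
        want = 50.0 * beam_6x.tmr(d_diode) / beam_6x.tmr(d_center) \
            * (100.0 / r) ** 2
        assert res.dose[k] == pytest.approx(float(want), rel=1e-12)

    def test_plug_effect_matches_path_length_oracle(self, layout, beam_6x):
        with_plug = PhantomModel(plug_present=True)
        without = PhantomModel(plug_present=False)
        src = np.array([0.0, 100.0, 0.0])
        k = int(np.argmin(np.linalg.norm(
            layout.positions - np.array([0.0, -10.5, 0.0]), axis=1)))
        p = layout.positions[k]
        r1 = diode_dose_from_center(100.0, beam_6x, with_plug, layout, 0.0)
        r2 = diode_dose_from_center(100.0, beam_6x, without, layout, 0.0)
        # step-wise numerical path integration oracle for the depth change
        steps = np.linspace(0, 1, 200001)
        seg = src + steps[:, None] * (p - src)
        rr = np.linalg.norm(seg[:, :2], axis=1)
        length = np.linalg.norm(p - src) / (steps.size - 1)
        chord = np.sum(rr < 7.5) * length
        d1 = radiological_depths(with_plug, src, p[None, :])[0]
        d2 = radiological_depths(without, src, p[None, :])[0]
        assert d1 - d2 == pytest.approx(
            chord * (with_plug.plug_density - without.cavity_density),
            abs=2e-3)
        # and the dose-factor ratio is the TMR ratio at those depths (both
        # renormalised by their own centre depth, which also changes)
        c1 = radiological_depths(with_plug, src, np.zeros((1, 3)))[0]
        c2 = radiological_depths(without, src, np.zeros((1, 3)))[0]
        want = (beam_6x.tmr(d1) / beam_6x.tmr(np.array(c1))) \
            / (beam_6x.tmr(d2) / beam_6x.tmr(np.array(c2)))
        assert r1.dose[k] / r2.dose[k] == pytest.approx(float(want), rel=1e-12)

    def test_out_of_beam_diodes_flagged(self, layout, beam_6x, phantom):
        res = diode_dose_from_center(100.0, beam_6x, phantom, layout, 0.0,
                                     field_size=10.0)
        assert np.any(~res.in_beam)
        assert np.all(np.isnan(res.dose[~res.in_beam]))
        assert np.all(np.isfinite(res.dose[res.in_beam]))

    def test_entrance_exit_partition(self, layout, beam_6x, phantom):
        res = diode_dose_from_center(100.0, beam_6x, phantom, layout, 37.0)
        assert int(res.entrance.sum()) + int(res.exit.sum()) == layout.n_diodes


class TestComputePointDoses:
    def test_central_axis_ratio_closed_form(self, beam_6x):
        proj = _open_field_projection(10.0, 100.0, 0.0)
        src = np.array([0.0, 100.0, 0.0])
        pts = np.array([[0.0, 5.0, 0.0], [0.0, -5.0, 0.0]])
        doses = compute_point_doses(pts, [proj], beam_6x, WATER)
        d = radiological_depths(WATER, src, pts)
        isl = (np.linalg.norm(pts[0] - src) / np.linalg.norm(pts[1] - src)) ** 2
        want = beam_6x.tmr(d[0]) / beam_6x.tmr(d[1]) / isl
        assert doses[0] / doses[1] == pytest.approx(float(want), rel=1e-9)

    def test_zero_meterset_gives_zero_grid(self, beam_6x, phantom):
        proj = _open_field_projection(10.0, 0.0, 0.0)
        grid = compute_dose_grid([proj], beam_6x, phantom, grid_spacing=2.0,
                                 grid_extent=(12.0, 12.0, 8.0))
        assert np.all(grid.values == 0)

    def test_opposed_beams_symmetric(self, beam_6x, phantom):
        projs = [_open_field_projection(10.0, 50.0, 0.0),
                 _open_field_projection(10.0, 50.0, 180.0)]
        grid = compute_dose_grid(projs, beam_6x, phantom, grid_spacing=1.0,
                                 grid_extent=(10.0, 10.0, 6.0))
        flipped = grid.values[:, ::-1, :]
        assert np.max(np.abs(grid.values - flipped)) < 1e-9

    def test_mu_linearity_exact(self, beam_6x, phantom):
        p1 = _open_field_projection(10.0, 100.0, 0.0)
        p2 = _open_field_projection(10.0, 200.0, 0.0)
        pts = np.array([[0.0, 10.5, 0.0], [0.0, 0.0, 0.0], [1.0, -9.0, 2.0]])
        d1 = compute_point_doses(pts, [p1], beam_6x, phantom)
        d2 = compute_point_doses(pts, [p2], beam_6x, phantom)
        assert np.array_equal(d2, 2.0 * d1)

    def test_inverse_square_recovery_attenuation_off(self):
        beam = BeamModel.no_attenuation()
        proj = _open_field_projection(10.0, 100.0, 0.0)
        src = np.array([0.0, 100.0, 0.0])
        # points along the central ray, inside the open field
        rs = np.linspace(88.0, 112.0, 25)
        pts = src + np.outer(rs, np.array([0.0, -1.0, 0.0]))
        doses = compute_point_doses(pts, [proj], beam, WATER)
        scaled = doses * rs ** 2 / (100.0 ** 2 * 100.0)
        assert np.max(np.abs(scaled - 1.0)) < 1e-10

    def test_exit_dose_strictly_higher_without_plug(self, beam_6x, layout):
        proj = _open_field_projection(10.0, 100.0, 0.0)
        exit_point = np.array([[0.0, -10.5, 0.0]])
        with_plug = compute_point_doses(
            exit_point, [proj], beam_6x, PhantomModel(plug_present=True))
        without = compute_point_doses(
            exit_point, [proj], beam_6x, PhantomModel(plug_present=False))
        assert without[0] > with_plug[0]

    def test_attenuation_coefficient_recovery(self, beam_6x, phantom):
        # fit an exponential slope to engine central-axis data: recovers the
        # configured attenuation coefficient within 1%
        proj = _open_field_projection(10.0, 100.0, 0.0)
        src = np.array([0.0, 100.0, 0.0])
        rs = np.linspace(92.0, 110.0, 40)
        pts = src + np.outer(rs, np.array([0.0, -1.0, 0.0]))
        doses = compute_point_doses(pts, [proj], beam_6x, phantom)
        deff = radiological_depths(phantom, src, pts)
        keep = deff > beam_6x.dmax + 0.5
        slope = np.polyfit(deff[keep],
                           np.log(doses[keep] * rs[keep] ** 2), 1)[0]
        assert -slope == pytest.approx(beam_6x.mu_attenuation, rel=0.01)


class TestVirtualDiodeReadings:
    def test_perfect_correction_recovers_plain_interpolation(self, layout,
                                                             beam_6x, phantom):
        proj = _open_field_projection(10.0, 100.0, 90.0)
        dose = compute_point_doses(layout.positions, [proj], beam_6x, phantom)
        _, _, _, src = beam_axes(90.0)
        angular = AngularResponse(enabled=True, correction_enabled=True)
        readings = virtual_diode_readings(dose, layout, source=src,
                                          angular=angular)
        assert np.allclose(readings, dose, rtol=1e-14)

    def test_deviation_bounded_by_amplitude(self, layout, beam_6x, phantom):
        proj = _open_field_projection(10.0, 100.0, 90.0, couch=40.0)
        dose = compute_point_doses(layout.positions, [proj], beam_6x, phantom)
        _, _, _, src = beam_axes(90.0, 40.0)
        angular = AngularResponse(amplitude=0.08, enabled=True,
                                  correction_enabled=False)
        readings = virtual_diode_readings(dose, layout, source=src,
                                          angular=angular)
        nonzero = dose > 0
        rel = readings[nonzero] / dose[nonzero]
        assert np.all(rel <= 1.0 + 1e-12)
        assert np.all(rel >= 1.0 - 0.08 - 1e-12)

    def test_noise_reproducible_with_fixed_seed(self, layout, beam_6x,
                                                phantom):
        proj = _open_field_projection(10.0, 100.0, 0.0)
        dose = compute_point_doses(layout.positions, [proj], beam_6x, phantom)
        r1 = virtual_diode_readings(dose, layout, noise_sd=0.01, seed=42)
        r2 = virtual_diode_readings(dose, layout, noise_sd=0.01, seed=42)
        assert np.array_equal(r1, r2)
        r3 = virtual_diode_readings(dose, layout, noise_sd=0.01, seed=43)
        assert not np.array_equal(r1, r3)

    def test_noise_without_seed_rejected(self, layout):
        with pytest.raises(ValueError, match="seed"):
            virtual_diode_readings(np.ones(layout.n_diodes), layout,
                                   noise_sd=0.01)

    def test_grid_interpolation_path(self, layout, beam_6x, phantom):
        proj = _open_field_projection(10.0, 100.0, 0.0)
        grid = compute_dose_grid([proj], beam_6x, phantom, grid_spacing=1.0,
                                 grid_extent=(26.0, 26.0, 24.0))
        readings = virtual_diode_readings(grid, layout)
        assert readings.shape == (layout.n_diodes,)
        assert np.allclose(readings, grid.interpolate(layout.positions) * 100)


class TestRigidTransform:
    def test_zero_transform_is_identity(self, layout):
        tr = RigidTransform()
        assert tr.is_identity
        assert np.array_equal(apply_misalignment(tr, layout),
                              layout.positions)

    def test_rotation_inverse_composes_to_identity(self, layout):
        for axis in ("cylinder", "vertical"):
            tr = RigidTransform(translation=(0.3, -0.2, 0.5),
                                rotation_deg=17.0, axis=axis)
            pts = apply_misalignment(tr, layout)
            back = tr.inverse().apply(pts)
            assert np.max(np.abs(back - layout.positions)) < 1e-12

    def test_one_cm_ap_shift(self, layout):
        tr = RigidTransform(translation=(1.0, 0.0, 0.0))
        moved = apply_misalignment(tr, layout)
        delta = moved - layout.positions
        assert np.allclose(delta[:, 1], 1.0)      # AP is the y axis
        assert np.allclose(delta[:, [0, 2]], 0.0)

    def test_rotation_range_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation_deg=200.0)

    def test_cylinder_rotation_preserves_radius_and_z(self, layout):
        tr = RigidTransform(rotation_deg=3.0)
        moved = apply_misalignment(tr, layout)
        assert np.allclose(np.linalg.norm(moved[:, :2], axis=1), 10.5)
        assert np.allclose(moved[:, 2], layout.positions[:, 2])


class TestMakeFixtures:
    def test_open_fixture_parses_and_is_consistent(self, tmp_path):
        spec = {"pattern": "open", "n_control_points": 177, "mu": 100.0}
        paths = make_fixtures(spec, seed=0, out_dir=tmp_path / "f")
        plan = read_plan(paths["plan"])
        assert len(plan.beams[0].control_points) == 177
        mlc0 = plan.beams[0].control_points[0].mlc_positions
        for cp in plan.beams[0].control_points:
            assert np.allclose(cp.mlc_positions, mlc0, atol=1e-4)
        grid = read_dose(paths["dose"])
        readings, chamber = read_readings(paths["readings"])
        assert readings.size == 1386
        assert chamber is not None and chamber > 0
        assert np.all(grid.values >= 0)

    def test_same_spec_and_seed_byte_identical(self, tmp_path):
        spec = {"pattern": "multiseg", "n_control_points": 25}
        p1 = make_fixtures(spec, seed=4, out_dir=tmp_path / "a")
        p2 = make_fixtures(spec, seed=4, out_dir=tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_modulated_fixture_has_varying_apertures(self, tmp_path):
        spec = {"pattern": "multiseg", "n_control_points": 25,
                "grid_spacing": 2.0, "grid_extent": (28.0, 28.0, 24.0)}
        paths = make_fixtures(spec, seed=9, out_dir=tmp_path / "m")
        plan = read_plan(paths["plan"])
        cps = plan.beams[0].control_points
        assert any(not np.allclose(cps[0].mlc_positions, cp.mlc_positions,
                                   atol=1e-3) for cp in cps[1:])
        w = np.array([cp.cumulative_weight for cp in cps])
        assert w[0] == 0.0 and w[-1] == 1.0 and np.all(np.diff(w) >= 0)


class TestPlanProjections:
    def test_projection_meterset_conserved(self):
        plan = generate_arc_plan(pattern="wedge", n_control_points=25,
                                 mu=150.0)
        projs = plan_projections(plan, angular_bin=30.0)
        assert sum(p.fluence.meterset for p in projs) == \
            pytest.approx(150.0, rel=1e-9)
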