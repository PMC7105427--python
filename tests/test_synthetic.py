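"""Generators against their closed forms: tube area, Poiseuille WSS,
prescribed OSI, Laplace-law stress, seeded perturbations, anastomosis labels."""

import numpy as np
import pytest

from graftmetrics import (
    CycleWindow,
    FluidSpec,
    TubeSpec,
    WaveformSpec,
    compute_osi,
    disturbed_velocity_series,
    make_anastomosis_surface,
    make_tube_surface,
    perturbation_rms,
    poiseuille_wss_series,
    prescribed_osi_wss_series,
    pressurised_tube_stress_series,
    von_mises,
    FieldSeries,
)


class TestTubeSurface:
    def test_area_matches_cylinder(self):
        spec = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=64, n_axial=40)
        mesh, _ = make_tube_surface(spec)
        analytic = 2 * np.pi * 3e-3 * 0.03
        assert mesh.total_area == pytest.approx(analytic, rel=5e-3)

    def test_refinement_reduces_area_error(self):
        analytic = 2 * np.pi * 3e-3 * 0.03
        errors = []
        for nc in (8, 16, 32, 64):
            spec = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=nc, n_axial=10)
            mesh, _ = make_tube_surface(spec)
            errors.append(abs(mesh.total_area - analytic))
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))

    def test_centreline_spans_length(self):
        spec = TubeSpec(3e-3, 0.03, 0.63e-3)
        _, cl = make_tube_surface(spec)
        assert cl.length == pytest.approx(0.03)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TubeSpec(-1.0, 0.03, 1e-3)
        with pytest.raises(ValueError):
            TubeSpec(3e-3, 0.03, 1e-3, n_circ=4)


class TestPoiseuilleWss:
    def test_steady_closed_form(self):
        # 600 ml/min through a 6 mm tube: |tau| = 4 mu Q / (pi r^3)
        spec = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=16, n_axial=8)
        wave = WaveformSpec(mean_flow=1e-5, period_T=1.0, harmonics=())
        mesh, series = poiseuille_wss_series(spec, wave, FluidSpec(), n_samples=9)
        expected = 4 * 4.5e-3 * 1e-5 / (np.pi * (3e-3) ** 3)
        assert expected == pytest.approx(2.122, abs=5e-4)  # hand evaluation
        np.testing.assert_allclose(series.magnitude(), expected, rtol=1e-12)

    def test_steady_flow_osi_zero(self):
        spec = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=16, n_axial=4)
        wave = WaveformSpec(mean_flow=1e-5, period_T=1.0, harmonics=())
        _, series = poiseuille_wss_series(spec, wave, n_samples=17)
        osi = compute_osi(series, series.window)
        np.testing.assert_allclose(osi.values, 0.0, atol=1e-12)

    def test_linearity_in_flow(self):
        spec = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=16, n_axial=4)
        w1 = WaveformSpec(mean_flow=1e-5, harmonics=())
        w2 = WaveformSpec(mean_flow=2e-5, harmonics=())
        _, s1 = poiseuille_wss_series(spec, w1, n_samples=9)
        _, s2 = poiseuille_wss_series(spec, w2, n_samples=9)
        np.testing.assert_allclose(s2.values, 2 * s1.values, rtol=1e-12)

    def test_retrograde_waveform_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            WaveformSpec(mean_flow=1e-6, harmonics=((5e-6, 0.0),))


class TestPrescribedOsi:
    @pytest.mark.parametrize("target", [0.0, 0.1, 0.25, 0.4, 0.5])
    def test_round_trip_through_metric(self, target):
        window = CycleWindow.uniform(1.0, 64)
        series = prescribed_osi_wss_series(target, 2.0, window)
        osi = compute_osi(series, series.window).values
        np.testing.assert_allclose(osi, target, atol=1e-6)

    def test_target_zero_is_steady_forward(self):
        window = CycleWindow.uniform(1.0, 64)
        series = prescribed_osi_wss_series(0.0, 2.0, window)
        assert np.all(series.values[:, :, 0] == 2.0)

    def test_target_half_has_zero_time_integral(self):
        window = CycleWindow.uniform(1.0, 64)
        series = prescribed_osi_wss_series(0.5, 2.0, window)
        w = series.window.trapezoid_weights()
        integral = np.einsum("t,tec->ec", w, series.values)
        np.testing.assert_allclose(integral, 0.0, atol=1e-12)

    def test_out_of_range_target_rejected(self):
        window = CycleWindow.uniform(1.0, 64)
        with pytest.raises(ValueError):
            prescribed_osi_wss_series(0.6, 1.0, window)


class TestPressurisedTube:
    def test_laplace_hoop_stress_value(self):
        # vein at 50 mmHg: sigma_theta = p r / h
        p = 50 * 133.322
        spec = TubeSpec(3.57e-3, 0.02, 0.357e-3, n_circ=16, n_axial=4)
        window = CycleWindow.uniform(1.0, 3)
        mesh, stress, areas = pressurised_tube_stress_series(
            spec, np.full(3, p), window
        )
        expected_hoop = p * 3.57e-3 / 0.357e-3
        assert expected_hoop == pytest.approx(66661.0, rel=1e-4)  # hand evaluation
        # principal stresses of the generated tensor: hoop, axial, ~0
        v = stress.values[0, 0]
        T = np.array(
            [[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]]
        )
        eig = np.sort(np.linalg.eigvalsh(T))
        assert eig[2] == pytest.approx(expected_hoop, rel=1e-9)
        assert eig[1] == pytest.approx(expected_hoop / 2, rel=1e-9)
        assert eig[0] == pytest.approx(0.0, abs=1e-6)

    def test_zero_pressure_gives_zero_state(self):
        spec = TubeSpec(3.57e-3, 0.02, 0.357e-3, n_circ=16, n_axial=4)
        window = CycleWindow.uniform(1.0, 3)
        _, stress, areas = pressurised_tube_stress_series(
            spec, np.zeros(3), window, youngs_modulus=0.445e6
        )
        np.testing.assert_allclose(stress.values, 0.0)
        np.testing.assert_allclose(areas.An, np.tile(areas.A0, (3, 1)))

    def test_von_mises_matches_plane_stress_identity(self):
        # closed form sqrt(s_th^2 + s_z^2 - s_th s_z) with s_r = 0
        p = 40 * 133.322
        spec = TubeSpec(3e-3, 0.02, 0.3e-3, n_circ=16, n_axial=4)
        window = CycleWindow.uniform(1.0, 3)
        _, stress, _ = pressurised_tube_stress_series(spec, np.full(3, p), window)
        s_th = p * 3e-3 / 0.3e-3
        s_z = s_th / 2
        expected = np.sqrt(s_th**2 + s_z**2 - s_th * s_z)
        vm = von_mises(stress)
        np.testing.assert_allclose(vm.values, expected, rtol=1e-9)

    def test_positive_semidefinite_for_positive_pressure(self):
        spec = TubeSpec(3e-3, 0.02, 0.3e-3, n_circ=12, n_axial=3)
        window = CycleWindow.uniform(1.0, 3)
        _, stress, _ = pressurised_tube_stress_series(
            spec, np.array([0.0, 5000.0, 1000.0]), window
        )
        v = stress.values
        for ti in range(3):
            for ei in range(0, v.shape[1], 7):
                c = v[ti, ei]
                T = np.array(
                    [[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]]
                )
                assert np.linalg.eigvalsh(T).min() >= -1e-6

    def test_thick_wall_warns(self):
        spec = TubeSpec(1e-3, 0.01, 0.5e-3, n_circ=8, n_axial=2)
        window = CycleWindow.uniform(1.0, 3)
        with pytest.warns(UserWarning, match="thin-wall"):
            pressurised_tube_stress_series(spec, np.zeros(3), window)


class TestDisturbedVelocity:
    def _base(self, n_pts=50, n_t=257):
        window = CycleWindow.uniform(1.0, n_t)
        vals = np.ones((n_t, n_pts, 1))
        return FieldSeries(
            kind="scalar", attachment="node", values=vals, units="m/s", window=window
        )

    def test_rms_of_injected_sinusoid(self):
        base = self._base()
        eps = 0.05
        s = disturbed_velocity_series(base, eps, 32.0, seed=1)
        pert = FieldSeries(
            kind="scalar",
            attachment="node",
            values=s.values - base.values,
            units="m/s",
            window=base.window,
        )
        rms = perturbation_rms(pert, base.window)
        np.testing.assert_allclose(rms.values, eps / np.sqrt(2), rtol=0.01)

    def test_zero_amplitude(self):
        base = self._base()
        s = disturbed_velocity_series(base, 0.0, 32.0, seed=1)
        np.testing.assert_allclose(s.values, base.values)

    def test_same_seed_reproducible(self):
        base = self._base()
        s1 = disturbed_velocity_series(base, 0.05, 32.0, seed=9)
        s2 = disturbed_velocity_series(base, 0.05, 32.0, seed=9)
        np.testing.assert_array_equal(s1.values, s2.values)
        s3 = disturbed_velocity_series(base, 0.05, 32.0, seed=10)
        assert not np.array_equal(s1.values, s3.values)

    def test_frequency_below_cutoff_rejected(self):
        base = self._base()
        with pytest.raises(ValueError, match="cutoff"):
            disturbed_velocity_series(base, 0.05, 5.0, seed=1)


@pytest.fixture(scope="module")
def model():
    graft = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=16, n_axial=12)
    vein = TubeSpec(3.57e-3, 0.075, 0.357e-3, n_circ=16, n_axial=24)
    return make_anastomosis_surface(graft, vein)


class TestAnastomosis:
    def test_graft_and_vein_partition_surface(self, model):
        a_graft = model.regions["graft"].total_area
        a_vein = model.regions["vein"].total_area
        assert a_graft + a_vein == pytest.approx(model.mesh.total_area, rel=1e-12)
        ids = np.concatenate(
            [model.regions["graft"].element_ids, model.regions["vein"].element_ids]
        )
        assert len(np.unique(ids)) == model.mesh.n_elements

    def test_anastomosis_mask_matches_sphere_roi(self, model):
        from graftmetrics import SphereROI, sphere_region

        roi_mask = sphere_region(model.mesh, SphereROI(center=tuple(model.junction)))
        np.testing.assert_array_equal(
            roi_mask.element_ids, model.regions["anastomosis"].element_ids
        )

    def test_degenerate_angle_rejected(self):
        graft = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=8, n_axial=2)
        vein = TubeSpec(3.57e-3, 0.075, 0.357e-3, n_circ=8, n_axial=3)
        with pytest.raises(ValueError, match="angle"):
            make_anastomosis_surface(graft, vein, angle=0.0)

    def test_centreline_has_transition_landmark(self, model):
        assert "transition" in model.centreline.landmarks
        s = model.centreline.landmarks["transition"]
        assert 0 < s < model.centreline.length
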