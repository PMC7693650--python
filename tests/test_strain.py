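import numpy as np
import pytest

from cardiostrain.geometry import DynamicLVMesh, compute_local_frames
from cardiostrain.phantom import ClassPhenotype, simulate_subject
from cardiostrain.strain import (
    COMBOS,
    StrainSeries,
    deformation_gradient,
    directional_strain,
    global_longitudinal_shortening,
    green_lagrange,
    principal_strains,
    strain_time_series,
    surface_deformation_gradient,
    temporal_metrics,
)


def _unit_hex():
    corners = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
        dtype=float,
    )
    return corners


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestDeformationGradient:
    def test_translation_gives_identity(self):
        ref = _unit_hex()
        f = deformation_gradient(ref, ref + np.array([3.0, -2.0, 0.5]))
        assert np.allclose(f, np.eye(3), atol=1e-12)

    def test_affine_map_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        ref = _unit_hex() + 0.1 * rng.normal(size=(8, 3))
        a = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        while np.linalg.det(a) <= 0:
            a = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        f = deformation_gradient(ref, ref @ a.T)
        assert np.allclose(f, a, atol=1e-10)

    def test_smooth_warp_matches_finite_differences(self):
        # warp phi(x) = x + 0.05 sin-type perturbation; compare centroid F
        # against central finite differences of phi at the centroid
        def phi(x):
            return x + 0.05 * np.stack(
                [np.sin(x[..., 1]), np.cos(x[..., 2]), np.sin(x[..., 0] + x[..., 1])], axis=-1
            )

        ref = 0.08 * _unit_hex()  # small element keeps trilinear error tiny
        f = deformation_gradient(ref, phi(ref))
        c = ref.mean(axis=0)
        h = 1e-5
        fd = np.empty((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fd[:, j] = (phi(c + e) - phi(c - e)) / (2 * h)
        assert np.allclose(f, fd, atol=1e-4)

    def test_singular_reference_rejected(self):
        ref = _unit_hex()
        ref[:, 2] = 0.0  # flat element
        with pytest.raises(ValueError, match="singular"):
            deformation_gradient(ref, ref)


class TestSurfaceDeformationGradient:
    quad = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)

    def test_isotropic_in_plane_scale(self):
        f = surface_deformation_gradient(self.quad, 0.9 * self.quad)
        assert np.allclose(f, 0.9 * np.eye(2), atol=1e-10)

    def test_rigid_rotation_leaves_metric_identity(self):
        rot = _rotation([1, 2, 3], 0.8)
        f = surface_deformation_gradient(self.quad, self.quad @ rot.T)
        assert np.allclose(f.T @ f, np.eye(2), atol=1e-10)

    def test_in_plane_affine_metric_recovered(self):
        rng = np.random.default_rng(1)
        m = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
        while np.linalg.det(m) <= 0:
            m = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
        deformed = self.quad.copy()
        deformed[:, :2] = self.quad[:, :2] @ m.T
        f = surface_deformation_gradient(self.quad, deformed)
        assert np.allclose(f.T @ f, m.T @ m, atol=1e-8)

    def test_degenerate_quad_rejected(self):
        bad = np.zeros((4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            surface_deformation_gradient(bad, bad)


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        assert np.allclose(green_lagrange(np.eye(3)), 0.0)

    def test_uniaxial_closed_form(self):
        e = green_lagrange(np.diag([0.8, 1.0, 1.0]))
        expected = np.zeros((3, 3))
        expected[0, 0] = (0.64 - 1.0) / 2.0
        assert np.allclose(e, expected, atol=1e-14)

    def test_objectivity_under_rotation(self):
        rot = _rotation([0.3, -1, 2], 1.1)
        assert np.allclose(green_lagrange(rot), 0.0, atol=1e-12)


class TestDirectionalStrain:
    def test_zero_strain_any_direction(self):
        d = np.array([0.6, 0.8, 0.0])
        assert directional_strain(np.zeros((3, 3)), d) == pytest.approx(0.0)

    def test_uniaxial_compression_is_minus_twenty_percent(self):
        e = green_lagrange(np.diag([0.8, 1.0, 1.0]))
        assert directional_strain(e, np.array([1.0, 0, 0])) == pytest.approx(-20.0, abs=1e-10)

    def test_matches_fiber_transform_oracle(self):
        # transform a fiber with any F satisfying F^T F = I + 2E and compare
        # its length change with the directional strain
        rng = np.random.default_rng(2)
        for _ in range(20):
            f = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
            if np.linalg.det(f) <= 0.2:
                continue
            e = green_lagrange(f)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            fiber = 100.0 * (np.linalg.norm(f @ d) - 1.0)
            assert directional_strain(e, d) == pytest.approx(fiber, abs=1e-9)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            directional_strain(np.zeros((3, 3)), np.array([1.0, 1.0, 0.0]))


class TestPrincipalStrains:
    def test_diagonal_stretch_closed_form(self):
        e = green_lagrange(np.diag([0.8, 0.9, 1.4]))
        mn, mx, _ = principal_strains(e)
        assert mn == pytest.approx(-20.0, abs=1e-10)
        assert mx == pytest.approx(40.0, abs=1e-10)

    def test_rigid_rotation_gives_zero(self):
        e = green_lagrange(_rotation([1, 1, 1], 0.9))
        mn, mx, _ = principal_strains(e)
        assert abs(mn) < 1e-10 and abs(mx) < 1e-10

    def test_bounds_dominate_directional_strains(self):
        rng = np.random.default_rng(3)
        f = np.eye(3) + 0.25 * rng.normal(size=(3, 3))
        e = green_lagrange(f)
        mn, mx, _ = principal_strains(e)
        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            s = directional_strain(e, d)
            assert mn - 1e-9 <= s <= mx + 1e-9

    def test_eigenvector_sign_convention(self):
        e = green_lagrange(np.diag([0.8, 0.9, 1.4]))
        _, _, vecs = principal_strains(e)
        for col in range(3):
            first_nonzero = vecs[np.flatnonzero(np.abs(vecs[:, col]) > 1e-12)[0], col]
            assert first_nonzero > 0

    def test_asymmetric_tensor_rejected(self):
        e = np.array([[0.1, 0.05, 0], [0.0, 0.1, 0], [0, 0, 0.1]])
        with pytest.raises(ValueError, match="symmetric"):
            principal_strains(e)


class TestStrainTimeSeries:
    def test_rigid_body_motion_yields_zero_everywhere(self, ref_mesh, frames):
        n_ph = 8
        nodes = ref_mesh.all_nodes()
        disp = np.zeros((n_ph, nodes.shape[0], 3))
        for p in range(1, n_ph):
            rot = _rotation([0.2, 1, 0.5], 0.1 * p)
            disp[p] = nodes @ rot.T + np.array([2.0, 0.0, -1.0]) * p - nodes
        dyn = DynamicLVMesh(mesh=ref_mesh, displacements=disp, cycle_ms=1000.0)
        series = strain_time_series(dyn, frames)
        for combo in COMBOS:
            assert np.max(np.abs(series[combo])) < 1e-8

    def test_phase_zero_is_exactly_zero(self, quiet_series):
        for combo in COMBOS:
            assert np.all(quiet_series[combo][:, 0] == 0.0)

    def test_all_combos_match_generator_ground_truth(self, quiet_hcm_subject, quiet_series):
        gt = quiet_hcm_subject.ground_truth
        for combo in COMBOS:
            s = quiet_series.global_series(combo)
            shortening = combo[0] in ("circumferential", "longitudinal", "min_principal")
            measured = s.min() if shortening else s.max()
            assert measured == pytest.approx(gt.peak_amp(combo), abs=0.5), combo

    def test_recovery_error_decreases_under_mesh_refinement(self):
        from cardiostrain.geometry import LVGeometryConfig

        errs = []
        for n_circ, n_long in ((16, 9), (40, 23)):
            geo = LVGeometryConfig(n_circ=n_circ, n_long=n_long)
            ph = ClassPhenotype(label="X", amp_subendo_circ=-0.178, amp_subendo_long=-0.152,
                                t_peak_frac=0.414, thickness_base=10.0)
            rec = simulate_subject(ph, geo, np.random.default_rng(0), n_phases=12)
            fr = compute_local_frames(rec.mesh.mesh)
            series = strain_time_series(rec.mesh, fr)
            meas = series.global_series(("max_principal", "transmural")).max()
            errs.append(abs(meas - rec.ground_truth.peak_amp(("max_principal", "transmural"))))
        assert errs[1] < errs[0]

    def test_incompressible_principal_stretch_product(self, quiet_hcm_subject, frames):
        mesh = quiet_hcm_subject.mesh.mesh
        ref = mesh.element_corner_coords()
        for p in range(quiet_hcm_subject.mesh.n_phases):
            f3 = deformation_gradient(ref, mesh.element_corner_coords(quiet_hcm_subject.mesh.nodes_at_phase(p)))
            lam = np.sqrt(1.0 + 2.0 * np.linalg.eigvalsh(green_lagrange(f3)))
            assert np.max(np.abs(lam.prod(axis=1) - 1.0)) < 1e-3

    def test_layer_gradient_with_prescribed_ratio(self, geo_config):
        ph = ClassPhenotype(label="X", amp_subendo_circ=-0.178, amp_subendo_long=-0.152,
                            t_peak_frac=0.414, thickness_base=10.0, endo_epi_amp_ratio=2.6)
        rec = simulate_subject(ph, geo_config, np.random.default_rng(0), incompressible=False)
        fr = compute_local_frames(rec.mesh.mesh)
        series = strain_time_series(rec.mesh, fr)
        endo = abs(series.global_series(("circumferential", "subendocardial")).min())
        epi = abs(series.global_series(("circumferential", "subepicardial")).min())
        assert endo > epi
        assert endo / epi == pytest.approx(2.6, rel=0.1)


class TestTemporalMetrics:
    @staticmethod
    def _series_from(arr2d, cycle_ms=1000.0):
        n = np.asarray(arr2d)
        return StrainSeries(series={("circumferential", "transmural"): n}, cycle_ms=cycle_ms)

    def test_time_to_peak_from_phase_index(self):
        s = np.zeros((1, 30))
        s[0, 12] = -10.0
        m = temporal_metrics(self._series_from(s))
        assert m[("circumferential", "transmural")]["time_to_peak"][0] == pytest.approx(40.0)

    def test_linear_ramp_rate(self):
        s = np.linspace(0, -15, 30)[None, :]
        m = temporal_metrics(self._series_from(s))
        combo = ("circumferential", "transmural")
        # constant slope -15% over 1 s sampled at dt = 1/30 s
        assert m[combo]["peak_systolic_rate"][0] == pytest.approx(-15.0 / (29 / 30), rel=0.02)

    def test_raised_cosine_rate_matches_analytic_derivative(self):
        from cardiostrain.phantom import activation_waveform

        t = np.arange(30) / 30
        s = (-20.0 * activation_waveform(t, 0.4))[None, :]
        m = temporal_metrics(self._series_from(s))
        combo = ("circumferential", "transmural")
        # d/dt of -20 * 0.5(1 - cos(pi t / 0.4)) peaks at -20 * pi/(2*0.4) %/s
        analytic = -20.0 * np.pi / (2 * 0.4)
        assert m[combo]["peak_systolic_rate"][0] == pytest.approx(analytic, rel=0.05)
        assert m[combo]["peak_diastolic_rate"][0] > 0

    def test_all_zero_series_flags_zero_metrics(self):
        m = temporal_metrics(self._series_from(np.zeros((2, 30))))
        combo = ("circumferential", "transmural")
        for key in ("peak_amp", "time_to_peak", "peak_systolic_rate", "peak_diastolic_rate"):
            assert np.all(m[combo][key] == 0.0)

    def test_tie_breaks_to_earliest_phase(self):
        s = np.zeros((1, 10))
        s[0, [4, 7]] = -5.0
        m = temporal_metrics(self._series_from(s))
        assert m[("circumferential", "transmural")]["time_to_peak"][0] == pytest.approx(40.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_metrics(self._series_from(np.zeros((1, 2))))


class TestGlobalLongitudinalShortening:
    def test_matches_prescribed_longitudinal_amplitude(self, geo_config):
        ph = ClassPhenotype(label="X", amp_subendo_circ=-0.15, amp_subendo_long=-0.127,
                            t_peak_frac=0.4, thickness_base=10.0)
        rec = simulate_subject(ph, geo_config, np.random.default_rng(0))
        gls, series = global_longitudinal_shortening(rec.mesh)
        assert series[0] == 0.0
        assert gls == pytest.approx(-12.7, abs=0.1)
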