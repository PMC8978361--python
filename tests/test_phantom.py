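"""Phantom calibration, closed-form strain vs finite-difference oracle,
encoding determinism, and cohort generation."""

from dataclasses import replace

import numpy as np
import pytest

from cinedense import core, phantom


class TestCalibration:
    def test_zero_targets_give_identity_map(self):
        spec = phantom.calibrate_deformation(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
        assert spec.a_es == pytest.approx(1.0)
        assert spec.b_es_at(0.0) == pytest.approx(0.0, abs=1e-12)
        assert spec.lambda_l_es == pytest.approx(1.0)
        X = np.array([30.0, 0.0])
        np.testing.assert_allclose(
            phantom.analytic_displacement(spec, X, spec.t_es_ms, 0.0), [0.0, 0.0],
            atol=1e-12,
        )

    def test_transmural_means_hit_targets(self):
        spec = phantom.calibrate_deformation(-0.18, 0.35, -0.15, (0.0, 0.0, 0.0))
        # closed-form identity: area-weighted mean lambda_c^2 equals target
        for z in spec.sax_z:
            re_, rp = spec.radii_at(z)
            a, b = spec.a_es, spec.b_es_at(z)
            span = rp**2 - re_**2
            mean_lam2 = a**2 + (4 * a * b * (rp - re_) + 2 * b**2 * np.log(rp / re_)) / span
            assert 0.5 * (mean_lam2 - 1.0) == pytest.approx(-0.18, abs=1e-9)
        # independent dense-quadrature oracle
        ecc, err = phantom.analytic_mean_strains(spec, 0.0, spec.t_es_ms)
        assert ecc == pytest.approx(-0.18, abs=5e-4)
        assert err == pytest.approx(0.35, abs=1e-9)

    def test_ell_target_inverts_to_longitudinal_stretch(self):
        spec = phantom.calibrate_deformation(0.0, 0.0, -0.15, (0.0, 0.0, 0.0))
        assert spec.lambda_l_es == pytest.approx(np.sqrt(0.70))

    @pytest.mark.parametrize("targets", [(-0.6, 0.0), (0.0, -0.55)])
    def test_infeasible_targets_rejected(self, targets):
        ecc, err = targets
        with pytest.raises(phantom.InfeasibleTargetError):
            phantom.calibrate_deformation(ecc, err, 0.0, (0.0, 0.0, 0.0))

    def test_torsion_twist_prescription_is_linear_in_z(self):
        tw = phantom.twists_for_torsion((0.0, 25.0, 50.0), 2.79)
        slope = np.polyfit(np.array([0.0, 25.0, 50.0]) / 10.0, tw, 1)[0]
        assert slope == pytest.approx(2.79, abs=1e-12)


class TestClosedFormStrain:
    def test_quarter_rotation_displacement(self):
        spec = phantom.PhantomSpec(twists_es=(90.0, 90.0, 90.0))
        X = np.array([30.0, 0.0])
        u = phantom.analytic_displacement(spec, X, spec.t_es_ms, 0.0)
        np.testing.assert_allclose(u, [-30.0, 30.0], atol=1e-9)

    def test_uniform_scaling_strain(self):
        # a = 1.25, b = 0: Ecc = Err = (1.25^2 - 1)/2 = 0.28125 everywhere
        spec = phantom.PhantomSpec(a_es=1.25, target_mean_ecc=0.5 * (1.25**2 - 1))
        assert spec.b_es_at(0.0) == pytest.approx(0.0, abs=1e-9)
        X = np.array([[26.0, 3.0], [0.0, 34.0]])
        ecc, err = phantom.analytic_strain(spec, X, spec.t_es_ms, 0.0)
        np.testing.assert_allclose(ecc, 0.28125, atol=1e-9)
        np.testing.assert_allclose(err, 0.28125, atol=1e-9)

    def test_twist_contributes_no_inplane_strain(self):
        spec = phantom.calibrate_deformation(-0.18, 0.35, -0.15, (0.0, 0.0, 0.0))
        twisted = replace(spec, twists_es=(12.0, 12.0, 12.0))
        X = np.array([[28.0, 5.0], [-20.0, 20.0]])
        for t in (100.0, spec.t_es_ms):
            np.testing.assert_allclose(
                phantom.analytic_strain(spec, X, t, 25.0),
                phantom.analytic_strain(twisted, X, t, 25.0),
                atol=1e-12,
            )

    @pytest.mark.parametrize("septal_reduction", [0.0, 0.5])
    def test_strain_matches_finite_difference_oracle(self, septal_reduction):
        """Green-Lagrange strain from numerically differentiated displacement."""
        spec = phantom.calibrate_deformation(-0.18, 0.35, -0.15, (2.0, 5.0, 8.0))
        spec = replace(spec, septal_reduction=septal_reduction)
        t, z = 300.0, 0.0
        rng = np.random.default_rng(0)
        R = rng.uniform(26.0, 34.0, 40)
        TH = rng.uniform(-np.pi, np.pi, 40)
        X = np.stack([R * np.cos(TH), R * np.sin(TH)], axis=-1)
        h = 1e-5
        F = np.empty((len(X), 2, 2))
        for d in range(2):
            dX = np.zeros(2)
            dX[d] = h
            up = phantom.analytic_displacement(spec, X + dX, t, z) + dX
            dn = phantom.analytic_displacement(spec, X - dX, t, z) - dX
            F[:, :, d] = (up - dn) / (2 * h)
        E = 0.5 * (np.einsum("nji,njk->nik", F, F) - np.eye(2))
        e_r = X / np.linalg.norm(X, axis=1, keepdims=True)
        e_c = np.stack([-e_r[:, 1], e_r[:, 0]], axis=-1)
        ecc_fd = np.einsum("ni,nij,nj->n", e_c, E, e_c)
        err_fd = np.einsum("ni,nij,nj->n", e_r, E, e_r)
        ecc, err = phantom.analytic_strain(spec, X, t, z)
        np.testing.assert_allclose(ecc, ecc_fd, atol=1e-6)
        np.testing.assert_allclose(err, err_fd, atol=1e-6)

    def test_displacement_outside_annulus_rejected(self):
        spec = phantom.PhantomSpec()
        with pytest.raises(phantom.DomainError):
            phantom.analytic_displacement(spec, np.array([5.0, 0.0]), 100.0, 0.0)

    def test_septal_reduction_weakens_septal_strain(self):
        spec = phantom.calibrate_deformation(-0.18, 0.35, -0.15, (0.0, 0.0, 0.0))
        sick = replace(spec, septal_reduction=0.5)
        septal_dir = sick.septal_center_rad
        lateral_dir = septal_dir + np.pi
        Xs = 30.0 * np.array([np.cos(septal_dir), np.sin(septal_dir)])
        Xl = 30.0 * np.array([np.cos(lateral_dir), np.sin(lateral_dir)])
        ecc_s, _ = phantom.analytic_strain(sick, Xs, sick.t_es_ms, 0.0)
        ecc_l, _ = phantom.analytic_strain(sick, Xl, sick.t_es_ms, 0.0)
        assert abs(ecc_s) < abs(ecc_l)
        # the lateral wall is unaffected by the septal window
        ecc_ref, _ = phantom.analytic_strain(spec, Xl, spec.t_es_ms, 0.0)
        assert ecc_l == pytest.approx(ecc_ref, abs=1e-12)


class TestRendering:
    def test_same_seed_bit_identical(self, healthy_spec):
        spec = replace(healthy_spec, noise_sd=4.0, n_frames=4)
        s1, r1 = phantom.render_dense_series(spec, "SAX-mid", 3.4, seed=9)
        s2, r2 = phantom.render_dense_series(spec, "SAX-mid", 3.4, seed=9)
        np.testing.assert_array_equal(s1.phase_x, s2.phase_x)
        np.testing.assert_array_equal(s1.magnitude, s2.magnitude)
        np.testing.assert_array_equal(r1.mask, r2.mask)

    def test_different_seed_changes_noise_not_geometry(self, healthy_spec):
        spec = replace(healthy_spec, noise_sd=4.0, n_frames=4)
        s1, r1 = phantom.render_dense_series(spec, "SAX-mid", 3.4, seed=1)
        s2, r2 = phantom.render_dense_series(spec, "SAX-mid", 3.4, seed=2)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert not np.array_equal(s1.phase_x, s2.phase_x)

    def test_noise_free_phase_encodes_displacement(self, sax_renders_17, healthy_spec):
        from conftest import eulerian_truth

        series, roi = sax_renders_17["SAX-base"]
        k = 20
        ux, uy, m = eulerian_truth(healthy_spec, series, roi, k)
        ke = series.encoding_frequency
        np.testing.assert_allclose(
            series.phase_x[k][m], core.wrap_phase(2 * np.pi * ke * ux[m]), atol=1e-9
        )
        np.testing.assert_allclose(
            series.phase_y[k][m], core.wrap_phase(2 * np.pi * ke * uy[m]), atol=1e-9
        )

    def test_grid_too_small_rejected(self, healthy_spec):
        with pytest.raises(phantom.GeometryError):
            phantom.render_dense_series(healthy_spec, "SAX-base", 3.4, seed=0, fov_mm=60.0)


class TestCohort:
    def test_zero_noise_zero_offset_scans_identical(self, tmp_path):
        manifest = phantom.render_cohort(
            1, 0, tmp_path, seed=0, noise_sd=0.0, scanb_z_offset=0.0,
            views=("SAX-mid",), n_frames=4,
        )
        a = manifest[manifest.scan == "A"].iloc[0]
        b = manifest[manifest.scan == "B"].iloc[0]
        sa, _ = core.read_series(tmp_path / a.path)
        sb, _ = core.read_series(tmp_path / b.path)
        np.testing.assert_array_equal(sa.phase_x, sb.phase_x)
        np.testing.assert_array_equal(sa.magnitude, sb.magnitude)

    def test_prescribed_means_match_distribution(self, tmp_path):
        manifest = phantom.render_cohort(
            30, 0, tmp_path, seed=1, views=("SAX-mid",), n_frames=4
        )
        ecc = manifest[manifest.scan == "A"].prescribed_ecc
        se = 0.03 / np.sqrt(30)
        assert abs(ecc.mean() - (-0.18)) < 2 * se + 1e-12

    def test_patient_septal_prescription(self, tmp_path):
        manifest = phantom.render_cohort(
            0, 2, tmp_path, seed=2, views=("SAX-mid",), n_frames=4
        )
        assert (manifest.septal_reduction > 0).all()
        assert (manifest.group == "patient").all()

    def test_manifest_written(self, tmp_path):
        phantom.render_cohort(1, 0, tmp_path, seed=3, views=("SAX-mid",), n_frames=4)
        assert (tmp_path / "manifest.csv").exists()
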