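"""Deformation gradient, tensor projections, AHA bookkeeping, twist/torsion."""

import numpy as np
import pytest

from cinedense import phantom, strain
from cinedense.core import InputError
from cinedense.phase import MaterialTrajectories


def _grid_trajectories(map_fn, n=7, spacing=1.0, frames=2):
    idx = np.arange(n) * spacing
    xx, yy = np.meshgrid(idx, idx, indexing="xy")
    X = np.stack([xx.ravel(), yy.ravel()], axis=-1)
    x = np.stack([X] + [map_fn(X) for _ in range(frames - 1)])
    return MaterialTrajectories(
        X=X,
        x_raw=x,
        valid=np.ones((frames, len(X)), dtype=bool),
        seed_pixels=np.stack([yy.ravel(), xx.ravel()], axis=-1).astype(int),
        times_ms=np.arange(frames, dtype=float),
        pixel_spacing=spacing,
    )


class TestDeformationGradient:
    def test_static_points_give_identity(self):
        traj = _grid_trajectories(lambda X: X.copy())
        F, ok = strain.deformation_gradient(traj, 1)
        assert ok.all()
        np.testing.assert_allclose(F, np.tile(np.eye(2), (len(F), 1, 1)), atol=1e-10)

    def test_uniform_scaling(self):
        traj = _grid_trajectories(lambda X: 1.2 * X)
        F, ok = strain.deformation_gradient(traj, 1)
        np.testing.assert_allclose(F[ok], np.tile(1.2 * np.eye(2), (int(ok.sum()), 1, 1)), atol=1e-9)

    def test_collinear_neighbors_flagged_not_raised(self):
        X = np.stack([np.arange(5.0), np.zeros(5)], axis=-1)  # one straight line
        traj = MaterialTrajectories(
            X=X,
            x_raw=np.stack([X, X]),
            valid=np.ones((2, 5), dtype=bool),
            seed_pixels=np.zeros((5, 2), dtype=int),
            times_ms=np.array([0.0, 1.0]),
            pixel_spacing=1.0,
        )
        F, ok = strain.deformation_gradient(traj, 1)
        assert not ok.any()
        np.testing.assert_allclose(F, np.tile(np.eye(2), (5, 1, 1)))  # inert placeholder

    def test_phantom_stretches_recovered(self, base_analysis_1mm, healthy_spec):
        # componentwise agreement with the analytic lambda_r / lambda_c;
        # raw trajectories isolate the F fit from the temporal-fit bias
        from dataclasses import replace as dc_replace

        traj = dc_replace(base_analysis_1mm["traj"], x_fit=None)
        series = base_analysis_1mm["series"]
        center = base_analysis_1mm["center_mm"]
        k = 23
        F, ok = strain.deformation_gradient(traj, k)
        X = traj.X[ok] - center
        R = np.linalg.norm(X, axis=1)
        e_r = X / R[:, None]
        e_c = np.stack([-e_r[:, 1], e_r[:, 0]], axis=-1)
        lam_r = np.einsum("ni,nij,nj->n", e_r, F[ok], e_r)
        lam_c = np.einsum("ni,nij,nj->n", e_c, F[ok], e_c)
        s = float(healthy_spec.activation(series.trigger_times[k]))
        a_t = 1 + (healthy_spec.a_es - 1) * s
        b_t = healthy_spec.b_es_at(0.0) * s
        # F carries the rigid twist: e' F e = lambda * cos(psi) for both axes
        psi = np.deg2rad(healthy_spec.twist_es_at(0.0)) * s
        np.testing.assert_allclose(lam_r, a_t * np.cos(psi), atol=0.01)
        np.testing.assert_allclose(lam_c, (a_t + b_t / R) * np.cos(psi), atol=0.01)


class TestGreenStrain:
    def test_identity_and_diagonal(self):
        np.testing.assert_allclose(strain.green_strain(np.eye(2)), 0.0, atol=1e-15)
        E = strain.green_strain(np.diag([0.8, 1.25]))
        np.testing.assert_allclose(E, np.diag([-0.18, 0.28125]), atol=1e-12)

    def test_pure_rotation_is_strain_free(self):
        th = 0.7
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.abs(strain.green_strain(Rm)).max() < 1e-10


class TestProjections:
    def test_basis_alignment_on_x_axis(self):
        E = np.diag([-0.18, 0.28125])
        ecc, err = strain.polar_project(E, np.array([10.0, 0.0]), np.zeros(2))
        assert err == pytest.approx(-0.18)
        assert ecc == pytest.approx(0.28125)

    def test_frame_covariance(self):
        E = np.array([[0.1, 0.03], [0.03, -0.2]])
        X = np.array([7.0, 3.0])
        th = np.pi / 2
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        base = strain.polar_project(E, X, np.zeros(2))
        rotated = strain.polar_project(Rm @ E @ Rm.T, Rm @ X, np.zeros(2))
        np.testing.assert_allclose(rotated, base, atol=1e-12)

    def test_center_coincidence_rejected(self):
        with pytest.raises(InputError):
            strain.polar_project(np.zeros((2, 2)), np.zeros(2), np.zeros(2))

    def test_longitudinal_uniform_stretch(self):
        # two straight vertical walls, E = diag(0, (lam^2-1)/2) everywhere
        lam = np.sqrt(0.70)
        ys = np.linspace(0, 80, 30)
        pts = np.concatenate(
            [np.stack([np.full_like(ys, x0), ys], axis=-1) for x0 in (-30.0, 30.0)]
        )
        E = np.tile(np.diag([0.0, 0.5 * (lam**2 - 1)]), (len(pts), 1, 1))
        ell = strain.longitudinal_project(
            E, pts, mitral_mid=np.array([0.0, 0.0]), apex=np.array([0.0, 80.0]),
            bin_width=4.0,
        )
        np.testing.assert_allclose(ell, -0.15, atol=1e-9)
        np.testing.assert_allclose(
            strain.longitudinal_project(
                np.zeros_like(E), pts, np.array([0.0, 0.0]), np.array([0.0, 80.0]), 4.0
            ),
            0.0,
            atol=1e-12,
        )


class TestSegments:
    def _ring(self, n=360):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return 30.0 * np.stack([np.cos(ang), np.sin(ang)], axis=-1)

    def test_three_level_bookkeeping(self):
        pts = self._ring()
        C = np.zeros(2)
        rv = np.array([-25.0, -18.0])
        ids = np.concatenate(
            [strain.assign_segments(pts, C, rv, level) for level in ("base", "mid", "apex")]
        )
        assert set(ids) == set(range(1, 17))
        counts = {
            "base": len(set(strain.assign_segments(pts, C, rv, "base"))),
            "mid": len(set(strain.assign_segments(pts, C, rv, "mid"))),
            "apex": len(set(strain.assign_segments(pts, C, rv, "apex"))),
        }
        assert counts == {"base": 6, "mid": 6, "apex": 4}

    def test_boundary_ray_half_open(self):
        C = np.zeros(2)
        rv = np.array([20.0, 0.0])
        on_origin_ray = np.array([[25.0, 0.0]])
        assert strain.assign_segments(on_origin_ray, C, rv, "base")[0] == 1
        on_60deg = 25.0 * np.array([[np.cos(np.pi / 3), np.sin(np.pi / 3)]])
        assert strain.assign_segments(on_60deg, C, rv, "base")[0] == 2

    def test_rotating_landmark_permutes_ids_cyclically(self):
        pts = self._ring()
        C = np.zeros(2)
        rv = np.array([20.0, 0.0])
        rv60 = 20.0 * np.array([np.cos(np.pi / 3), np.sin(np.pi / 3)])
        ids = strain.assign_segments(pts, C, rv, "base")
        ids_rot = strain.assign_segments(pts, C, rv60, "base")
        np.testing.assert_array_equal(ids_rot, (ids - 1 - 1) % 6 + 1)

    def test_missing_landmark_rejected(self):
        with pytest.raises(InputError):
            strain.assign_segments(self._ring(), np.zeros(2), None, "base")


class TestTwistTorsion:
    def test_rigid_rotation_recovered_exactly(self):
        ang = np.deg2rad(8.0)
        Rm = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        traj = _grid_trajectories(lambda X: (X - 10.0) @ Rm.T + 10.0)
        C = np.array([10.0, 10.0])
        assert strain.compute_twist(traj, C, 1) == pytest.approx(8.0, abs=1e-9)
        assert strain.compute_twist(traj, C, 0) == pytest.approx(0.0, abs=1e-12)

    def test_torsion_exact_line_and_degenerate(self):
        assert strain.compute_torsion([2.0, 5.0, 8.0], [0.0, 30.0, 60.0]) == pytest.approx(1.0)
        assert strain.compute_torsion([4.0, 4.0, 4.0], [0.0, 25.0, 50.0]) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(InputError):
            strain.compute_torsion([2.0], [0.0])

    def test_phantom_per_slice_twist_recovered(self, sax_renders_17, healthy_spec):
        # raw (unsmoothed) trajectories isolate compute_twist from the
        # temporal-fit bias; recovery within 0.1 degrees
        from cinedense import phase

        for view, idx in (("SAX-base", 0), ("SAX-mid", 1), ("SAX-apex", 2)):
            series, roi = sax_renders_17[view]
            unw = phase.unwrap_phase(series, roi)
            disp = phase.to_displacement(unw, series.encoding_frequency, series.pixel_spacing)
            traj = phase.track_trajectories(
                disp, roi.reference_mask, times_ms=series.trigger_times, smooth_degree=None
            )
            n = series.grid_shape[0]
            C = np.array([1.0, 1.0]) * (n - 1) / 2.0 * series.pixel_spacing
            k = 23  # the frame closest to prescribed end systole (345 ms)
            measured = strain.compute_twist(traj, C, k)
            expected = healthy_spec.twists_es[idx] * float(
                healthy_spec.activation(series.trigger_times[k])
            )
            assert measured == pytest.approx(expected, abs=0.1)


class TestStrainSummary:
    def test_uniform_activation_curve(self):
        frames = 20
        t = np.arange(frames) * 15.0
        s = np.sin(np.pi * t / (2 * t[-1])) ** 2
        ecc = -0.2 * np.tile(s[:, None], (1, 10))
        fld = strain.StrainField(
            X=np.random.default_rng(0).uniform(0, 10, (10, 2)),
            valid=np.ones((frames, 10), dtype=bool),
            ecc=ecc,
            err=np.zeros_like(ecc),
            ell=None,
            segments=np.full(10, 4),
            view="SAX-mid",
            times_ms=t,
        )
        summary = strain.strain_summary(fld)
        assert summary.es_frame == int(np.argmax(s))
        assert summary.es_ecc == pytest.approx(-0.2)

    def test_global_ell_is_mean_of_mid_segments(self):
        frames = 12
        t = np.arange(frames, dtype=float)
        ramp = t / t[-1]
        ell = np.zeros((frames, 8))
        segs = np.array([9, 9, 9, 9, 12, 12, 12, 12])
        ell[:, segs == 9] = -0.10 * ramp[:, None]
        ell[:, segs == 12] = -0.20 * ramp[:, None]
        fld = strain.StrainField(
            X=np.stack([np.arange(8.0), np.arange(8.0)], axis=-1),
            valid=np.ones((frames, 8), dtype=bool),
            ecc=None,
            err=None,
            ell=ell,
            segments=segs,
            view="LAX-4CH",
            times_ms=t,
        )
        summary = strain.strain_summary(fld)
        assert summary.global_ell == pytest.approx(-0.15)

    def test_whole_pipeline_transmural_mean(self, sax_summaries_17):
        # whole-slice end-systolic Ecc within 0.01 of the prescribed mean
        for summary in sax_summaries_17.values():
            t_es = summary.times_ms[summary.es_frame]
            assert summary.es_ecc == pytest.approx(-0.18, abs=0.01)
            assert t_es == pytest.approx(345.0, abs=30.0)

    def test_lax_global_ell_recovery(self, lax_summary_17):
        assert lax_summary_17.global_ell == pytest.approx(-0.15, abs=0.01)
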