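"""Displacement integration, Savitzky-Golay gradients, strain tensors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myodyn import strain, synthetic
from myodyn.io import RoiMask, VelocitySeries
from myodyn.strain import (
    DisplacementSeries,
    StrainCurve,
    integrate_velocity,
    principal_strains,
    roi_strain_curve,
    spatial_gradient_sg,
    strain_tensor,
)


def _vel(data, dt=50.0, venc=15.0, spacing=(1.0, 1.0, 1.0)):
    return VelocitySeries(data=data, venc=venc, frame_interval=dt,
                          voxel_spacing=spacing)


class TestIntegrateVelocity:
    def test_zero_velocity_zero_displacement(self):
        v = _vel(np.zeros((3, 8, 4, 4, 4)))
        u = integrate_velocity(v)
        assert np.all(u.data == 0)

    def test_constant_drift_nulled_exactly(self):
        """A constant velocity everywhere (eddy-current-like offset) must
        integrate to identically zero displacement under the blend."""
        v = _vel(np.full((3, 16, 3, 3, 3), 2.7))
        u = integrate_velocity(v)
        assert np.abs(u.data).max() < 1e-9

    def test_cosine_velocity_integrates_to_sine_second_order(self):
        """v = cos(2 pi t / T) -> u = (T / 2 pi) sin(2 pi t / T); the
        quadrature error must fall ~4x when the frame count doubles."""
        errs = []
        for n in (16, 32, 64):
            T = 1600.0
            dt = T / n
            t = np.arange(n) * dt
            vdat = np.zeros((3, n, 2, 2, 2))
            vdat[0] = np.cos(2 * np.pi * t / T)[None, :, None, None, None]
            u = integrate_velocity(_vel(vdat, dt=dt))
            # cm/s * ms -> mm conversion factor 0.01
            expected = 0.01 * (T / (2 * np.pi)) * np.sin(2 * np.pi * t / T)
            errs.append(np.abs(u.data[0, :, 0, 0, 0] - expected).max())
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_first_frame_zero(self):
        rng = np.random.default_rng(0)
        v = _vel(rng.normal(size=(3, 12, 3, 3, 3)))
        u = integrate_velocity(v)
        assert np.all(u.data[:, 0] == 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            integrate_velocity(_vel(np.zeros((3, 2, 3, 3, 3))))

    def test_round_trip_with_generator(self, phantom_truth):
        v, _ = synthetic.velocities_from_displacement(
            phantom_truth.displacement)
        u = integrate_velocity(v)
        peak = np.abs(phantom_truth.displacement.data).max()
        err = np.abs(u.data - phantom_truth.displacement.data).max()
        assert err < 0.02 * peak

    def test_round_trip_error_shrinks_with_frames(
            self, phantom, uniaxial_model):
        rel = []
        for n in (16, 64):
            t = np.arange(n) * uniaxial_model.cycle_duration / n
            truth = synthetic.analytic_displacement(phantom, uniaxial_model,
                                                    t)
            v, _ = synthetic.velocities_from_displacement(truth.displacement)
            u = integrate_velocity(v)
            peak = np.abs(truth.displacement.data).max()
            rel.append(np.abs(u.data - truth.displacement.data).max() / peak)
        assert rel[1] < rel[0]


class TestSpatialGradient:
    def _disp(self, u):
        n = u.shape[1]
        return DisplacementSeries(data=u, frame_times=np.arange(n) * 50.0,
                                  voxel_spacing=(2.0, 1.5, 1.0),
                                  cycle_duration=n * 50.0)

    def test_constant_displacement_zero_gradient(self):
        u = np.full((3, 2, 9, 9, 9), 3.3)
        g = spatial_gradient_sg(self._disp(u))
        np.testing.assert_allclose(g, 0, atol=1e-12)

    def test_linear_field_exact_interior(self):
        """u_x = 0.1 x (x in mm) must give (grad u)_xx = 0.1 exactly."""
        shape = (11, 9, 9)
        x = np.arange(shape[0]) * 2.0  # mm, spacing 2.0 along axis 0
        u = np.zeros((3, 2) + shape)
        u[0] = x[None, :, None, None] * 0.1
        g = spatial_gradient_sg(self._disp(u))
        interior = g[:, 3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(interior[..., 0, 0], 0.1, atol=1e-10)
        np.testing.assert_allclose(interior[..., 0, 1], 0.0, atol=1e-10)

    def test_quadratic_field_exact_for_order_2(self):
        shape = (13, 9, 9)
        a = 0.01
        xmm = np.arange(shape[0]) * 2.0
        u = np.zeros((3, 1) + shape)
        u[0] = (a * xmm ** 2)[None, :, None, None]
        g = spatial_gradient_sg(self._disp(u), window=5, poly_order=2)
        expected = 2 * a * xmm
        got = g[0, 3:-3, 4, 4, 0, 0]
        np.testing.assert_allclose(got, expected[3:-3], atol=1e-10)

    def test_window_validation(self):
        u = np.zeros((3, 1, 9, 9, 9))
        with pytest.raises(ValueError, match="odd"):
            spatial_gradient_sg(self._disp(u), window=4)
        with pytest.raises(ValueError, match="exceeds"):
            spatial_gradient_sg(self._disp(u), window=11)


class TestStrainTensor:
    def test_zero_gradient_zero_strain(self):
        g = np.zeros((1, 4, 4, 4, 3, 3))
        E = strain_tensor(g)
        assert np.all(E.data == 0)

    def test_uniaxial_green_lagrange_vs_infinitesimal(self):
        g = np.zeros((1, 1, 1, 1, 3, 3))
        g[..., 0, 0] = 0.1
        gl = strain_tensor(g, "green_lagrange").data[0, 0, 0, 0]
        lin = strain_tensor(g, "infinitesimal").data[0, 0, 0, 0]
        assert gl[0, 0] == pytest.approx(0.105, abs=1e-12)  # (1.1^2-1)/2
        assert lin[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_exact_rotation_has_zero_green_lagrange_strain(self):
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        g = np.broadcast_to(R - np.eye(3), (1, 2, 2, 2, 3, 3)).copy()
        gl = strain_tensor(g, "green_lagrange").data
        lin = strain_tensor(g, "infinitesimal").data
        assert np.abs(gl).max() < 1e-14
        assert np.abs(lin).max() > 1e-3  # small-strain tensor is fooled

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            strain_tensor(np.zeros((1, 1, 1, 1, 3, 3)), "bogus")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_always_symmetric(self, seed):
        g = np.random.default_rng(seed).normal(size=(2, 3, 3, 3, 3, 3)) * 0.2
        E = strain_tensor(g).data
        np.testing.assert_array_equal(E, np.swapaxes(E, -1, -2))


class TestPrincipalStrains:
    def test_diagonal_tensor_eigenvalues(self):
        E = np.zeros((1, 1, 1, 1, 3, 3))
        E[..., 0, 0], E[..., 1, 1], E[..., 2, 2] = 0.105, 0.0, -0.05
        ts = strain_tensor(np.zeros_like(E))
        ts.data = E
        P = principal_strains(ts)
        assert P.eigenvalues[0, 0, 0, 0, 0] == pytest.approx(0.105)
        assert P.first_positive[0, 0, 0, 0] == pytest.approx(0.105)

    def test_simple_shear_largest_eigenvalue(self):
        """gamma = 0.2 simple shear: lambda1 = 0.1105 against an independent
        characteristic-polynomial root oracle."""
        gamma = 0.2
        G = np.zeros((1, 1, 1, 1, 3, 3))
        G[..., 0, 1] = gamma  # F = I + gamma e_x (x) e_y
        E = strain_tensor(G, "green_lagrange")
        P = principal_strains(E)
        lam1 = P.eigenvalues[0, 0, 0, 0, 0]
        # oracle: det(E - lam I) = 0 via numpy polynomial roots
        Em = E.data[0, 0, 0, 0]
        c2 = -np.trace(Em)
        c1 = 0.5 * (np.trace(Em) ** 2 - np.trace(Em @ Em))
        c0 = -np.linalg.det(Em)
        roots = np.roots([1.0, c2, c1, c0])
        assert lam1 == pytest.approx(np.max(roots.real), abs=1e-12)
        assert lam1 == pytest.approx(0.1105, abs=1e-4)

    def test_all_negative_clamped_and_flagged(self):
        E = np.zeros((1, 1, 1, 1, 3, 3))
        E[..., 0, 0] = E[..., 1, 1] = E[..., 2, 2] = -0.1
        ts = strain_tensor(np.zeros_like(E))
        ts.data = E
        P = principal_strains(ts)
        assert P.first_positive[0, 0, 0, 0] == 0.0
        assert P.nonpositive_flag[0, 0, 0, 0]

    def test_nonfinite_voxel_invalidated(self):
        E = np.zeros((1, 8, 8, 8, 3, 3))
        E[0, 4, 4, 4, 0, 0] = np.nan
        ts = strain_tensor(np.zeros_like(E), window=1)
        ts.data = E
        ts.valid = np.ones((8, 8, 8), dtype=bool)
        P = principal_strains(ts)
        assert not P.valid[4, 4, 4]
        assert np.isnan(P.first_positive[0, 4, 4, 4])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_eigenvalues_sorted_descending(self, seed):
        g = np.random.default_rng(seed).normal(size=(1, 2, 2, 2, 3, 3)) * 0.3
        P = principal_strains(strain_tensor(g))
        lam = P.eigenvalues[:, P.valid] if P.valid.any() else P.eigenvalues
        lam = P.eigenvalues.reshape(-1, 3)
        lam = lam[np.isfinite(lam).all(axis=1)]
        assert (np.diff(lam, axis=1) <= 1e-12).all()


class TestRoiCurve:
    def _uniform_P(self, value=0.2, shape=(10, 10, 20), frames=4):
        E = np.zeros((frames,) + shape + (3, 3))
        E[..., 0, 0] = value
        ts = strain_tensor(np.zeros_like(E))
        ts.data = E
        ts.valid = np.ones(shape, dtype=bool)
        return principal_strains(ts)

    def test_uniform_region_returns_constant_curve(self):
        P = self._uniform_P(0.2)
        mask = RoiMask(label_volume=np.ones((10, 10, 20), dtype=int))
        curve = roi_strain_curve(P, mask, 1)
        np.testing.assert_allclose(curve.values, 0.2)

    def test_electrode_span_counts_half_muscle(self):
        P = self._uniform_P(0.2)
        labels = np.ones((10, 10, 20), dtype=int)
        mask = RoiMask(label_volume=labels)
        centers = ((5, 5, 0), (5, 5, 9.0))
        curve = roi_strain_curve(P, mask, 1, centers)
        assert curve.n_voxels[0] == 10 * 10 * 10

    def test_empty_span_rejected(self):
        P = self._uniform_P()
        labels = np.zeros((10, 10, 20), dtype=int)
        labels[..., 15:] = 1
        mask = RoiMask(label_volume=labels)
        with pytest.raises(ValueError, match="span"):
            roi_strain_curve(P, mask, 1, ((5, 5, 0), (5, 5, 5)))

    def test_phantom_peak_within_5pct_of_closed_form(
            self, phantom, phantom_truth, uniaxial_model):
        v, _ = synthetic.velocities_from_displacement(
            phantom_truth.displacement)
        u = integrate_velocity(v)
        grad = spatial_gradient_sg(u)
        E = strain_tensor(grad, frame_times=u.frame_times)
        P = principal_strains(E)
        labels = np.where(phantom_truth.interior_mask,
                          phantom.label_volume, 0)
        mask = RoiMask(label_volume=labels)
        curve = roi_strain_curve(P, mask, 1, phantom.electrode_centers)
        assert curve.values.max() == pytest.approx(0.22, rel=0.05)


class TestStrainCurveType:
    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            StrainCurve(times=np.array([0.0, 0.0, 1.0]),
                        values=np.zeros(3), n_voxels=np.ones(3))
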