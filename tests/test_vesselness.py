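"""Hessian vesselness: analytic kernels, eigen ordering, response, transform."""

import numpy as np
import pytest

from cerevess.errors import ValidationError
from cerevess.phantom import PhantomSpec, StraightCenterline, TubeSpec, make_phantom
from cerevess.vesselness import (
    EigenField,
    ScaleSpaceParams,
    eigen_sorted,
    gaussian_hessian,
    regularized_lambda,
    vesselness_multiscale,
    vesselness_single_scale,
    vesselness_transform,
)


class TestGaussianHessian:
    @pytest.mark.parametrize("sigma", [0.8, 1.5, 3.0])
    def test_quadratic_volume_diagonal(self, sigma):
        # f = z1^2: the Gaussian-smoothed second derivative along axis 1 is
        # exactly 2, so the normalized component is 2 sigma^2
        z = np.arange(40, dtype=float)
        vol = np.broadcast_to(z[None, :, None] ** 2, (40, 40, 40)).copy()
        h = gaussian_hessian(vol, sigma)
        c = 20
        assert h[(1, 1)][c, c, c] == pytest.approx(2 * sigma ** 2, rel=1e-10)
        for ab in [(0, 0), (2, 2), (0, 1), (0, 2), (1, 2)]:
            assert h[ab][c, c, c] == pytest.approx(0.0, abs=1e-8)

    def test_bilinear_mixed_term(self):
        i = np.arange(32, dtype=float)
        vol = i[:, None, None] * i[None, :, None] * np.ones((1, 1, 32))
        h = gaussian_hessian(vol, 1.2)
        assert h[(0, 1)][16, 16, 16] == pytest.approx(1.2 ** 2, rel=1e-10)

    def test_constant_volume_zero(self):
        h = gaussian_hessian(np.full((24, 24, 24), 250.0), 2.0)
        for a in range(3):
            for b in range(a, 3):
                assert np.allclose(h[(a, b)], 0.0, atol=1e-9)

    def test_symmetry_on_random_volume(self, rng):
        vol = rng.normal(size=(20, 20, 20))
        h = gaussian_hessian(vol, 1.0)
        assert np.array_equal(h[(1, 2)], h[(2, 1)])
        assert np.array_equal(h[(0, 1)], h[(1, 0)])

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError, match="sigma"):
            gaussian_hessian(np.zeros((16, 16, 16)), 0.0)


class TestEigenSorted:
    def _field_from_matrix(self, m):
        comps = {(a, b): np.full((2, 2, 2), m[a, b]) for a in range(3)
                 for b in range(a, 3)}
        from cerevess.vesselness import HessianField
        return HessianField(comps, 1.0)

    def test_diagonal_matrix_magnitude_order(self):
        eigs = eigen_sorted(self._field_from_matrix(np.diag([0.1, -5.0, -4.0])))
        assert np.allclose(eigs.lambdas[0, 0, 0], [0.1, -4.0, -5.0])

    def test_zero_matrix(self):
        eigs = eigen_sorted(self._field_from_matrix(np.zeros((3, 3))))
        assert np.allclose(eigs.lambdas, 0.0)

    def test_trace_and_set_identity_random(self, rng):
        a = rng.normal(size=(3, 3))
        m = (a + a.T) / 2
        eigs = eigen_sorted(self._field_from_matrix(m))
        triple = eigs.lambdas[0, 0, 0]
        assert triple.sum() == pytest.approx(np.trace(m), rel=1e-10)
        # the magnitude-ordered triple is a permutation of the raw eigenvalues
        assert np.allclose(np.sort(triple), np.linalg.eigvalsh(m), atol=1e-10)
        assert np.all(np.diff(np.abs(triple)) >= -1e-12)


class TestRegularizedLambda:
    def _eigs(self, l3_values):
        lams = np.zeros((len(l3_values), 1, 1, 3))
        lams[..., 0, 0, 2] = np.asarray(l3_values).reshape(-1)
        return EigenField(lams, 1.0)

    def test_three_case_table(self):
        # M = 10, eps = 0.5: above the floor, below it, and negative
        eigs = self._eigs([10.0, 7.0, 3.0, -1.0])
        le = regularized_lambda(eigs, 0.5)
        assert le[0, 0, 0] == 10.0
        assert le[1, 0, 0] == 7.0
        assert le[2, 0, 0] == 5.0
        assert le[3, 0, 0] == 0.0

    def test_all_nonpositive_gives_zero(self):
        le = regularized_lambda(self._eigs([-3.0, -1.0, 0.0]), 0.5)
        assert np.all(le == 0.0)

    def test_epsilon_validation(self):
        with pytest.raises(ValidationError, match="epsilon"):
            regularized_lambda(self._eigs([1.0]), 0.0)


class TestSingleScaleResponse:
    def _T(self, l2, le):
        lams = np.zeros((1, 3))
        lams[0, 1] = l2
        lams[0, 2] = max(le, l2)
        return float(vesselness_single_scale(EigenField(lams, 1.0),
                                             np.array([le]))[0])

    def test_boundary_case_equals_one(self):
        # l2 = le/2 is the seam between the polynomial and saturated cases
        assert self._T(1.0, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_interior_value(self):
        assert self._T(1.0, 4.0) == pytest.approx(81 / 125, rel=1e-12)

    def test_nonvessel_sign_gives_zero(self):
        assert self._T(-1.0, 4.0) == 0.0
        assert self._T(1.0, 0.0) == 0.0

    def test_continuity_at_seam(self):
        le = 2.0
        delta = 1e-6
        assert abs(self._T(le / 2 - delta, le) - 1.0) < 1e-5

    def test_range_on_random_eigenvalues(self, rng):
        lams = np.sort(np.abs(rng.normal(size=(5000, 3))), axis=1) \
            * np.sign(rng.normal(size=(5000, 3)))
        order = np.argsort(np.abs(lams), axis=1)
        lams = np.take_along_axis(lams, order, axis=1)
        eigs = EigenField(lams, 1.0)
        le = regularized_lambda(eigs, 0.5)
        T = vesselness_single_scale(eigs, le)
        assert np.all(T >= 0.0) and np.all(T <= 1.0)


class TestMultiscale:
    def test_constant_volume_zero_response(self):
        params = ScaleSpaceParams(sigma_min=1.0, sigma_max=2.0, n_scales=2)
        vmap = vesselness_multiscale(np.full((24, 24, 24), 80.0), params)
        assert np.all(vmap.T == 0.0)

    def test_single_scale_grid_matches_direct_path(self, rng):
        vol = rng.normal(100.0, 10.0, size=(24, 24, 24))
        params = ScaleSpaceParams(sigma_min=1.5, sigma_max=1.5, n_scales=1)
        vmap = vesselness_multiscale(vol, params)
        eigs = eigen_sorted(gaussian_hessian(vol, 1.5))
        eigs = EigenField(-eigs.lambdas, 1.5)
        le = regularized_lambda(eigs, params.epsilon)
        T = vesselness_single_scale(eigs, le)
        assert np.allclose(vmap.T, T)

    def test_tube_centerline_brighter_than_background(self, noiseless_tube):
        vol, mask = noiseless_tube
        params = ScaleSpaceParams(sigma_min=1.0, sigma_max=4.0, n_scales=4)
        vmap = vesselness_multiscale(vol, params)
        on_axis = vmap.T[20, 20, 10:30].mean()
        background = vmap.T[~mask.astype(bool)].mean()
        assert on_axis > 10 * background
        assert on_axis > 0.5

    def test_rotation_robustness(self, noiseless_tube):
        vol, _ = noiseless_tube
        params = ScaleSpaceParams(sigma_min=1.0, sigma_max=3.0, n_scales=3)
        T0 = vesselness_multiscale(vol, params).T
        # rotate 90 degrees about axis 0 (tube stays axis-aligned)
        vol_rot = np.rot90(vol, k=1, axes=(1, 2))
        T_rot = vesselness_multiscale(vol_rot, params).T
        back = np.rot90(T_rot, k=-1, axes=(1, 2))
        assert np.allclose(T0, back, atol=1e-6)

    def test_structure_discrimination_tube_plate_ball(self):
        # the response uses only the two large eigenvalues: plates (one
        # strong curvature direction) are suppressed hard, while an isolated
        # ball saturates like a tube does — the operator carries no blob
        # penalty, a documented limitation of the response family
        shape = (40, 40, 40)
        idx = np.indices(shape, dtype=float)
        contrast = 100.0
        tube = contrast * np.exp(-((idx[0] - 20) ** 2 + (idx[1] - 20) ** 2) / (2 * 3 ** 2))
        plate = contrast * np.exp(-((idx[0] - 20) ** 2) / (2 * 3 ** 2))
        ball = contrast * np.exp(-(((idx - 20) ** 2).sum(axis=0)) / (2 * 3 ** 2))
        params = ScaleSpaceParams(sigma_min=1.5, sigma_max=4.0, n_scales=3)
        t_tube = vesselness_multiscale(tube, params).T[20, 20, 8:32].mean()
        t_plate = vesselness_multiscale(plate, params).T[20, 8:32, 8:32].mean()
        t_ball = vesselness_multiscale(ball, params).T[20, 20, 20]
        assert t_tube > 0.9
        assert t_plate < 1e-6
        assert t_tube > t_plate
        assert t_ball == pytest.approx(1.0)  # no lambda1 term: blobs saturate

    @pytest.mark.parametrize("radius", [2.0, 3.0])
    def test_scale_selectivity_of_normalized_eigenvalue(self, radius):
        # the scale-normalized lambda3 on the centerline peaks at the sigma
        # matched to the tube's effective cross-section width (~ r/2 for a
        # parabolic profile); assert the argmax lands within one grid step
        spec = PhantomSpec(
            shape=(40, 40, 40),
            tubes=(TubeSpec(
                StraightCenterline((20.0, 20.0, 0.0), (20.0, 20.0, 39.0)),
                radius=radius, peak_intensity=200.0, flow_profile_exponent=2.0),),
            background_components=((1.0, 20.0, 1e-12),), noise_sd=0.0, seed=0)
        vol, _ = make_phantom(spec)
        sigmas = ScaleSpaceParams(sigma_min=0.5, sigma_max=4.0, n_scales=5).sigmas
        response = [
            -eigen_sorted(gaussian_hessian(vol, float(s))).lambda3[20, 20, 20]
            for s in sigmas
        ]
        best = int(np.argmax(response))
        matched = int(np.argmin(np.abs(np.log(sigmas / (radius / 2)))))
        assert abs(best - matched) <= 1

    def test_volume_too_small_for_kernel(self):
        with pytest.raises(ValidationError, match="kernel support"):
            vesselness_multiscale(np.zeros((20, 20, 20)),
                                  ScaleSpaceParams(sigma_max=4.0))

    def test_response_bounds_on_random_volumes(self, rng):
        params = ScaleSpaceParams(sigma_min=0.7, sigma_max=2.0, n_scales=3)
        for _ in range(5):
            vol = rng.normal(100.0, 20.0, size=(24, 24, 24))
            T = vesselness_multiscale(vol, params).T
            assert np.all(T >= 0.0) and np.all(T <= 1.0)
            S = vesselness_transform(T, 0.3)
            assert np.all(S >= 0.0) and np.all(S < 1.0)


class TestTransform:
    def test_fixed_points(self):
        T = np.array([0.0, 0.5, 1.5, 1.0])
        S = vesselness_transform(T, 0.5)
        assert S[0] == 0.0
        assert S[1] == pytest.approx(0.5)
        assert S[2] == pytest.approx(0.9)       # T = 3Q
        assert S[3] == pytest.approx(1 / (1 + 0.25))

    def test_monotone_in_T(self):
        T = np.linspace(0, 1, 101)
        S = vesselness_transform(T, 0.2)
        assert np.all(np.diff(S) > 0)

    def test_invalid_Q(self):
        with pytest.raises(ValidationError, match="Q"):
            vesselness_transform(np.array([0.5]), 0.0)


def test_scale_space_params_validation():
    with pytest.raises(ValidationError):
        ScaleSpaceParams(sigma_min=0.0)
    with pytest.raises(ValidationError):
        ScaleSpaceParams(epsilon=1.5)
    with pytest.raises(ValidationError):
        ScaleSpaceParams(sigma_min=2.0, sigma_max=1.0)
    grid = ScaleSpaceParams(sigma_min=1.0, sigma_max=4.0, n_scales=3).sigmas
    assert np.allclose(grid, [1.0, 2.0, 4.0])
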