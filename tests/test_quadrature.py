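"""Sphere quadrature, projection tensors and integral identities."""

import numpy as np
import pytest

from microsma import (
    build_microplane_system,
    integrate_sphere,
    normal_tensor,
    shear_direction,
    shear_tensor,
    transformation_direction,
)
from microsma.quadrature import resolved_stress_integral

from conftest import random_rotation, random_symmetric

UNIAXIAL = np.diag([0.0, 0.0, 100.0])


class TestSystemConstruction:
    def test_42_point_rule_shape_and_normalisation(self, system42):
        assert len(system42) == 42
        assert np.linalg.norm(system42.normals, axis=1) == pytest.approx(1.0, abs=1e-12)
        assert system42.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (system42.weights > 0).all()

    def test_point_set_is_antipodally_symmetric(self, system42):
        pts = {tuple(np.round(n, 12)) for n in system42.normals}
        assert all(tuple(np.round(-n, 12)) in pts for n in system42.normals)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown quadrature scheme"):
            build_microplane_system("lebedev")

    def test_planes_view(self, system42):
        planes = system42.planes
        assert len(planes) == 42
        assert planes[0].w > 0 and abs(np.dot(planes[0].n, planes[0].n) - 1) < 1e-12


@pytest.mark.parametrize("scheme_fixture", ["system42", "dense_system"])
class TestMomentIdentities:
    def test_second_moment_is_identity(self, scheme_fixture, request):
        system = request.getfixturevalue(scheme_fixture)
        n, w = system.normals, system.weights
        moment = 3 * np.einsum("k,ki,kj->ij", w, n, n)
        assert np.abs(moment - np.eye(3)).max() < 1e-12

    def test_fourth_moment_scalar(self, scheme_fixture, request):
        system = request.getfixturevalue(scheme_fixture)
        n, w = system.normals, system.weights
        assert 3 * np.sum(w * n[:, 2] ** 4) == pytest.approx(3 / 5, abs=1e-12)

    def test_fourth_moment_full_tensor(self, scheme_fixture, request):
        # (3/4pi) int n_i n_j n_r n_s dphi = (d_ij d_rs + d_ir d_js + d_is d_jr)/5
        system = request.getfixturevalue(scheme_fixture)
        n, w = system.normals, system.weights
        moment = 3 * np.einsum("k,ki,kj,kr,ks->ijrs", w, n, n, n, n)
        d = np.eye(3)
        expected = (
            np.einsum("ij,rs->ijrs", d, d)
            + np.einsum("ir,js->ijrs", d, d)
            + np.einsum("is,jr->ijrs", d, d)
        ) / 5.0
        assert np.abs(moment - expected).max() < 1e-12


class TestProjectionTensors:
    def test_normal_tensor_axis_aligned(self):
        N = normal_tensor(np.array([0.0, 0.0, 1.0]))
        expected = np.zeros((3, 3))
        expected[2, 2] = 1.0
        assert np.array_equal(N, expected)

    def test_normal_tensor_diagonal_direction(self):
        n = np.ones(3) / np.sqrt(3)
        assert normal_tensor(n) == pytest.approx(np.full((3, 3), 1 / 3))

    def test_normal_tensor_trace_and_projection(self, rng):
        v = rng.normal(size=3)
        n = v / np.linalg.norm(v)
        N = normal_tensor(n)
        assert np.trace(N) == pytest.approx(1.0, abs=1e-12)
        assert N @ n == pytest.approx(n, abs=1e-12)

    def test_normal_tensor_rejects_non_unit(self):
        with pytest.raises(ValueError, match="unit"):
            normal_tensor(np.array([1.0, 1.0, 0.0]))

    def test_shear_direction_45_degree_plane(self):
        n = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        t = shear_direction(n, UNIAXIAL)
        assert t == pytest.approx(np.array([-1.0, 0.0, 1.0]) / np.sqrt(2), abs=1e-12)

    def test_shear_direction_degenerate_cases(self):
        # traction parallel to the normal, and hydrostatic stress: no shear
        assert np.array_equal(shear_direction(np.array([0.0, 0.0, 1.0]), UNIAXIAL), np.zeros(3))
        hydro = 50.0 * np.eye(3)
        n = np.array([1.0, 2.0, 2.0]) / 3.0
        assert np.array_equal(shear_direction(n, hydro), np.zeros(3))

    def test_shear_direction_orthogonal_unit(self, rng):
        for _ in range(20):
            sigma = random_symmetric(rng)
            v = rng.normal(size=3)
            n = v / np.linalg.norm(v)
            t = shear_direction(n, sigma)
            mag = np.linalg.norm(t)
            assert mag == pytest.approx(1.0, abs=1e-9) or mag == 0.0
            assert abs(np.dot(t, n)) < 1e-9

    def test_shear_direction_rejects_asymmetric(self):
        bad = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            shear_direction(np.array([0.0, 0.0, 1.0]), bad)

    def test_shear_tensor_resolved_stress_on_45_plane(self):
        n = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        T = shear_tensor(n, UNIAXIAL)
        assert np.trace(T) == pytest.approx(0.0, abs=1e-12)
        assert np.sum(T * UNIAXIAL) == pytest.approx(50.0)  # tau = sigma/2 at 45 deg

    def test_shear_tensor_traceless_and_zero_for_hydrostatic(self, rng):
        for _ in range(10):
            sigma = random_symmetric(rng)
            v = rng.normal(size=3)
            n = v / np.linalg.norm(v)
            assert abs(np.trace(shear_tensor(n, sigma))) < 1e-12
        assert np.array_equal(shear_tensor(n, 10.0 * np.eye(3)), np.zeros((3, 3)))


class TestSphereIntegrals:
    def test_normal_field_integrates_to_identity(self, system42):
        result = integrate_sphere(system42, lambda n: np.outer(n, n))
        assert np.abs(result - np.eye(3)).max() < 1e-12

    def test_unit_shear_field_uniaxial_dense_oracle(self, dense_system):
        # continuum values: (3/4pi) int T33 dphi = 1, int T11 dphi = -1/2;
        # the 64x128 grid resolves the kinked integrand to ~3e-4
        result = integrate_sphere(
            dense_system, lambda n: shear_tensor(n, UNIAXIAL)
        )
        assert result[2, 2] == pytest.approx(1.0, abs=5e-4)
        assert result[0, 0] == pytest.approx(-0.5, abs=5e-4)

    def test_42_point_unit_shear_matches_its_calibration_constant(self, system42):
        # the discrete rule carries a known systematic factor on the unit
        # shear field; its inverse is stored as the calibration constant
        result = integrate_sphere(system42, lambda n: shear_tensor(n, UNIAXIAL))
        assert result[2, 2] == pytest.approx(1.0 / system42.shear_calibration, rel=1e-12)

    def test_resolved_stress_integral_recovers_sigma(self, system42, rng):
        # integrand sigma_N N + sigma_T T collapses to sym(n x sigma.n):
        # exact for any rule with exact second moments
        for _ in range(20):
            sigma = random_symmetric(rng)
            assert np.abs(resolved_stress_integral(system42, sigma) - sigma).max() < 1e-10

    def test_transformation_direction_uniaxial_calibrated(self, system42):
        lam = transformation_direction(system42, UNIAXIAL)
        assert lam == pytest.approx(np.diag([-0.5, -0.5, 1.0]), abs=1e-12)

    def test_transformation_direction_zero_stress(self, system42):
        assert np.array_equal(
            transformation_direction(system42, np.zeros((3, 3))), np.zeros((3, 3))
        )

    def test_transformation_direction_scale_invariant(self, system42, rng):
        sigma = random_symmetric(rng)
        a = transformation_direction(system42, sigma)
        b = transformation_direction(system42, 7.5 * sigma)
        assert a == pytest.approx(b, abs=1e-12)


class TestFrameBehaviour:
    def test_resolved_stress_integral_equivariant(self, system42, rng):
        for _ in range(10):
            sigma = random_symmetric(rng)
            R = random_rotation(rng)
            left = resolved_stress_integral(system42, R @ sigma @ R.T)
            right = R @ resolved_stress_integral(system42, sigma) @ R.T
            assert np.abs(left - right).max() < 1e-10

    def test_unit_shear_integral_equivariant_on_dense_grid(self, dense_system, rng):
        # limited by the grid's resolution of the kinked field (~1e-3)
        for _ in range(5):
            sigma = random_symmetric(rng)
            R = random_rotation(rng)
            left = transformation_direction(dense_system, R @ sigma @ R.T)
            right = R @ transformation_direction(dense_system, sigma) @ R.T
            rel = np.linalg.norm(left - right) / np.linalg.norm(right)
            assert rel < 5e-3
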