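"""Unit and property tests for the deterministic model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barebones import (
    ModelParams,
    classify_fixed_points,
    count_splitting_probabilities,
    derive_constants,
    f_map,
    g_map,
    jacobian_f,
    offspring_means,
    splitting_probabilities,
)
from conftest import random_valid_params


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a1=0.0, a2=1.0, gamma=0.5),
            dict(a1=-1.0, a2=1.0, gamma=0.5),
            dict(a1=1.0, a2=0.0, gamma=0.5),
            dict(a1=1.0, a2=1.0, gamma=0.0),
            dict(a1=1.0, a2=1.0, gamma=1.0),
            dict(a1=1.0, a2=1.0, gamma=1.5),
            dict(a1=1.0, a2=1.0, gamma=0.5, K=0),
            dict(a1=1.0, a2=1.0, gamma=0.5, K=2.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_coexistence_flag(self):
        assert ModelParams(1.0, 1.0, 1 / 3).coexistence
        # strongly asymmetric capacities break condition C but not validity
        assert not ModelParams(1.0, 5.0, 0.5).coexistence

    def test_subcritical_mutant_rejected_in_derivation(self):
        p = ModelParams(5.0, 1.0, 0.5)  # a2 < gamma*a1
        assert not p.supercritical
        with pytest.raises(ValueError):
            derive_constants(p)


class TestDerivedConstants:
    def test_reference_values(self, d0):
        assert d0.rho == pytest.approx(1.5, abs=1e-15)
        assert d0.b == pytest.approx(1 / math.log(1.5), abs=1e-12)
        assert d0.x_co == pytest.approx((0.75, 0.75), abs=1e-12)
        assert d0.x_re == (1.0, 0.0)
        assert d0.x_mu == (0.0, 1.0)
        assert d0.x_ex == (0.0, 0.0)
        assert d0.coexistence

    def test_fixed_points_are_fixed(self, p0, d0):
        for pt in d0.fixed_points.values():
            fx = f_map(pt, p0)
            assert max(abs(fx[0] - pt[0]), abs(fx[1] - pt[1])) < 1e-12

    def test_fixed_points_random_parameters(self):
        rng = np.random.default_rng(7)
        for p in random_valid_params(rng, 25):
            d = derive_constants(p)
            for pt in d.fixed_points.values():
                fx = f_map(pt, p)
                assert max(abs(fx[0] - pt[0]), abs(fx[1] - pt[1])) < 1e-12

    def test_rho_tilde_bracket(self):
        # sup of the Jacobian norm over the quadrant lies in (rho, 2]
        rng = np.random.default_rng(11)
        for p in random_valid_params(rng, 5):
            d = derive_constants(p)
            assert d.rho < d.rho_tilde <= 2.0 + 1e-9

    def test_jacobian_rowsum_bounded_by_two(self, p0):
        xs = np.linspace(0, 4, 40)
        for x1 in xs:
            for x2 in xs:
                J = jacobian_f((x1, x2), p0)
                assert np.abs(J).sum(axis=1).max() <= 2.0 + 1e-12

    def test_serialization_roundtrip(self, p0K):
        d = derive_constants(p0K)
        doc = d.to_dict()
        assert doc["rho"] == d.rho
        assert doc["K"] == 10_000
        assert doc["x_co"] == pytest.approx([0.75, 0.75], abs=1e-12)
        assert set(doc) >= {"a1", "a2", "gamma", "K", "rho", "b", "x_ex",
                            "x_re", "x_mu", "x_co", "coexistence", "rho_tilde"}


class TestPerCapitaLaws:
    def test_resident_probability_half_at_equilibrium(self, p0):
        p1, _ = splitting_probabilities((p0.a1, 0.0), p0)
        assert p1 == 0.5

    def test_mutant_probability_rho_over_two_at_resident_equilibrium(self, p0, d0):
        _, p2 = splitting_probabilities(d0.x_re, p0)
        assert p2 == pytest.approx(d0.rho / 2, abs=1e-15)

    def test_empty_habitat_certain_splitting(self, p0):
        assert splitting_probabilities((0.0, 0.0), p0) == (1.0, 1.0)

    def test_count_scale_probability_exact(self):
        p = ModelParams(1.0, 1.0, 1 / 3, K=10_000)
        p1, _ = count_splitting_probabilities((10_000, 0), p)
        assert p1 == 0.5

    def test_negative_state_rejected(self, p0):
        with pytest.raises(ValueError):
            splitting_probabilities((-0.1, 0.5), p0)

    @given(
        x1=st.floats(0, 50, allow_nan=False),
        x2=st.floats(0, 50, allow_nan=False),
        dx=st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_probabilities_in_range_and_monotone(self, x1, x2, dx):
        p = ModelParams(1.0, 1.2, 0.4)
        p1, p2 = splitting_probabilities((x1, x2), p)
        assert 0 < p1 <= 1 and 0 < p2 <= 1
        q1, q2 = splitting_probabilities((x1 + dx, x2), p)
        assert q1 <= p1 and q2 <= p2
        r1, r2 = splitting_probabilities((x1, x2 + dx), p)
        assert r1 <= p1 and r2 <= p2

    def test_offspring_means(self, p0, d0):
        assert offspring_means(d0.x_co, p0) == pytest.approx((1.0, 1.0), abs=1e-12)
        assert offspring_means(d0.x_re, p0) == pytest.approx((1.0, 1.5), abs=1e-15)
        assert offspring_means((0.5, 0.5), p0) == pytest.approx((1.2, 1.2), abs=1e-15)


class TestMap:
    def test_pointwise_value(self, p0):
        assert f_map((0.5, 0.5), p0) == pytest.approx((0.6, 0.6), abs=1e-15)

    def test_zeros_preserved(self, p0):
        assert f_map((0.0, 0.0), p0) == (0.0, 0.0)
        assert f_map((0.7, 0.0), p0)[1] == 0.0
        assert f_map((0.0, 0.7), p0)[0] == 0.0

    def test_image_bounds(self, p0):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x = rng.uniform(0, 10, size=2)
            fx = f_map(x, p0)
            assert 0 <= fx[0] < 2 * p0.a1 and 0 <= fx[1] < 2 * p0.a2

    def test_forward_invariance_of_tube(self, p0, d0):
        # [x_co1, inf) x [0, x_co2] maps into itself
        rng = np.random.default_rng(5)
        c1, c2 = d0.x_co
        pts = np.column_stack(
            [c1 + rng.exponential(1.0, 200), rng.uniform(0, c2, 200)]
        )
        # include boundary points
        pts = np.vstack([pts, [c1, 0.0], [c1, c2], [c1 + 5, c2], [c1, c2 / 2]])
        for x in pts:
            fx = f_map(x, p0)
            assert fx[0] >= c1 - 1e-12 and fx[1] <= c2 + 1e-12


class TestTranslation:
    def test_zero_fixed(self, p0):
        assert g_map((0.0, 0.0), p0) == (0.0, 0.0)

    def test_definitional_consistency(self, p0):
        rng = np.random.default_rng(9)
        for _ in range(100):
            x = rng.uniform([-0.9, 0], [3, 3])
            f_shift = f_map((p0.a1 + x[0], x[1]), p0)
            gx = g_map(x, p0)
            assert abs(gx[0] - (f_shift[0] - p0.a1)) < 1e-14
            assert abs(gx[1] - f_shift[1]) < 1e-14

    def test_outside_domain_rejected(self, p0):
        with pytest.raises(ValueError):
            g_map((-2.0, 0.1), p0)

    def test_linearization_error_quadratic(self, p0, d0):
        A = jacobian_f(d0.x_re, p0)
        errs = []
        for scale in (1e-3, 1e-4, 1e-5):
            x = np.array([0.6, 0.8]) * scale
            gx = np.array(g_map(x, p0))
            errs.append(np.max(np.abs(gx - A @ x)))
        # error ~ C*||x||^2: shrinks ~100x per decade of scale
        assert errs[1] < errs[0] / 50
        assert errs[2] < errs[1] / 50


class TestJacobian:
    def test_at_resident_equilibrium(self, p0, d0):
        A = jacobian_f(d0.x_re, p0)
        expected = np.array([[0.5, -1 / 6], [0.0, 1.5]])
        assert np.max(np.abs(A - expected)) < 1e-15

    def test_at_origin(self, p0):
        assert np.allclose(jacobian_f((0.0, 0.0), p0), 2 * np.eye(2), atol=1e-15)

    def test_matches_finite_differences(self, p0):
        rng = np.random.default_rng(13)
        h = 1e-6
        for _ in range(25):
            x = rng.uniform(0.05, 3.0, size=2)
            J = jacobian_f(x, p0)
            num = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fp = np.array(f_map(x + e, p0))
                fm = np.array(f_map(x - e, p0))
                num[:, j] = (fp - fm) / (2 * h)
            assert np.max(np.abs(J - num)) < 1e-6

    def test_stable_subspace_contraction(self, p0, d0):
        # vectors along the resident axis are halved in sup-norm by A
        A = jacobian_f(d0.x_re, p0)
        for x1 in (-2.0, -0.5, 0.3, 1.7):
            v = A @ np.array([x1, 0.0])
            assert abs(v[1]) == 0.0
            assert abs(abs(v[0]) - abs(x1) / 2) < 1e-15


class TestClassification:
    def test_reference_labels(self, d0):
        labels = classify_fixed_points(d0)
        assert labels == {
            "x_ex": "unstable",
            "x_re": "saddle",
            "x_mu": "saddle",
            "x_co": "stable",
        }

    def test_saddle_eigenvalues_at_x_re(self, p0, d0):
        eig = np.linalg.eigvals(jacobian_f(d0.x_re, p0))
        assert sorted(eig.real) == pytest.approx([0.5, 1.5], abs=1e-12)

    def test_coexistence_suppressed_without_condition(self):
        p = ModelParams(1.0, 5.0, 0.5)  # supercritical mutant, no coexistence
        d = derive_constants(p)
        labels = classify_fixed_points(d)
        assert labels["x_co"] is None
        assert labels["x_ex"] == "unstable"
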