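"""Analytic autoregulation phase space: fixed points, roots, boundaries."""

import math

import numpy as np
import pytest

from ddemotifs.autoreg import (
    characteristic_roots,
    classify_analytic,
    dominant_root,
    fixed_points,
    hopf_curve,
    hopf_eta_min,
    hopf_gamma_asymptote,
    period_estimate,
    saddle_node_eta,
    slope_M,
    spiral_boundary,
    spiral_eta,
    spiral_gamma_asymptote,
)
from ddemotifs.classifier import oscillation_features
from ddemotifs.models import build_motif
from ddemotifs.solver import integrate, resample_uniform


class TestFixedPoints:
    def test_repressor_single_point(self):
        fp = fixed_points(2.0, 2)
        assert len(fp.points) == 1
        assert fp.points[0] == pytest.approx(1.0, abs=1e-10)

    def test_activator_three_points(self):
        fp = fixed_points(3.0, -2)
        assert len(fp.points) == 3
        assert fp.points[0] == 0.0
        assert fp.points[1] == pytest.approx((3 - math.sqrt(5)) / 2, abs=1e-9)
        assert fp.points[2] == pytest.approx((3 + math.sqrt(5)) / 2, abs=1e-9)
        assert fp.stability == ("stable", "unstable", "stable")

    def test_weak_activator_origin_only(self):
        fp = fixed_points(1.0, -2)
        assert fp.points == (0.0,)

    @pytest.mark.parametrize("eta, n", [(2.0, 2), (7.0, 3), (4.0, -2), (1.5, -3)])
    def test_balance_residual(self, eta, n):
        for x in fixed_points(eta, n).points:
            if x > 0:
                assert x * (1 + x**n) == pytest.approx(eta, abs=1e-10)

    def test_delay_independence_of_steady_state(self):
        # the same monostable point reached at two very different delays
        finals = []
        for gamma in (0.3, 3.0):
            m = build_motif("autoregulation", eta=1.0, n=2, gamma=gamma)
            traj = integrate(m, [0.2], 40.0 * (gamma + 1))
            finals.append(traj.values[-1, 0])
        assert abs(finals[0] - finals[1]) < 1e-4
        x_star = fixed_points(1.0, 2).points[0]
        assert finals[0] == pytest.approx(x_star, abs=1e-4)


class TestSlopeM:
    @pytest.mark.parametrize("x, n, expected", [(1.0, 2, 0.5), (1.0, -2, -0.5)])
    def test_values(self, x, n, expected):
        assert slope_M(x, n) == pytest.approx(expected)

    def test_sign_follows_n(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.uniform(0.05, 5.0)
            n = rng.uniform(0.2, 8.0)
            assert slope_M(x, n) > 0
            assert slope_M(x, -n) < 0

    def test_origin_limits(self):
        assert slope_M(0.0, -0.5) == -math.inf  # weakly cooperative activator
        assert slope_M(0.0, -2) == 0.0


class TestCharacteristicRoots:
    def test_no_delay(self):
        assert characteristic_roots(1.0, 0.0) == [complex(-2.0)]

    def test_no_feedback(self):
        assert characteristic_roots(0.0, 5.0) == [complex(-1.0)]

    def test_hopf_pair_on_axis(self):
        roots = characteristic_roots(math.sqrt(2), 3 * math.pi / 4, count=2)
        assert sorted(r.imag for r in roots) == pytest.approx([-1.0, 1.0], abs=1e-9)
        assert all(abs(r.real) < 1e-9 for r in roots)

    @pytest.mark.parametrize("a, gamma", [(0.5, 1.0), (3.0, 2.0), (-0.8, 4.0), (10.0, 0.3)])
    def test_residuals(self, a, gamma):
        for lam in characteristic_roots(a, gamma, count=5):
            res = lam + a * np.exp(-gamma * lam) + 1
            assert abs(res) < 1e-9


class TestSaddleNode:
    def test_boundary_values(self):
        assert saddle_node_eta(-2) == pytest.approx(2.0, abs=1e-12)
        assert saddle_node_eta(-3) == pytest.approx(3 * 2 ** (-2 / 3), abs=1e-9)

    def test_bounded_between_one_and_two(self):
        ms = np.linspace(1.001, 100, 5000)
        etas = np.array([saddle_node_eta(-m) for m in ms])
        assert etas.max() <= 2.0 + 1e-12
        assert etas.min() >= 1.0 - 1e-9
        assert ms[etas.argmax()] == pytest.approx(2.0, abs=0.05)

    def test_requires_cooperative_activation(self):
        with pytest.raises(ValueError):
            saddle_node_eta(-0.5)
        with pytest.raises(ValueError):
            saddle_node_eta(2)

    @pytest.mark.parametrize("n", [-2.0, -3.0, -1.5])
    def test_tangency_of_fixed_points(self, n):
        # at the boundary the production and removal curves are tangent: the
        # double root X_c solves both the balance and its derivative
        eta_c = saddle_node_eta(n)
        x_c = (-1.0 / (n + 1.0)) ** (1.0 / n)
        assert x_c * (1 + x_c**n) == pytest.approx(eta_c, abs=1e-10)
        assert 1 + (n + 1) * x_c**n == pytest.approx(0.0, abs=1e-10)
        # just above the boundary the pair splits around X_c
        fp = fixed_points(eta_c * 1.001, n)
        nonzero = [x for x in fp.points if x > 0]
        assert len(nonzero) == 2
        assert all(abs(x - x_c) < 0.2 for x in nonzero)


class TestHopf:
    def test_point_at_unit_frequency(self):
        c = hopf_curve(2, k=1, omega_grid=np.array([1.0]))
        assert c.gamma[0] == pytest.approx(3 * math.pi / 4, abs=1e-12)
        assert c.eta[0] == pytest.approx(5.3049, abs=2e-4)

    def test_asymptotes(self):
        assert hopf_eta_min(2) == pytest.approx(2.0, abs=1e-12)
        assert hopf_gamma_asymptote(2) == pytest.approx(
            math.acos(-0.5) / math.sqrt(3), abs=1e-12
        )
        assert hopf_gamma_asymptote(2) == pytest.approx(1.20920, abs=1e-5)

    def test_round_trip_dominant_root(self):
        # every emitted boundary point reproduces a characteristic root at
        # +i omega through the fixed point it implies
        for n in (2, 4):
            c = hopf_curve(n, k=1)
            for w, g, e in zip(c.omega, c.gamma, c.eta):
                x_star = fixed_points(e, n).points[0]
                roots = characteristic_roots(e * slope_M(x_star, n), g, count=7)
                assert min(abs(r - 1j * w) for r in roots) < 1e-6

    def test_branches_require_k_at_least_one(self):
        with pytest.raises(ValueError):
            hopf_curve(2, k=0)

    def test_omega_domain(self):
        with pytest.raises(ValueError):
            hopf_curve(2, k=1, omega_grid=np.array([5.0]))  # beyond sqrt(n^2-1)


class TestSpiral:
    def test_value_at_unit_delay(self):
        assert spiral_eta(2, 1.0) == pytest.approx(0.2889, abs=2e-4)

    def test_vertical_asymptote(self):
        g0 = spiral_gamma_asymptote(2)
        assert g0 == pytest.approx(0.1572, abs=2e-4)
        assert 2 * g0 * math.exp(g0 + 1) == pytest.approx(1.0, abs=1e-10)

    def test_decays_for_large_delay(self):
        c = spiral_boundary(2)
        assert c.eta[-1] < 0.01
        assert np.all(np.diff(c.eta[len(c.eta) // 2 :]) <= 0)

    def test_root_type_switches_across_boundary(self):
        # 5% above the curve the dominant root is complex; 5% below, real
        n, gamma = 2, 1.0
        eta_b = spiral_eta(n, gamma)
        for fac, complex_expected in ((1.05, True), (0.95, False)):
            eta = eta_b * fac
            x_star = fixed_points(eta, n).points[0]
            lam = dominant_root(eta * slope_M(x_star, n), gamma)
            assert (abs(lam.imag) > 1e-9) == complex_expected


class TestClassifyAnalytic:
    @pytest.mark.parametrize(
        "eta, gamma, n, label",
        [
            (10, 5, 2, "oscillatory"),
            (3, 0.7, -2, "bistable"),
            (1, 0.1, 2, "monostable"),
            (2, 3, 2, "monostable_spiral"),
            (1.5, 2, -2, "monostable"),
            (0.5, 8, 3, "monostable_spiral"),
        ],
    )
    def test_labels(self, eta, gamma, n, label):
        assert classify_analytic(eta, gamma, n) == label

    def test_bistability_is_delay_independent(self):
        assert {classify_analytic(3, g, -2) for g in (0.0, 0.5, 5.0, 50.0)} == {"bistable"}


class TestPeriod:
    @pytest.mark.parametrize("gamma, expected", [(5, 12), (0, 2)])
    def test_estimate(self, gamma, expected):
        assert period_estimate(gamma) == expected

    def test_dimensional_form(self):
        # tau=3, beta=0.5: 2 (tau + 1/beta) = 10 time units
        gamma = 3 * 0.5
        period_dimless = period_estimate(gamma)
        assert period_dimless / 0.5 == pytest.approx(10.0)

    @pytest.mark.parametrize("n, eta, gamma", [(2, 10, 5), (4, 20, 3), (2, 10, 10)])
    def test_simulated_period_within_20_percent(self, n, eta, gamma):
        m = build_motif("autoregulation", eta=eta, n=n, gamma=gamma)
        t_end = 40.0 * (gamma + 1)
        traj = integrate(m, [0.3], t_end)
        dt = 0.05 * (gamma + 1)
        ts, vs = resample_uniform(traj, dt, t_end / 4)
        feat = oscillation_features(vs[:, 0], dt, threshold=1.0)
        assert feat["dominant_period"] == pytest.approx(period_estimate(gamma), rel=0.2)
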