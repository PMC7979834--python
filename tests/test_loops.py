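"""Two-component feedback loops: fixed points, modes, boundaries, phases."""

import math

import numpy as np
import pytest

from ddemotifs.loops import (
    LoopParams,
    classify_loop_analytic,
    loop_eigenmodes,
    loop_fixed_points,
    loop_hopf_curve,
    loop_hopf_mean_delay,
    loop_hopf_point,
    loop_phase_offset,
    loop_saddle_node_curve,
)
from ddemotifs.models import build_motif
from ddemotifs.solver import integrate, resample_uniform


class TestFixedPoints:
    def test_symmetric_point(self):
        fps = loop_fixed_points(LoopParams(2, 2, 2, 2, 1, 1))
        assert len(fps) == 1
        assert fps[0]["X"] == pytest.approx(1.0, abs=1e-4)
        assert fps[0]["Y"] == pytest.approx(1.0, abs=1e-4)

    def test_two_repressors_beyond_boundary(self):
        fps = loop_fixed_points(LoopParams(3, 3, 2, 2, 1, 1))
        assert len(fps) == 3
        outer = [fp for fp in fps if fp["stability"] == "stable"]
        assert len(outer) == 2
        # asymmetric mirror pair
        assert outer[0]["X"] == pytest.approx(outer[1]["Y"], abs=1e-8)
        assert outer[0]["Y"] == pytest.approx(outer[1]["X"], abs=1e-8)

    def test_two_activators_origin_present(self):
        fps = loop_fixed_points(LoopParams(3, 3, -2, -2, 1, 1))
        assert fps[0]["X"] == 0.0 and fps[0]["Y"] == 0.0
        assert fps[0]["stability"] == "stable"

    @pytest.mark.parametrize(
        "p",
        [
            LoopParams(3, 3, 2, 2, 1, 1),
            LoopParams(5, 2, 2, -2, 0.5, 2),
            LoopParams(3, 3, -2, -2, 1, 1),
        ],
    )
    def test_balance_residuals(self, p):
        for fp in loop_fixed_points(p):
            x, y = fp["X"], fp["Y"]
            if x == 0 and y == 0:
                continue
            assert x * (1 + y**p.n1) == pytest.approx(p.eta1, rel=1e-8)
            assert y * (1 + x**p.n2) == pytest.approx(p.eta2, rel=1e-8)


class TestEigenmodes:
    def test_equal_delay_phase_relations(self):
        # oscillatory-mode X-Y offsets: synchronous for two repressors,
        # anti-synchronous for two activators, quarter-period for mixed
        cases = {
            (2, 2): 0.0,
            (-2, -2): math.pi,
            (2, -2): math.pi / 2,
        }
        for (n1, n2), expected in cases.items():
            p = LoopParams(5, 5, n1, n2, 2, 2)
            fps = [f for f in loop_fixed_points(p) if f["X"] > 0]
            mid = fps[len(fps) // 2]
            modes = loop_eigenmodes(p, (mid["X"], mid["Y"]))
            osc = [m for m in modes if abs(m.lam.imag) > 1e-9]
            assert osc, f"no oscillatory mode for {(n1, n2)}"
            offs = min(abs(abs(m.phase_offset) - expected) for m in osc)
            assert offs < 1e-6

    def test_roots_satisfy_mode_equation(self):
        p = LoopParams(4, 3, 2, -3, 1.0, 2.0)
        (fp,) = loop_fixed_points(p)
        for m in loop_eigenmodes(p, (fp["X"], fp["Y"])):
            sgn = 1.0 if m.mode == "plus" else -1.0
            a = sgn * np.sqrt(complex(p.eta1 * m.M1 * p.eta2 * m.M2))
            res = m.lam + a * np.exp(-m.lam * p.mean_delay) + 1
            assert abs(res) < 1e-9


class TestSaddleNodeCurve:
    @pytest.mark.parametrize("n", [2, -2])
    def test_symmetric_point_at_two_two(self, n):
        c = loop_saddle_node_curve(n, n)
        i = np.argmin(np.abs(c["X"] - 1.0))
        assert c["eta1"][i] == pytest.approx(2.0, abs=1e-9)
        assert c["eta2"][i] == pytest.approx(2.0, abs=1e-9)

    def test_constraint_satisfied_on_curve(self):
        c = loop_saddle_node_curve(2, 2)
        for x, y in zip(c["X"], c["Y"]):
            f = 4 * x**2 * y**2 / ((1 + x**2) * (1 + y**2))
            assert f == pytest.approx(1.0, abs=1e-9)

    def test_exchange_symmetry(self):
        # swapping the arms maps each boundary point (eta1, eta2) at (X, Y)
        # to the point (eta2, eta1) of the swapped curve swept at X' = Y
        c12 = loop_saddle_node_curve(2, 3, np.geomspace(0.2, 5, 101))
        c21 = loop_saddle_node_curve(3, 2, c12["Y"])
        assert np.allclose(c21["eta1"], c12["eta2"], rtol=1e-9)
        assert np.allclose(c21["eta2"], c12["eta1"], rtol=1e-9)

    def test_rejects_mixed_signs(self):
        with pytest.raises(ValueError):
            loop_saddle_node_curve(2, -2)


class TestHopf:
    def test_mean_delay_examples(self):
        assert loop_hopf_mean_delay(2, -2, 1.0, k=0) == pytest.approx(math.pi / 4, abs=1e-12)
        assert loop_hopf_mean_delay(2, 2, 1.0, k=1) == pytest.approx(3 * math.pi / 4, abs=1e-12)

    def test_zero_delay_arm_admissible(self):
        # a mixed loop can oscillate with one instantaneous arm as long as
        # the delay sum matches the mean-delay relation
        pt = loop_hopf_point(2, -2, 1.0, x=0.5, k=0, delta_gamma=-2 * math.pi / 4)
        assert pt.gamma1 == pytest.approx(0.0, abs=1e-12)
        assert pt.mean_delay == pytest.approx(math.pi / 4, abs=1e-12)

    def test_curve_points_consistent(self):
        pts = loop_hopf_curve(2, -2, np.linspace(0.5, 1.3, 9), x=0.5, k=0)
        for pt in pts:
            assert pt.mean_delay == pytest.approx(
                loop_hopf_mean_delay(2, -2, pt.omega, k=0), abs=1e-12
            )
            assert pt.eta1 > 0 and pt.eta2 > 0

    def test_phase_relation(self):
        assert loop_phase_offset(2, -2, 2.0, 2.0, 1.0) == pytest.approx(math.pi / 2)
        assert loop_phase_offset(2, 2, 3.0, 1.0, 0.7) == pytest.approx(0.7)


class TestClassification:
    @pytest.mark.parametrize(
        "p, label",
        [
            (LoopParams(3, 3, 2, 2, 1, 1), "bistable"),
            (LoopParams(1, 1, 2, 2, 1, 1), "monostable"),
            (LoopParams(5, 5, 2, -2, 2, 2), "oscillatory"),
            (LoopParams(5, 5, 2, -2, 0.1, 0.1), "monostable"),
            (LoopParams(3, 3, -2, -2, 1, 1), "bistable"),
        ],
    )
    def test_labels(self, p, label):
        assert classify_loop_analytic(p)["label"] == label

    def test_depends_only_on_mean_delay(self):
        # splitting the delays any way around the same mean cannot change
        # the verdict
        for eta in (3.0, 5.0, 8.0):
            for mean in (0.5, 1.5, 3.0):
                labels = set()
                for frac in (0.0, 0.3, 1.0):
                    g1 = 2 * mean * frac
                    g2 = 2 * mean - g1
                    labels.add(
                        classify_loop_analytic(LoopParams(eta, eta, 2, -2, g1, g2))["label"]
                    )
                assert len(labels) == 1


class TestSimulatedPhases:
    @staticmethod
    def _measure(n1, n2, eta, gamma, ic, t0, t1, dt=0.02):
        m = build_motif("loop", eta1=eta, eta2=eta, n1=n1, n2=n2, gamma1=gamma, gamma2=gamma)
        traj = integrate(m, ic, t1)
        ts, vs = resample_uniform(traj, dt, t0)
        x, y = vs[:, 0].copy(), vs[:, 1].copy()
        for v in (x, y):
            v -= np.polyval(np.polyfit(ts, v, 1), ts)
        mag = np.abs(np.fft.rfft(x))
        k = int(np.argmax(mag[1:])) + 1
        period = (ts[-1] - ts[0]) / k
        cc = np.correlate(y, x, mode="full")
        lags = (np.arange(cc.size) - (x.size - 1)) * dt
        sel = np.abs(lags) <= period * 0.55
        lag = lags[sel][np.argmax(cc[sel])]
        return 2 * math.pi * lag / period, period

    def test_mixed_loop_quarter_period(self):
        phase, _ = self._measure(2, -2, 5, 2, [0.5, 0.25], 60, 120)
        assert abs(abs(phase) - math.pi / 2) < 0.1 * 2 * math.pi

    def test_two_repressors_synchronous_transient(self):
        fps = loop_fixed_points(LoopParams(5, 5, 2, 2, 3, 3))
        s = [f for f in fps if abs(f["X"] - f["Y"]) < 1e-6][0]["X"]
        phase, _ = self._measure(2, 2, 5, 3, [s * 1.05, s * 1.0502], 10, 60)
        assert abs(phase) < 0.1 * 2 * math.pi

    def test_two_activators_antisynchronous_transient(self):
        fps = loop_fixed_points(LoopParams(5, 5, -2, -2, 5, 5))
        s = [f for f in fps if 0 < f["X"] < 1][0]["X"]
        phase, _ = self._measure(-2, -2, 5, 5, [s * 1.02, s * 0.98], 20, 65)
        assert abs(abs(phase) - math.pi) < 0.1 * 2 * math.pi

    def test_relay_degenerate_smoke(self):
        # one near-instantaneous relay node: the loop behaves like delayed
        # autoregulation of the slow node (smoke check: oscillation onset
        # needs the delay, as in one-node repression)
        osc = classify_loop_analytic(LoopParams(10, 30, 2, -9, 4, 0))
        no_delay = classify_loop_analytic(LoopParams(10, 30, 2, -9, 0.05, 0))
        assert osc["label"] != "bistable"
        assert no_delay["label"] == "monostable"
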