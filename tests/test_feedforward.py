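"""Feedforward closed forms against quadrature oracles and simulation."""

import math

import numpy as np
import pytest

from ddemotifs.feedforward import (
    FFLParams,
    bandpass_scan,
    fourier_coefficients,
    frequency_response,
    response_envelope,
    step_response,
)
from ddemotifs.models import InputSignal, build_motif
from ddemotifs.solver import integrate, resample_uniform

FIG_PARAMS = dict(eta1=0.9, eta2=0.7, n1=2, n2=-2, K=1.0)


class TestStepResponse:
    def test_steady_state_from_zero_baseline(self):
        p = FFLParams(**FIG_PARAMS, delta_gamma=4.0)
        sr = step_response(p, X0=0.0, etaX=6.0, w=10.0)
        assert sr.Z_ss == pytest.approx(0.9)  # repressor arm on, activator arm off

    def test_window_function_zero_before_pulse(self):
        p = FFLParams(**FIG_PARAMS, delta_gamma=4.0)
        sr = step_response(p, X0=0.0, etaX=6.0, w=10.0)
        assert sr.f(-3.0) == 0.0 and sr.f(0.0) == 0.0

    def test_returns_to_steady_state(self):
        p = FFLParams(**FIG_PARAMS, delta_gamma=4.0)
        sr = step_response(p, X0=0.0, etaX=6.0, w=5.0)
        assert sr(200.0) == pytest.approx(sr.Z_ss, abs=1e-12)

    @pytest.mark.parametrize(
        "X0, etaX, w",
        [
            (0.0, 6.0, 2.0),   # short on-pulse
            (0.0, 6.0, 12.0),  # long on-pulse
            (6.0, 0.0, 2.0),   # short off-pulse
            (6.0, 0.0, 12.0),  # long off-pulse
        ],
    )
    def test_matches_simulation(self, X0, etaX, w):
        p = FFLParams(**FIG_PARAMS, delta_gamma=4.0)
        sr = step_response(p, X0=X0, etaX=etaX, w=w)
        inp = InputSignal("step_pulse", X0=X0, eta_X=etaX, w=w)
        m = build_motif(**FIG_PARAMS, kind="feedforward", delta_gamma=4.0, input=inp)
        traj = integrate(m, [sr.Z_ss], 30.0, rtol=1e-8, atol=1e-11)
        ts = np.linspace(0.0, 30.0, 601)
        assert np.max(np.abs(traj(ts)[:, 0] - sr(ts))) < 1e-3

    def test_time_shift_identity(self):
        # only the difference of arm delays matters: (g1, g2) vs (0, g2-g1)
        # give the same output shifted by g1
        from ddemotifs.models import MotifSystem, Node, RegulationTerm

        inp = InputSignal("step_pulse", X0=0.0, eta_X=6.0, w=5.0)
        g1, g2 = 1.5, 5.5
        shifted = MotifSystem(
            (
                Node(
                    "Z",
                    terms=(
                        RegulationTerm(inp.name, 0.9, 2, g1),
                        RegulationTerm(inp.name, 0.7, -2, g2),
                    ),
                ),
            ),
            input=inp,
        )
        base = MotifSystem(
            (
                Node(
                    "Z",
                    terms=(
                        RegulationTerm(inp.name, 0.9, 2, 0.0),
                        RegulationTerm(inp.name, 0.7, -2, g2 - g1),
                    ),
                ),
            ),
            input=inp,
        )
        z0 = 0.9
        tr_shift = integrate(shifted, [z0], 30.0, rtol=1e-8, atol=1e-11)
        tr_base = integrate(base, [z0], 30.0, rtol=1e-8, atol=1e-11)
        ts = np.linspace(g1 + 0.5, 28.0, 300)
        assert np.max(np.abs(tr_shift(ts)[:, 0] - tr_base(ts - g1)[:, 0])) < 1e-5


class TestFourierCoefficients:
    def test_zero_amplitude_repressor(self):
        a = fourier_coefficients(0.0, 2, 4)
        assert a[0] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(a[1:], 0.0, atol=1e-10)

    @pytest.mark.parametrize("n", [1, 2, 3.5])
    @pytest.mark.parametrize("A", [0.5, 1.0, 2.0])
    def test_sign_antisymmetry(self, n, A):
        ap = fourier_coefficients(A, n, 5)
        am = fourier_coefficients(A, -n, 5)
        assert np.allclose(ap[1:] + am[1:], 0.0, atol=1e-10)
        # DC terms are complementary instead: g(-n) = 1 - g(n)
        assert ap[0] + am[0] == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_against_dense_trapezoid_oracle(self, k):
        A, n = 1.0, 2
        T = np.linspace(0.0, 2 * math.pi, 400001)
        integrand = np.cos(k * T) / (1.0 + (A * (1 + np.cos(T))) ** n)
        oracle = np.trapezoid(integrand, T) / math.pi
        assert fourier_coefficients(A, n, k)[k] == pytest.approx(oracle, abs=1e-8)


class TestFrequencyResponse:
    def test_arm_exchange_symmetry_of_magnitudes(self):
        f1 = frequency_response(FFLParams(0.9, 0.7, 2, -2, 1.0, 4.0), 1.0, 0.05)
        f2 = frequency_response(FFLParams(0.7, 0.9, -2, 2, 1.0, 4.0), 1.0, 0.05)
        assert np.allclose(f1.I, f2.I, atol=1e-12)
        assert not np.allclose(f1.phi[1:], f2.phi[1:], atol=1e-6)  # phases are not

    def test_balanced_incoherent_null(self):
        # perfectly balanced opposing arms cancel at integer multiples of
        # the inverse delay difference
        p = FFLParams(0.8, 0.8, 2, -2, 1.0, 4.0)
        null = frequency_response(p, 1.0, 1.0 / p.delta_gamma)
        assert abs(null.I[1]) < 1e-6
        # away from the null the fundamental is finite
        mid = frequency_response(p, 1.0, 0.5 / p.delta_gamma)
        assert mid.I[1] > 0.1

    def test_fundamental_on_envelope_at_commensurate_frequency(self):
        p = FFLParams(0.9, 0.7, 2, -2, 1.0, 4.0)
        for m in (1, 2):
            f = m / p.delta_gamma
            fr = frequency_response(p, 1.0, f)
            I_env, _ = fr.envelope(1)
            assert fr.I[1] == pytest.approx(I_env, rel=1e-9)

    @pytest.mark.parametrize("f", [0.02, 0.05, 0.2])
    @pytest.mark.parametrize("dg", [1.0, 4.0])
    def test_against_simulation(self, f, dg):
        p = FFLParams(**FIG_PARAMS, delta_gamma=dg)
        inp = InputSignal("sinusoid", A=1.0, f=f)
        m = build_motif(**FIG_PARAMS, kind="feedforward", delta_gamma=dg, input=inp)
        n_per = 6 if f < 0.05 else 10
        t_end = (n_per + 6) / f
        traj = integrate(m, [1.0], t_end)
        ts, vs = resample_uniform(traj, 1.0 / (f * 256), t_end - n_per / f)
        z, tt = vs[:-1, 0], ts[:-1]
        c = 2 * np.mean(z * np.cos(2 * math.pi * f * tt))
        s = 2 * np.mean(z * np.sin(2 * math.pi * f * tt))
        fr = frequency_response(p, 1.0, f)
        assert math.hypot(c, s) == pytest.approx(fr.I[1], rel=0.02)
        assert math.atan2(s, c) == pytest.approx(fr.phi[1], abs=0.02 * 2 * math.pi)

    def test_parseval_bound(self):
        # total harmonic power cannot exceed the simulated output variance
        p = FFLParams(**FIG_PARAMS, delta_gamma=4.0)
        f = 0.05
        inp = InputSignal("sinusoid", A=1.0, f=f)
        m = build_motif(**FIG_PARAMS, kind="feedforward", delta_gamma=4.0, input=inp)
        t_end = 16 / f
        traj = integrate(m, [1.0], t_end)
        _, vs = resample_uniform(traj, 1.0 / (f * 512), t_end - 8 / f)
        var = float(np.var(vs[:-1, 0]))
        fr = frequency_response(p, 1.0, f, k_max=16)
        power = 0.5 * float(np.sum(fr.I[1:] ** 2))
        assert power <= var * 1.01


class TestEnvelope:
    def test_half_magnitude_point(self):
        f = math.sqrt(3) / (2 * math.pi)
        I_env, phi_env = response_envelope(f, 1, 2.0)
        assert I_env == pytest.approx(1.0, abs=1e-12)
        _, phi_dc = response_envelope(0.0, 1, 2.0)
        assert phi_env - phi_dc == pytest.approx(math.pi / 3, abs=1e-12)

    def test_dc_limit(self):
        I_env, _ = response_envelope(0.0, 1, 1.7)
        assert I_env == 1.7

    def test_root2_point(self):
        I_env, _ = response_envelope(1.0 / (2 * math.pi), 1, 1.0)
        assert I_env == pytest.approx(1 / math.sqrt(2), abs=1e-12)


class TestBandpassScan:
    def test_incoherent_window(self):
        p = FFLParams(**FIG_PARAMS)
        f_grid = np.geomspace(1e-3, 10, 500)
        scan = bandpass_scan(p, 1.0, np.array([0.05, 1.0, 10.0]), f_grid)
        # tiny delay difference: low-pass (maximum at the lowest frequency)
        assert scan[0]["argmax_f"] == f_grid[0]
        # delay difference near one: band-pass at moderate frequency
        assert 0.1 < scan[1]["argmax_f"] < 10.0
        assert scan[1]["activates"]

    def test_coherent_always_low_pass(self):
        p = FFLParams(0.9, 0.7, 2, 2, 1.0, 0.0)
        f_grid = np.geomspace(1e-3, 10, 300)
        scan = bandpass_scan(p, 1.0, np.geomspace(0.05, 10, 12), f_grid)
        for row in scan:
            assert row["argmax_f"] == f_grid[0]

    def test_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            bandpass_scan(FFLParams(**FIG_PARAMS), 1.0, np.array([]), np.array([0.1]))
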