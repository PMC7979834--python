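"""Closed-form responses of the two-arm feedforward motif.

One input regulates one output through a fast arm (delay 0 after time
shifting) and a slow arm (delay ``delta_gamma``), with an input-scale
ratio ``K`` between the two half-maximal thresholds:

    dZ/dT = eta1/(1 + X^n1(T)) + eta2/(1 + K^n2 X^n2(T - delta_gamma)) - Z.

Because there is no feedback and the square-pulse input takes only two
values, the step response solves in closed form; under a sinusoidal input
the output is a Fourier series whose harmonic magnitudes and phases admit
universal envelopes (independent of delay difference and logic) at
frequencies commensurate with 1/delta_gamma.  Incoherent arms
(sgn n1 != sgn n2) give pulse generation and band-pass filtering;
coherent arms give low-pass filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .models import hill_rate

__all__ = [
    "FFLParams",
    "StepResponse",
    "FrequencyResponse",
    "step_response",
    "fourier_coefficients",
    "frequency_response",
    "response_envelope",
    "bandpass_scan",
]


@dataclass(frozen=True)
class FFLParams:
    eta1: float
    eta2: float
    n1: float
    n2: float
    K: float = 1.0
    delta_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.eta1 < 0 or self.eta2 < 0:
            raise ValueError("strengths must be nonnegative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.delta_gamma < 0:
            raise ValueError("delta_gamma must be nonnegative (slow arm second)")

    @property
    def coherent(self) -> bool:
        return self.n1 * self.n2 > 0


def _sgn(v: float) -> float:
    return math.copysign(1.0, v) if v != 0 else 0.0


# ---------------------------------------------------------------------------
# step response


@dataclass(frozen=True)
class StepResponse:
    """Closed-form square-pulse response; call on (arrays of) time."""

    params: FFLParams
    X0: float
    etaX: float
    w: float
    Z_ss: float
    dev1: float  # deviation magnitude of the fast arm
    dev2: float  # deviation magnitude of the slow arm

    def f(self, T):
        """Rise-and-decay window (1-e^-T)Theta(T) - (1-e^-(T-w))Theta(T-w)."""
        T = np.asarray(T, dtype=float)
        up = np.where(T > 0, 1.0 - np.exp(-np.clip(T, 0, None)), 0.0)
        dn = np.where(T > self.w, 1.0 - np.exp(-(np.clip(T - self.w, 0, None))), 0.0)
        return up - dn

    def __call__(self, T):
        p = self.params
        T = np.asarray(T, dtype=float)
        out = (
            self.Z_ss
            + _sgn(p.n1) * p.eta1 * self.dev1 * self.f(T)
            + _sgn(p.n2) * p.eta2 * self.dev2 * self.f(T - p.delta_gamma)
        )
        return out if out.shape else float(out)


def _deviation(kappa: float, n: float, etaX: float, X0: float) -> float:
    a = abs(n)
    return 1.0 / (1.0 + (kappa * etaX) ** a) - 1.0 / (1.0 + (kappa * X0) ** a)


def step_response(p: FFLParams, X0: float, etaX: float, w: float) -> StepResponse:
    """Closed-form output for a square input pulse of width ``w``.

    The input sits at ``X0`` for T < 0, jumps to ``etaX`` on (0, w) and
    returns; the output starts from its steady state and relaxes back to it
    once both arms have seen the end of the pulse.
    """
    if X0 < 0 or etaX < 0:
        raise ValueError("input levels must be nonnegative")
    if w <= 0:
        raise ValueError("pulse width must be positive")
    Z_ss = float(hill_rate(X0, p.eta1, p.n1) + hill_rate(X0, p.eta2, p.n2, K=p.K))
    return StepResponse(
        params=p,
        X0=X0,
        etaX=etaX,
        w=w,
        Z_ss=Z_ss,
        dev1=_deviation(1.0, p.n1, etaX, X0),
        dev2=_deviation(p.K, p.n2, etaX, X0),
    )


# ---------------------------------------------------------------------------
# frequency response


def fourier_coefficients(A: float, n: float, k_max: int = 16, epsrel: float = 1e-10) -> np.ndarray:
    """Fourier coefficients of the Hill term under X(T) = A (1 + cos T).

        a_k = (1/pi) Int_0^2pi cos(kT) / (1 + A^n (1+cos T)^n) dT

    Activator integrands (n < 0) are rewritten through u^|n|/(1 + u^|n|)
    with u = A (1 + cos T), so the zero-input point T = pi is regular.
    """
    if A < 0:
        raise ValueError("amplitude must be nonnegative")
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")

    a = abs(n)

    def integrand(T: float, k: int) -> float:
        u = A * (1.0 + math.cos(T))
        if n == 0:
            g = 0.5
        elif n > 0:
            g = 1.0 / (1.0 + u ** a)
        else:
            ua = u ** a
            g = ua / (1.0 + ua)
        return math.cos(k * T) * g

    out = np.empty(k_max + 1)
    for k in range(k_max + 1):
        val, err = quad(
            integrand, 0.0, 2.0 * math.pi, args=(k,), epsrel=epsrel, epsabs=1e-13, limit=400,
            points=[math.pi],
        )
        if not math.isfinite(val) or err > max(1e-8, 1e-6 * abs(val)):
            raise RuntimeError(f"quadrature failed for a_{k} (A={A}, n={n}): err={err}")
        out[k] = val / math.pi
    return out


@dataclass(frozen=True)
class FrequencyResponse:
    """Harmonic decomposition of the output under sinusoidal input."""

    params: FFLParams
    A: float
    f: float
    a1: np.ndarray  # Fourier coefficients of the fast arm, k = 0..k_max
    a2: np.ndarray  # and of the slow arm
    I: np.ndarray   # magnitudes, k = 0..k_max (I[0] is the DC term)
    phi: np.ndarray  # phases, k = 0..k_max (phi[0] = 0 by convention)

    @property
    def dc(self) -> float:
        return float(self.I[0])

    def envelope(self, k: int) -> tuple[float, float]:
        """Universal envelope (I_env, phi_env) at harmonic k."""
        I0 = self.params.eta1 * self.a1[k] + self.params.eta2 * self.a2[k]
        return response_envelope(self.f, k, I0)

    def series(self, T) -> np.ndarray:
        """Reconstructed output Z(T) from the computed harmonics."""
        T = np.asarray(T, dtype=float)
        out = np.full(T.shape, self.dc)
        for k in range(1, len(self.I)):
            out = out + self.I[k] * np.cos(2.0 * math.pi * k * self.f * T - self.phi[k])
        return out


def frequency_response(p: FFLParams, A: float, f: float, k_max: int = 16) -> FrequencyResponse:
    """Harmonic magnitudes I_k and phases phi_k of the output.

    For each harmonic k of the input frequency f,

        I_k   = sqrt((e1 a1)^2 + 2 e1 e2 cos(2 pi k f dg) a1 a2 + (e2 a2)^2)
                / sqrt(1 + (2 pi k f)^2)
        phi_k = atan2(..., ...)   (two-argument arctangent)

    with a1 = a_k^{n1}, a2 = a_k^{n2} evaluated at amplitude K*A for the
    slow arm (the input-scale ratio rescales the effective amplitude).
    The DC term is (eta1 a_0^1 + eta2 a_0^2)/2.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    a1 = fourier_coefficients(A, p.n1, k_max)
    a2 = fourier_coefficients(p.K * A, p.n2, k_max)
    dg = p.delta_gamma
    I = np.empty(k_max + 1)
    phi = np.zeros(k_max + 1)
    I[0] = (p.eta1 * a1[0] + p.eta2 * a2[0]) / 2.0
    for k in range(1, k_max + 1):
        wk = 2.0 * math.pi * k * f
        c = math.cos(wk * dg)
        s = math.sin(wk * dg)
        t1 = p.eta1 * a1[k]
        t2 = p.eta2 * a2[k]
        num = t1 * t1 + 2.0 * t1 * t2 * c + t2 * t2
        I[k] = math.sqrt(max(num, 0.0) / (1.0 + wk * wk))
        phi[k] = math.atan2(
            wk * t1 + p.eta2 * (wk * c + s) * a2[k],
            t1 + p.eta2 * (c - wk * s) * a2[k],
        )
    return FrequencyResponse(params=p, A=A, f=f, a1=a1, a2=a2, I=I, phi=phi)


def response_envelope(f: float, k: int, I0: float, phi0: float | None = None) -> tuple[float, float]:
    """Universal delay- and logic-independent envelope at harmonic k.

        I_env   = I0 / sqrt(1 + (2 pi k f)^2)
        phi_env = arctan(2 pi k f) - phi0,  phi0 = pi (sgn I0 + 1) / 2

    The magnitude halves at 2 pi k f = sqrt(3) with a phase shift of -pi/3.
    """
    if f < 0:
        raise ValueError("frequency must be nonnegative")
    wk = 2.0 * math.pi * k * f
    if phi0 is None:
        phi0 = math.pi * (_sgn(I0) + 1.0) / 2.0
    return abs(I0) / math.sqrt(1.0 + wk * wk), math.atan(wk) - phi0


def bandpass_scan(
    p: FFLParams,
    A: float,
    delta_gamma_grid: np.ndarray,
    f_grid: np.ndarray,
    k_max: int = 8,
) -> list[dict]:
    """Fundamental-harmonic response surface over delay differences.

    For each delta_gamma, tabulates max_f I_1, the frequency attaining it
    and whether the output can activate a unity-threshold reporter
    (max I_1 > 1 - <I>, with <I> the DC term).
    """
    delta_gamma_grid = np.asarray(delta_gamma_grid, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if delta_gamma_grid.size == 0 or f_grid.size == 0:
        raise ValueError("grids must be nonempty")
    # Fourier coefficients depend only on (A, n); compute once
    a1 = fourier_coefficients(A, p.n1, 1)
    a2 = fourier_coefficients(p.K * A, p.n2, 1)
    t1 = p.eta1 * a1[1]
    t2 = p.eta2 * a2[1]
    dc = (p.eta1 * a1[0] + p.eta2 * a2[0]) / 2.0
    out = []
    for dg in delta_gamma_grid:
        w = 2.0 * math.pi * f_grid
        num = t1 * t1 + 2.0 * t1 * t2 * np.cos(w * dg) + t2 * t2
        I1 = np.sqrt(np.clip(num, 0.0, None) / (1.0 + w * w))
        i = int(np.argmax(I1))
        out.append(
            {
                "delta_gamma": float(dg),
                "max_I1": float(I1[i]),
                "argmax_f": float(f_grid[i]),
                "activates": bool(I1[i] > 1.0 - dc),
            }
        )
    return out
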