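"""Analytic phase space of delayed autoregulation.

A single species regulating its own production with strength ``eta``,
signed cooperativity ``n`` and delay ``gamma`` obeys

    dX/dT = eta / (1 + X^n(T - gamma)) - X(T)        (zero leakage)

Fixed points solve ``X (1 + X^n) = eta`` (plus ``X = 0`` for activators)
and do not depend on the delay.  Linearizing about a fixed point gives the
transcendental characteristic equation

    lambda + eta M e^{-gamma lambda} + 1 = 0,
    M(X*) = n X*^{n-1} / (1 + X*^n)^2,

whose rightmost roots determine stability.  Closed-form boundaries exist
for the saddle-node bifurcation (bistability of autoactivators), the Hopf
bifurcation (sustained oscillation of autorepressors) and the spiral
boundary above which the dominant root is complex (damped oscillation).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "FixedPointSet",
    "BifurcationCurve",
    "fixed_points",
    "slope_M",
    "characteristic_roots",
    "dominant_root",
    "saddle_node_eta",
    "hopf_curve",
    "hopf_eta_min",
    "hopf_gamma_asymptote",
    "hopf_gamma_at",
    "spiral_boundary",
    "spiral_eta",
    "spiral_gamma_asymptote",
    "classify_analytic",
    "period_estimate",
]

REGION_LABELS = ("monostable", "monostable_spiral", "oscillatory", "bistable")


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple[float, ...]
    stability: tuple[str, ...]
    M: tuple[float, ...]
    dominant_root: tuple[complex, ...]


@dataclass(frozen=True)
class BifurcationCurve:
    """Parametric (gamma, eta) boundary points of one type and branch."""

    type: str  # saddle_node | hopf | spiral
    k: int
    gamma: np.ndarray
    eta: np.ndarray
    omega: np.ndarray | None = None
    asymptotes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fixed points and slopes


def slope_M(x_star: float, n: float) -> float:
    """Slope factor M(X*) = n X*^(n-1) / (1 + X*^n)^2; sign follows n."""
    if x_star < 0:
        raise ValueError("fixed point must be nonnegative")
    if x_star == 0:
        # limits of n X^(n-1)/(1+X^n)^2 as X -> 0+
        if n > 1:
            return 0.0
        if n == 1:
            return 1.0
        if n > 0:
            return math.inf
        if n == 0:
            return 0.0
        if n > -1:
            return -math.inf  # origin instability for weakly cooperative activators
        if n == -1:
            return -1.0
        return 0.0  # |n| > 1 activators: production flat at the origin
    xn = x_star ** n
    return n * x_star ** (n - 1.0) / (1.0 + xn) ** 2


def fixed_points(eta: float, n: float, epsilon: float = 0.0, gamma: float = 0.0) -> FixedPointSet:
    """All nonnegative steady states of delayed autoregulation.

    Solves ``X (1 + X^n) = eta + epsilon (1 + X^n) - ...`` in the general
    leaky form ``epsilon + eta/(1+X^n) = X``; with ``epsilon = 0`` this is
    ``X (1 + X^n) = eta`` plus the origin for activators.  Stability is read
    off the dominant characteristic root at the supplied delay.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")

    def g(x: float) -> float:
        # production minus removal at state x (x > 0)
        if n >= 0:
            return epsilon + eta / (1.0 + x ** n) - x
        p = x ** (-n)
        return epsilon + eta * p / (1.0 + p) - x

    roots: list[float] = []
    upper = epsilon + eta + 1.0
    grid = np.geomspace(1e-12, upper, 2000)
    vals = np.array([g(float(x)) for x in grid])
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(brentq(g, float(grid[i]), float(grid[i + 1]), xtol=1e-14, rtol=1e-14))
    # dedupe
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-9 * max(1.0, r):
            uniq.append(r)
    if n < 0 and epsilon == 0.0:
        uniq.insert(0, 0.0)

    Ms, doms, stab = [], [], []
    for x in uniq:
        if x == 0.0:
            # origin of an activator: production term vanishes identically
            # like X^|n|, dominant root -1 for |n| > 1 (stable), unstable
            # for |n| < 1 where M diverges
            if n <= -1:
                Ms.append(0.0)
                doms.append(complex(-1.0, 0.0))
                stab.append("stable")
            else:
                Ms.append(-math.inf)
                doms.append(complex(math.inf, 0.0))
                stab.append("unstable")
            continue
        M = slope_M(x, n)
        lam = dominant_root(eta * M, gamma)
        Ms.append(M)
        doms.append(lam)
        stab.append("stable" if lam.real < 0 else "unstable")
    return FixedPointSet(tuple(uniq), tuple(stab), tuple(Ms), tuple(doms))


# ---------------------------------------------------------------------------
# characteristic roots of lambda + a e^(-gamma lambda) + 1 = 0


def characteristic_roots(a: complex, gamma: float, count: int = 1) -> list[complex]:
    """The ``count`` rightmost roots of lambda + a e^(-gamma lambda) + 1 = 0.

    With mu = gamma (lambda + 1) the equation becomes mu e^mu =
    -a gamma e^gamma, solved exactly branch-by-branch with the Lambert W
    function; every returned root has residual below 1e-9.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if count < 1:
        raise ValueError("count must be at least 1")
    if gamma == 0.0:
        return [complex(-(1.0 + a))]
    if a == 0:
        return [complex(-1.0)]
    # log of the W argument z = -a gamma e^gamma, kept in log form so very
    # large delays do not overflow
    log_z = cmath.log(-a * gamma) + gamma
    big = log_z.real > 600.0
    z = None if big else -a * gamma * cmath.exp(gamma)
    roots: list[complex] = []
    for k in range(-(count + 2), count + 3):
        if big:
            # asymptotic branch W_k(z) = L - log(W_k(z)) iterated from
            # L = log z + 2 pi i k
            L = log_z + 2j * math.pi * k
            w = L
            for _ in range(100):
                w_new = L - cmath.log(w)
                if abs(w_new - w) < 1e-15 * abs(w_new):
                    w = w_new
                    break
                w = w_new
        else:
            w = complex(lambertw(z, k=k))
        lam = w / gamma - 1.0
        # at a root a e^(-gamma lam) = -(lam + 1); evaluate the residual via
        # the log form to avoid overflow for large gamma
        res = abs(lam + 1.0 + cmath.exp(cmath.log(complex(a)) + gamma - w))
        if res < 1e-9 * max(1.0, abs(lam)):
            roots.append(lam)
    if not roots:
        raise RuntimeError(f"no characteristic roots converged for a={a}, gamma={gamma}")
    # dedupe conjugate-duplicate W branches and order by real part
    uniq: list[complex] = []
    for r in sorted(roots, key=lambda c: (-c.real, -c.imag)):
        if not any(abs(r - u) < 1e-9 * max(1.0, abs(u)) for u in uniq):
            uniq.append(r)
    return uniq[:count]


def dominant_root(a: complex, gamma: float) -> complex:
    """Rightmost characteristic root (ties resolved to nonneg imag part)."""
    return characteristic_roots(a, gamma, count=1)[0]


# ---------------------------------------------------------------------------
# closed-form boundaries


def saddle_node_eta(n: float) -> float:
    """Bistability boundary eta = -n (-n-1)^(-(-n-1)/(-n)) for n < -1.

    Separates one from three fixed points for autoactivation; as a function
    of ``-n`` the boundary stays within [1, 2], peaking at ``-n = 2``.
    """
    if n >= -1:
        raise ValueError("bistability requires -n > 1 (autoactivation with |n| > 1)")
    m = -n
    return m * (m - 1.0) ** (-(m - 1.0) / m)


def hopf_eta_min(n: float) -> float:
    """Horizontal asymptote of the Hopf curve: minimum eta for oscillation."""
    m = abs(n)
    if m <= 1:
        raise ValueError("oscillation boundary requires |n| > 1")
    return m * (m - 1.0) ** (-(n + 1.0) / n)


def hopf_gamma_asymptote(n: float) -> float:
    """Vertical asymptote: minimum delay, approached as omega -> sqrt(n^2-1)."""
    m = abs(n)
    if m <= 1:
        raise ValueError("oscillation boundary requires |n| > 1")
    return math.acos(-1.0 / m) / math.sqrt(n * n - 1.0)


def _hopf_point(omega: float, n: float, k: int) -> tuple[float, float]:
    gamma = (-math.atan(omega) + math.pi * k) / omega
    q = abs(n) / math.sqrt(1.0 + omega * omega)
    eta = q * (q - 1.0) ** (-(n + 1.0) / n)
    return gamma, eta


def hopf_curve(n: float, k: int = 1, omega_grid: np.ndarray | None = None) -> BifurcationCurve:
    """Hopf boundary branch ``k >= 1`` parameterized by omega in (0, sqrt(n^2-1)).

        gamma(omega) = (-arctan omega + pi k) / omega
        eta(omega)   = q (q - 1)^(-(n+1)/n),  q = |n| / sqrt(1 + omega^2)
    """
    if k < 1:
        raise ValueError("biologically meaningful Hopf branches have k >= 1")
    m = abs(n)
    if m <= 1:
        raise ValueError("Hopf boundary requires |n| > 1")
    omega_max = math.sqrt(n * n - 1.0)
    if omega_grid is None:
        lo, hi = omega_max * 1e-6, omega_max * (1.0 - 1e-6)
        omega_grid = np.geomspace(lo, hi, 400)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0) or np.any(omega_grid >= omega_max):
        raise ValueError(f"omega must lie in (0, {omega_max})")
    pts = np.array([_hopf_point(float(w), n, k) for w in omega_grid])
    return BifurcationCurve(
        type="hopf",
        k=k,
        gamma=pts[:, 0],
        eta=pts[:, 1],
        omega=omega_grid,
        asymptotes={"eta_min": hopf_eta_min(n), "gamma_min": hopf_gamma_asymptote(n)},
    )


def hopf_gamma_at(eta: float, n: float, k: int = 1) -> float:
    """Critical delay on Hopf branch k at strength eta (inf below eta_min).

    eta(omega) increases monotonically from eta_min (omega -> 0) to
    infinity (omega -> sqrt(n^2-1)); invert by bisection, then map to gamma.
    """
    m = abs(n)
    if m <= 1 or eta <= hopf_eta_min(n):
        return math.inf
    omega_max = math.sqrt(n * n - 1.0)

    def f(w: float) -> float:
        return _hopf_point(w, n, k)[1] - eta

    lo, hi = omega_max * 1e-12, omega_max * (1.0 - 1e-14)
    w = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return _hopf_point(w, n, k)[0]


def spiral_gamma_asymptote(n: float) -> float:
    """Root of n gamma e^(gamma+1) = 1: below it no damped-oscillation boundary."""
    if n <= 0:
        raise ValueError("spiral boundary exists only for repressors (n > 0)")
    return float(brentq(lambda g: n * g * math.exp(g + 1.0) - 1.0, 1e-12, 10.0, rtol=8.9e-16))


def spiral_eta(n: float, gamma: float) -> float:
    """Spiral boundary eta = q (q-1)^(-(n+1)/n) with q = n gamma e^(gamma+1)."""
    if n <= 0:
        raise ValueError("spiral boundary exists only for repressors (n > 0)")
    q = n * gamma * math.exp(gamma + 1.0)
    if q <= 1.0:
        raise ValueError(f"no damped-oscillation boundary at gamma={gamma} (n gamma e^(gamma+1) <= 1)")
    return q * (q - 1.0) ** (-(n + 1.0) / n)


def spiral_boundary(n: float, gamma_grid: np.ndarray | None = None) -> BifurcationCurve:
    """Damped-oscillation boundary: above it the dominant root is complex.

    Has a vertical asymptote at the root of ``n gamma e^(gamma+1) = 1`` and
    approaches ``eta = 0`` for large delay.
    """
    g0 = spiral_gamma_asymptote(n)
    if gamma_grid is None:
        gamma_grid = g0 + np.geomspace(1e-6, 20.0, 400)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(gamma_grid <= g0):
        raise ValueError(f"gamma must exceed the asymptote {g0}")
    eta = np.array([spiral_eta(n, float(g)) for g in gamma_grid])
    return BifurcationCurve(
        type="spiral",
        k=0,
        gamma=gamma_grid,
        eta=eta,
        asymptotes={"gamma_min": g0, "eta_large_gamma": 0.0},
    )


# ---------------------------------------------------------------------------
# classification and period


_BOUNDARY_TOL = 1e-9


def classify_analytic(eta: float, gamma: float, n: float) -> str:
    """Region label from the closed-form boundaries (zero-leakage regime).

    Boundary ties (within 1e-9) resolve to the less exotic label
    (monostable over spiral, spiral over oscillatory).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if n < 0:
        if n < -1 and eta > saddle_node_eta(n) + _BOUNDARY_TOL:
            return "bistable"
        return "monostable"
    if n == 0:
        return "monostable"
    # repressor
    if n > 1:
        g_hopf = hopf_gamma_at(eta, n, k=1)
        if gamma > g_hopf + _BOUNDARY_TOL:
            return "oscillatory"
    q = n * gamma * math.exp(gamma + 1.0) if gamma > 0 else 0.0
    if q > 1.0 and eta > spiral_eta(n, gamma) + _BOUNDARY_TOL:
        return "monostable_spiral"
    return "monostable"


def period_estimate(gamma: float) -> float:
    """Approximate oscillation period 2 (gamma + 1) in dimensionless time."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return 2.0 * (gamma + 1.0)
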