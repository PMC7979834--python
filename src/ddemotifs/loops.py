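"""Two-component feedback loop analytics.

Two species cross-regulate with strengths ``eta1, eta2``, signed
cooperativities ``n1, n2`` and delays ``gamma1, gamma2`` (equal degradation
rates):

    dX/dT = eta1 / (1 + Y^n1(T - gamma1)) - X
    dY/dT = eta2 / (1 + X^n2(T - gamma2)) - Y

Fixed points solve eta1 = X (1 + Y^n1), eta2 = Y (1 + X^n2) (plus the
origin for two activators).  Perturbations split into two eigenmodes
v+ = (1, R e^{i phi}) and v- = (-1, R e^{i phi}) with characteristic
equations

    Lambda_pm:  lambda +- sqrt(eta1 M1) sqrt(eta2 M2) e^{-lambda <gamma>} + 1 = 0,

where <gamma> = (gamma1 + gamma2)/2, so the onset of oscillation depends on
the delays only through their mean, while the X-Y phase offset depends on
their difference.  Saddle-node and Hopf boundaries follow in closed form,
parameterized along the constraint curve f(X, Y) = 1.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .autoreg import characteristic_roots, slope_M

__all__ = [
    "LoopParams",
    "LoopEigenmode",
    "LoopHopfPoint",
    "loop_fixed_points",
    "loop_eigenmodes",
    "loop_saddle_node_curve",
    "loop_hopf_point",
    "loop_hopf_curve",
    "loop_hopf_mean_delay",
    "loop_phase_offset",
    "classify_loop_analytic",
]


@dataclass(frozen=True)
class LoopParams:
    eta1: float
    eta2: float
    n1: float
    n2: float
    gamma1: float = 0.0
    gamma2: float = 0.0

    def __post_init__(self) -> None:
        if self.eta1 <= 0 or self.eta2 <= 0:
            raise ValueError("strengths must be positive")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("delays must be nonnegative")

    @property
    def mean_delay(self) -> float:
        return 0.5 * (self.gamma1 + self.gamma2)


@dataclass(frozen=True)
class LoopEigenmode:
    """One eigenmode at a fixed point: rightmost root, amplitude ratio, phase.

    ``phase_offset`` is the physical X-to-Y phase difference of the mode,
    arg(B/A) evaluated at its root; the mode-parity pi (synchronous vs
    anti-synchronous bookkeeping) is already contained in the ratio's sign,
    so no separate correction is applied.
    """

    mode: str  # "plus" | "minus": sign taken by the sqrt of the slope product
    lam: complex
    ratio_R: float
    phase_offset: float
    M1: float
    M2: float


# ---------------------------------------------------------------------------
# fixed points


def loop_fixed_points(p: LoopParams) -> list[dict]:
    """All nonnegative fixed points with stability.

    Reduces to a scalar equation in X: Y(X) = eta2 / (1 + X^n2), then
    requires eta1 = X (1 + Y(X)^n1); roots located by a bracketed scan.
    The origin is appended for two activators.
    """

    def Y_of_X(x: float) -> float:
        if p.n2 >= 0:
            return p.eta2 / (1.0 + x ** p.n2)
        q = x ** (-p.n2)
        return p.eta2 * q / (1.0 + q)

    def g(x: float) -> float:
        y = Y_of_X(x)
        if p.n1 >= 0:
            return p.eta1 / (1.0 + y ** p.n1) - x
        q = y ** (-p.n1)
        return p.eta1 * q / (1.0 + q) - x

    grid = np.concatenate([[1e-12], np.geomspace(1e-10, p.eta1 * (1 + 1e-9) + 1.0, 4000)])
    vals = np.array([g(float(x)) for x in grid])
    xs: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            xs.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            xs.append(brentq(g, float(grid[i]), float(grid[i + 1]), xtol=1e-14, rtol=8.9e-16))
    uniq: list[float] = []
    for r in sorted(xs):
        if not uniq or abs(r - uniq[-1]) > 1e-9 * max(1.0, r):
            uniq.append(r)

    out = []
    for x in uniq:
        y = Y_of_X(x)
        modes = loop_eigenmodes(p, (x, y))
        lam = max((m.lam for m in modes), key=lambda c: c.real)
        out.append(
            {
                "X": x,
                "Y": y,
                "stability": "stable" if lam.real < 0 else "unstable",
                "dominant_root": lam,
            }
        )
    if p.n1 < 0 and p.n2 < 0:
        # two activators: the origin is always a fixed point; production is
        # flat there for |n| > 1, giving a stable node
        stable = abs(p.n1) > 1 and abs(p.n2) > 1
        out.insert(
            0,
            {
                "X": 0.0,
                "Y": 0.0,
                "stability": "stable" if stable else "unstable",
                "dominant_root": complex(-1.0 if stable else math.inf, 0.0),
            },
        )
    if not out:
        raise RuntimeError(
            f"fixed-point scan found no roots for {p}; scanned X in (0, {p.eta1 + 1.0}]"
        )
    return out


# ---------------------------------------------------------------------------
# eigenmodes


def loop_eigenmodes(p: LoopParams, fixed_point: tuple[float, float]) -> list[LoopEigenmode]:
    """Rightmost root of each eigenmode characteristic equation at a fixed point.

    Works with the product eta1 M1 eta2 M2 and explicit mode parity: the
    plus (minus) mode uses +sqrt (-sqrt) of the product through the
    principal branch, absorbing the sign of negative products.
    """
    x, y = fixed_point
    if x < 0 or y < 0:
        raise ValueError("fixed point must be nonnegative")
    # slope of X-equation w.r.t. Y and of Y-equation w.r.t. X
    M1 = slope_M(y, p.n1)
    M2 = slope_M(x, p.n2)
    prod = (p.eta1 * M1) * (p.eta2 * M2)
    root = cmath.sqrt(complex(prod))
    mean_g = p.mean_delay
    out = []
    for mode, sgn in (("plus", +1.0), ("minus", -1.0)):
        a = sgn * root
        lam = characteristic_roots(a, mean_g, count=1)[0]
        R, phi = _mode_ratio(p, M1, M2, lam, sgn)
        out.append(
            LoopEigenmode(mode=mode, lam=lam, ratio_R=R, phase_offset=phi, M1=M1, M2=M2)
        )
    return out


def _mode_ratio(p: LoopParams, M1: float, M2: float, lam: complex, sgn: float) -> tuple[float, float]:
    # B/A from the linearized X equation: A (lambda + 1) = -eta1 M1 B e^{-lambda gamma1}
    denom = p.eta1 * M1 * cmath.exp(-lam * p.gamma1)
    if denom == 0:
        return math.nan, math.nan
    ba = -(lam + 1.0) / denom
    return abs(ba), math.atan2(ba.imag, ba.real)


def loop_phase_offset(n1: float, n2: float, gamma1: float, gamma2: float, omega: float) -> float:
    """X-Y phase difference of the oscillatory mode.

        phi = (omega/2)(gamma1 - gamma2) + (pi/4)(sgn n1 - sgn n2)

    For the minus mode an extra pi applies; for equal delays this gives
    synchronous two-repressor, anti-synchronous two-activator and
    quarter-period-shifted mixed oscillations.
    """
    return 0.5 * omega * (gamma1 - gamma2) + 0.25 * math.pi * (_sgn(n1) - _sgn(n2))


def _sgn(v: float) -> float:
    return math.copysign(1.0, v) if v != 0 else 0.0


# ---------------------------------------------------------------------------
# saddle-node boundary


def _solve_Y(n1: float, n2: float, x: float, target: float) -> float | None:
    """Solve Y^n1/(1+Y^n1) * n1 n2 X^n2/(1+X^n2) = target monotonically.

    Returns the Y > 0 with u(Y) = Y^n1/(1+Y^n1) equal to the required
    value, or None if outside (0, 1).
    """
    xn = x ** n2
    gx = xn / (1.0 + xn)  # in (0,1)
    if gx <= 0:
        return None
    need = target / (n1 * n2 * gx)
    if not (0.0 < need < 1.0):
        return None
    # u(Y) = Y^n1/(1+Y^n1) = need  ->  Y^n1 = need/(1-need)
    val = need / (1.0 - need)
    return val ** (1.0 / n1)


def loop_saddle_node_curve(
    n1: float, n2: float, x_grid: np.ndarray | None = None
) -> dict:
    """Parametric bistability boundary (eta1, eta2) for a same-sign loop.

        eta1 = n1 n2 X^{n2+1} / ((n1 n2 - 1) X^{n2} - 1)
        eta2 = n1 n2 Y^{n1+1} / ((n1 n2 - 1) Y^{n1} - 1)

    along the constraint f(X, Y) = n1 n2 X^{n2} Y^{n1} /
    ((1+X^{n2})(1+Y^{n1})) = 1, which maps X to Y monotonically.
    """
    if n1 * n2 <= 0:
        raise ValueError("saddle-node boundary requires same-sign cooperativities")
    if abs(n1 * n2) <= 1:
        raise ValueError("saddle-node boundary requires |n1 n2| > 1")
    if x_grid is None:
        x_grid = np.geomspace(1e-3, 1e3, 801)
    e1, e2, xs, ys = [], [], [], []
    for x in np.asarray(x_grid, dtype=float):
        y = _solve_Y(n1, n2, x, 1.0)
        if y is None:
            continue
        d1 = (n1 * n2 - 1.0) * x ** n2 - 1.0
        d2 = (n1 * n2 - 1.0) * y ** n1 - 1.0
        if d1 <= 0 or d2 <= 0:
            continue
        eta1 = n1 * n2 * x ** (n2 + 1.0) / d1
        eta2 = n1 * n2 * y ** (n1 + 1.0) / d2
        if eta1 <= 0 or eta2 <= 0:
            continue
        e1.append(eta1)
        e2.append(eta2)
        xs.append(x)
        ys.append(y)
    if not e1:
        raise ValueError(f"no admissible (X, Y) on the f=1 constraint for n1={n1}, n2={n2}")
    return {
        "eta1": np.array(e1),
        "eta2": np.array(e2),
        "X": np.array(xs),
        "Y": np.array(ys),
        "n1": n1,
        "n2": n2,
    }


def _saddle_eta2_of_eta1(n1: float, n2: float, eta1: float) -> float | None:
    """eta2 on the bistability boundary at a given eta1 (None if below range)."""
    curve = loop_saddle_node_curve(n1, n2, np.geomspace(1e-4, 1e4, 4001))
    order = np.argsort(curve["eta1"])
    e1 = curve["eta1"][order]
    e2 = curve["eta2"][order]
    if eta1 < e1.min() or eta1 > e1.max():
        return None
    return float(np.interp(eta1, e1, e2))


# ---------------------------------------------------------------------------
# Hopf boundary


@dataclass(frozen=True)
class LoopHopfPoint:
    omega: float
    k: int
    gamma1: float
    gamma2: float
    eta1: float
    eta2: float
    phi: float
    mean_delay: float


def loop_hopf_mean_delay(n1: float, n2: float, omega: float, k: int = 0) -> float:
    """Mean delay on the Hopf boundary at eigenfrequency omega.

        <gamma> = (1/omega)(-arctan omega + (pi/4)(2 - sgn n1 - sgn n2) + pi k)
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return (
        -math.atan(omega) + 0.25 * math.pi * (2.0 - _sgn(n1) - _sgn(n2)) + math.pi * k
    ) / omega


def loop_hopf_point(
    n1: float,
    n2: float,
    omega: float,
    x: float,
    k: int = 0,
    delta_gamma: float = 0.0,
) -> LoopHopfPoint:
    """One Hopf-boundary point at eigenfrequency omega and constraint position X.

    The delay expressions contain the eigenmode phase phi, which itself
    depends on the delay difference.  Substituting the phase relation into
    the delay expressions shows the pair is identically self-consistent for
    any delay split, so phi is computed directly from the requested
    ``delta_gamma`` = gamma1 - gamma2 (0 gives equal delays) and the
    consistency is asserted on the emitted point.
    """
    F = abs(n1 * n2) / (1.0 + omega * omega)
    if F <= 1.0:
        raise ValueError("inadmissible omega: |n1 n2| / (1 + omega^2) must exceed 1")
    # constraint |n1 n2|/(1+w^2) * X^{n2}Y^{n1}/((1+X^{n2})(1+Y^{n1})) = 1
    # inverted for u = Y^{n1}/(1+Y^{n1}) in (0, 1)
    xn = x ** n2
    need = (1.0 + omega * omega) / (abs(n1 * n2)) * (1.0 + xn) / xn
    if not (0.0 < need < 1.0):
        raise ValueError("no admissible Y on the Hopf constraint at this X and omega")
    y = (need / (1.0 - need)) ** (1.0 / n1)
    d1 = (F - 1.0) * xn - 1.0
    d2 = (F - 1.0) * y ** n1 - 1.0
    if d1 <= 0 or d2 <= 0:
        raise ValueError("no admissible strengths on the Hopf constraint at this X and omega")
    eta1 = F * x ** (n2 + 1.0) / d1
    eta2 = F * y ** (n1 + 1.0) / d2

    base = -math.atan(omega)
    s1 = 0.5 * math.pi * (1.0 - _sgn(n1))
    s2 = 0.5 * math.pi * (1.0 - _sgn(n2))
    phi = 0.5 * omega * delta_gamma + 0.25 * math.pi * (_sgn(n1) - _sgn(n2))
    g1 = (base + phi + s1 + math.pi * k) / omega
    g2 = (base - phi + s2 + math.pi * k) / omega
    # self-consistency of the phase with the emitted delay split
    phi_check = 0.5 * omega * (g1 - g2) + 0.25 * math.pi * (_sgn(n1) - _sgn(n2))
    if abs(phi_check - phi) > 1e-10 * max(1.0, abs(phi)):
        raise RuntimeError("phase/delay consistency failed on the Hopf point")
    return LoopHopfPoint(
        omega=omega,
        k=k,
        gamma1=g1,
        gamma2=g2,
        eta1=eta1,
        eta2=eta2,
        phi=phi,
        mean_delay=0.5 * (g1 + g2),
    )


def loop_hopf_curve(
    n1: float,
    n2: float,
    omega_grid: np.ndarray,
    x: float = 1.0,
    k: int = 0,
    delta_gamma: float = 0.0,
) -> list[LoopHopfPoint]:
    """Hopf-boundary points over an omega grid at fixed constraint position X."""
    out = []
    for w in np.asarray(omega_grid, dtype=float):
        try:
            out.append(loop_hopf_point(n1, n2, float(w), x, k=k, delta_gamma=delta_gamma))
        except ValueError:
            continue
    if not out:
        raise ValueError("no admissible omega in the supplied grid")
    return out


# ---------------------------------------------------------------------------
# classification


def classify_loop_analytic(p: LoopParams) -> dict:
    """Label a loop from its fixed-point structure and eigenmode roots.

    Same-sign loops: bistable beyond the saddle-node curve (with a
    transient-oscillation flag when the middle fixed point also carries an
    unstable complex pair); mixed loops: oscillatory when the unique fixed
    point has an unstable complex dominant root.
    """
    fps = loop_fixed_points(p)
    nontrivial = [fp for fp in fps if fp["X"] > 0 or fp["Y"] > 0]
    same_sign = p.n1 * p.n2 > 0
    if same_sign:
        stable = [fp for fp in fps if fp["stability"] == "stable"]
        bistable = len(stable) >= 2
        transient = False
        if bistable:
            for fp in fps:
                if fp["stability"] == "unstable" and abs(fp["dominant_root"].imag) > 1e-12:
                    transient = True
        if bistable:
            return {"label": "bistable", "transient_oscillation": transient, "fixed_points": fps}
        # a same-sign loop below the boundary settles to its single stable state
        return {"label": "monostable", "transient_oscillation": False, "fixed_points": fps}
    # mixed loop: single fixed point
    fp = nontrivial[0]
    lam = fp["dominant_root"]
    if lam.real > 0 and abs(lam.imag) > 1e-12:
        return {"label": "oscillatory", "transient_oscillation": False, "fixed_points": fps}
    return {"label": "monostable", "transient_oscillation": False, "fixed_points": fps}
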