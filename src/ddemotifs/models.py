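"""Unified signed-Hill regulation and motif construction.

Regulation of a target by a source concentration ``x`` is written with a
single Hill term whose signed cooperativity ``n`` selects the regulatory
mode:

* ``n > 0`` — repression, production falls with ``x``;
* ``n < 0`` — activation, production rises with ``x`` (effective
  cooperativity ``|n|``);
* ``n == 0`` — constitutive, production independent of ``x``.

In dimensionless form (concentrations in units of the half-maximal input
``k``, time in units of the degradation time ``1/beta``) a regulation edge
carries a strength ``eta``, a delay ``gamma``, an optional input-scale ratio
``K`` and the signed cooperativity ``n``; a node additionally carries a
leakage ``epsilon`` and a relative degradation-rate factor ``beta_ratio``.

Motifs are assembled as :class:`MotifSystem` objects: ordered nodes, each
with a list of delayed Hill terms whose contributions sum, plus an optional
external input signal that terms may reference instead of a node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DimensionalParams",
    "RegulationTerm",
    "Node",
    "MotifSystem",
    "InputSignal",
    "ReducedRegulation",
    "hill_rate",
    "nondimensionalize",
    "redimensionalize",
    "build_motif",
    "rhs_eval",
    "reduce_cascade",
    "total_cascade_delay",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameters of one regulation edge.

    alpha0 : leakage production rate (concentration / time)
    alpha  : maximal regulated production rate (concentration / time)
    k      : half-maximal input concentration
    beta   : first-order removal rate (1 / time)
    tau    : regulatory delay (time)
    n      : signed cooperativity (dimensionless)
    """

    alpha0: float
    alpha: float
    k: float
    beta: float
    tau: float
    n: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("half-maximal input k must be positive")
        if self.beta <= 0:
            raise ValueError("removal rate beta must be positive")
        if self.alpha0 < 0 or self.alpha < 0:
            raise ValueError("production rates must be nonnegative")
        if self.tau < 0:
            raise ValueError("delay tau must be nonnegative")


@dataclass(frozen=True)
class RegulationTerm:
    """One delayed Hill regulation edge in dimensionless form."""

    source: str
    eta: float
    n: float
    gamma: float = 0.0
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("regulation strength eta must be nonnegative")
        if self.gamma < 0:
            raise ValueError("delay gamma must be nonnegative")
        if self.K <= 0:
            raise ValueError("input-scale ratio K must be positive")


@dataclass(frozen=True)
class Node:
    """A dynamical species: leakage, relative degradation, incoming terms."""

    name: str
    epsilon: float = 0.0
    beta_ratio: float = 1.0
    terms: tuple[RegulationTerm, ...] = ()

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("leakage epsilon must be nonnegative")
        if self.beta_ratio <= 0:
            raise ValueError("beta_ratio must be positive")


@dataclass(frozen=True)
class InputSignal:
    """External input bound to a symbolic source name.

    kind:
      constant     -- X(T) = level
      exp_approach -- X' = eta_X - X from X0, X(T) = eta_X + (X0-eta_X) e^{-T}
                      for T > 0, X0 for T <= 0
      step_pulse   -- square pulse of width ``w`` from X0 up (or down) to
                      eta_X starting at T = 0
      sinusoid     -- X(T) = A (1 + cos(2 pi f T)), defined for all T
    """

    kind: str
    name: str = "X"
    level: float = 0.0
    X0: float = 0.0
    eta_X: float = 0.0
    w: float = 1.0
    A: float = 1.0
    f: float = 1.0

    _KINDS = ("constant", "exp_approach", "step_pulse", "sinusoid")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown input kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "sinusoid":
            if self.f <= 0:
                raise ValueError("sinusoid frequency f must be positive")
            if self.A < 0:
                raise ValueError("sinusoid amplitude A must be nonnegative")
        if self.kind == "step_pulse" and self.w <= 0:
            raise ValueError("pulse width w must be positive")

    def __call__(self, t):
        """Evaluate the input at (array of) times ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.broadcast_to(float(self.level), t.shape).copy()
        if self.kind == "exp_approach":
            out = self.eta_X + (self.X0 - self.eta_X) * np.exp(-np.clip(t, 0.0, None))
            return np.where(t <= 0, self.X0, out)
        if self.kind == "step_pulse":
            inside = (t > 0) & (t < self.w)
            return np.where(inside, self.eta_X, self.X0)
        # sinusoid
        return self.A * (1.0 + np.cos(2.0 * math.pi * self.f * t))

    def breakpoints(self) -> tuple[float, ...]:
        """Times at which the input is non-smooth (for mesh alignment)."""
        if self.kind == "step_pulse":
            return (0.0, self.w)
        if self.kind == "exp_approach":
            return (0.0,)
        return ()


@dataclass(frozen=True)
class MotifSystem:
    """A motif: ordered nodes with summed delayed-Hill production terms."""

    nodes: tuple[Node, ...]
    input: InputSignal | None = None

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a MotifSystem needs at least one node")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        known = set(names)
        if self.input is not None:
            known.add(self.input.name)
        for nd in self.nodes:
            for tm in nd.terms:
                if tm.source not in known:
                    raise ValueError(
                        f"term on node {nd.name!r} references unknown source {tm.source!r}"
                    )

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(nd.name for nd in self.nodes)

    @property
    def max_delay(self) -> float:
        return max((tm.gamma for nd in self.nodes for tm in nd.terms), default=0.0)

    def delays(self) -> tuple[float, ...]:
        """Sorted unique positive delays appearing in any term."""
        out = sorted({tm.gamma for nd in self.nodes for tm in nd.terms if tm.gamma > 0})
        return tuple(out)

    def index(self, name: str) -> int:
        return self.node_names.index(name)


@dataclass(frozen=True)
class ReducedRegulation:
    """Effective single-step regulation collapsing a two-step cascade."""

    alpha0_eff: float
    alpha_eff: float
    k_eff: float
    h: float
    gamma_eff: float = 0.0


# ---------------------------------------------------------------------------
# the unified Hill rate


def hill_rate(x, eta: float, n: float, K: float = 1.0, epsilon: float = 0.0):
    """Production rate ``epsilon + eta / (1 + (K x)^n)`` for signed ``n``.

    Activators (``n < 0``) are evaluated through the algebraically
    equivalent form ``epsilon + eta (Kx)^|n| / (1 + (Kx)^|n|)`` so that
    ``x = 0`` yields exactly ``epsilon`` with no division by zero.
    ``n = 0`` is constitutive: ``epsilon + eta / 2``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration x must be nonnegative")
    if eta < 0 or epsilon < 0:
        raise ValueError("eta and epsilon must be nonnegative")
    if K <= 0:
        raise ValueError("K must be positive")
    if n == 0:
        out = np.full(x.shape, epsilon + eta / 2.0)
        return out if out.shape else float(out)
    u = K * x
    if n > 0:
        out = epsilon + eta / (1.0 + u ** n)
    else:
        p = u ** (-n)  # -n = |n| > 0
        out = epsilon + eta * p / (1.0 + p)
    return out if out.shape else float(out)


def _hill_sum(u: np.ndarray, eta: float, n: float) -> np.ndarray:
    """Unchecked scalar-parameter Hill term used in compiled right-hand sides."""
    if n == 0:
        return np.full_like(u, eta / 2.0)
    if n > 0:
        return eta / (1.0 + u ** n)
    p = u ** (-n)
    return eta * p / (1.0 + p)


# ---------------------------------------------------------------------------
# nondimensionalization


def nondimensionalize(p: DimensionalParams) -> dict:
    """Convert dimensional edge parameters to (epsilon, eta, gamma, n).

    Returns the four dimensionless parameters together with the
    concentration scale ``k`` and time scale ``1/beta`` needed to undo the
    transformation.
    """
    return {
        "epsilon": p.alpha0 / (p.k * p.beta),
        "eta": p.alpha / (p.k * p.beta),
        "gamma": p.tau * p.beta,
        "n": p.n,
        "conc_scale": p.k,
        "time_scale": 1.0 / p.beta,
    }


def redimensionalize(
    epsilon: float, eta: float, gamma: float, n: float, conc_scale: float, time_scale: float
) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize`."""
    if conc_scale <= 0 or time_scale <= 0:
        raise ValueError("scales must be positive")
    beta = 1.0 / time_scale
    k = conc_scale
    return DimensionalParams(
        alpha0=epsilon * k * beta,
        alpha=eta * k * beta,
        k=k,
        beta=beta,
        tau=gamma / beta,
        n=n,
    )


# ---------------------------------------------------------------------------
# motif constructors


def _require(params: dict, kind: str, *names: str) -> list:
    vals = []
    for nm in names:
        if nm not in params:
            raise KeyError(f"motif kind {kind!r} requires parameter {nm!r}")
        vals.append(params[nm])
    return vals


def build_motif(kind: str, **params) -> MotifSystem:
    """Construct one of the canonical motifs.

    kind:
      direct          -- input X regulating one node Y (eta, n, gamma,
                         epsilon, plus an ``input`` InputSignal)
      cascade         -- X -> Y -> Z chain of non-delayed Hill steps with
                         relative degradation rates (eta_X, eta_Y, eta_Z,
                         n_X, n_Y, beta_x_ratio, beta_y_ratio)
      autoregulation  -- one node with one self-term (eta, n, gamma)
      logic           -- two inputs X, Y summed onto Z, optional reporter R
      feedforward     -- one output with two terms from one input at delays
                         0 and delta_gamma (eta1, eta2, n1, n2, K,
                         delta_gamma, input)
      loop            -- two nodes regulating each other (eta1, eta2, n1,
                         n2, gamma1, gamma2)
      double_feedback -- one node with two self-terms, K = 1 (eta1, eta2,
                         n1, n2, gamma1, gamma2)
    """
    if kind == "direct":
        eta, n = _require(params, kind, "eta", "n")
        gamma = params.get("gamma", 0.0)
        epsilon = params.get("epsilon", 0.0)
        inp = params.get("input") or InputSignal("constant", level=params.get("level", 1.0))
        node = Node("Y", epsilon=epsilon, terms=(RegulationTerm(inp.name, eta, n, gamma),))
        return MotifSystem((node,), input=inp)

    if kind == "autoregulation":
        eta, n, gamma = _require(params, kind, "eta", "n", "gamma")
        epsilon = params.get("epsilon", 0.0)
        node = Node("X", epsilon=epsilon, terms=(RegulationTerm("X", eta, n, gamma),))
        return MotifSystem((node,))

    if kind == "cascade":
        eta_X, eta_Y, eta_Z, n_X, n_Y = _require(
            params, kind, "eta_X", "eta_Y", "eta_Z", "n_X", "n_Y"
        )
        bx = params.get("beta_x_ratio", 1.0)  # beta_z / beta_x
        by = params.get("beta_y_ratio", 1.0)  # beta_z / beta_y
        gamma_y = params.get("gamma_y", 0.0)
        gamma_z = params.get("gamma_z", 0.0)
        # (beta_z/beta_x) X' = eta_X - X is encoded as epsilon=eta_X, beta_ratio=bx
        x = Node("X", epsilon=eta_X, beta_ratio=bx)
        y = Node(
            "Y", beta_ratio=by, terms=(RegulationTerm("X", eta_Y, n_X, gamma_y),)
        )
        z = Node("Z", terms=(RegulationTerm("Y", eta_Z, n_Y, gamma_z),))
        return MotifSystem((x, y, z))

    if kind == "logic":
        etaZ1, etaZ2, n1, n2 = _require(params, kind, "etaZ1", "etaZ2", "n1", "n2")
        gamma1 = params.get("gamma1", 0.0)
        gamma2 = params.get("gamma2", 0.0)
        etaX = params.get("etaX", 0.0)
        etaY = params.get("etaY", 0.0)
        nodes = [
            Node("X", epsilon=etaX),
            Node("Y", epsilon=etaY),
            Node(
                "Z",
                terms=(
                    RegulationTerm("X", etaZ1, n1, gamma1),
                    RegulationTerm("Y", etaZ2, n2, gamma2),
                ),
            ),
        ]
        if "etaR" in params:
            nodes.append(
                Node(
                    "R",
                    terms=(
                        RegulationTerm(
                            "Z", params["etaR"], params.get("n3", -20.0), params.get("gammaZ", 0.0)
                        ),
                    ),
                )
            )
        return MotifSystem(tuple(nodes))

    if kind == "feedforward":
        eta1, eta2, n1, n2, dg = _require(params, kind, "eta1", "eta2", "n1", "n2", "delta_gamma")
        if dg < 0:
            raise ValueError("delta_gamma must be nonnegative (slow arm second)")
        K = params.get("K", 1.0)
        inp = params.get("input") or InputSignal("constant", level=params.get("level", 1.0))
        node = Node(
            "Z",
            terms=(
                RegulationTerm(inp.name, eta1, n1, 0.0),
                RegulationTerm(inp.name, eta2, n2, dg, K=K),
            ),
        )
        return MotifSystem((node,), input=inp)

    if kind == "loop":
        eta1, eta2, n1, n2, g1, g2 = _require(
            params, kind, "eta1", "eta2", "n1", "n2", "gamma1", "gamma2"
        )
        x = Node("X", terms=(RegulationTerm("Y", eta1, n1, g1),))
        y = Node("Y", terms=(RegulationTerm("X", eta2, n2, g2),))
        return MotifSystem((x, y))

    if kind == "double_feedback":
        eta1, eta2, n1, n2, g1, g2 = _require(
            params, kind, "eta1", "eta2", "n1", "n2", "gamma1", "gamma2"
        )
        node = Node(
            "X",
            terms=(
                RegulationTerm("X", eta1, n1, g1),
                RegulationTerm("X", eta2, n2, g2),
            ),
        )
        return MotifSystem((node,))

    raise ValueError(
        f"unknown motif kind {kind!r}; expected one of direct, cascade, autoregulation, "
        "logic, feedforward, loop, double_feedback"
    )


# ---------------------------------------------------------------------------
# right-hand-side evaluation


def rhs_eval(
    system: MotifSystem,
    state_now: Sequence[float],
    delayed_states: dict,
    input_now: float | None = None,
) -> np.ndarray:
    """Per-node derivative given the current and delayed states.

    ``delayed_states`` maps each term (by ``(node_index, term_index)``) to
    the source value at the lagged time; terms absent from the map use the
    current state of their source.  Each node obeys

        beta_ratio * dX_i/dT = epsilon_i + sum_terms hill(source) - X_i
    """
    state_now = np.asarray(state_now, dtype=float)
    if state_now.shape[0] != len(system.nodes):
        raise ValueError("state dimension does not match node count")
    deriv = np.empty_like(state_now)
    names = system.node_names
    for i, nd in enumerate(system.nodes):
        total = nd.epsilon
        for j, tm in enumerate(nd.terms):
            if (i, j) in delayed_states:
                src_val = delayed_states[(i, j)]
            elif tm.source in names:
                src_val = state_now[names.index(tm.source)]
            elif input_now is not None:
                src_val = input_now
            else:
                raise ValueError(f"no value available for source {tm.source!r}")
            total += hill_rate(src_val, tm.eta, tm.n, tm.K)
        deriv[i] = (total - state_now[i]) / nd.beta_ratio
    return deriv


# ---------------------------------------------------------------------------
# cascade reduction


def reduce_cascade(eta_Y: float, eta_Z: float, n_X: float, n_Y: float) -> ReducedRegulation:
    """Collapse the two-step Hill cascade X -> Y -> Z to one delayed step.

    Matches the composite Hill-within-Hill regulation at X in {0, 1, inf}
    and its slope at X = 1 with a single Hill function with leakage.  The
    effective coefficient ``h`` is negatively proportional to the product of
    the individual cooperativities, so the collapsed step is activating for
    two activators or two repressors and repressive otherwise.
    """
    if eta_Y <= 0 or eta_Z <= 0:
        raise ValueError("cascade strengths must be positive")
    if n_X == 0 or n_Y == 0:
        raise ValueError("cascade reduction requires nonzero cooperativities")
    a = abs(n_Y)
    two_a = 2.0 ** a
    if two_a - 1.0 <= 1e-12 or not math.isfinite(two_a):
        raise ValueError("2^|n_Y| - 1 under/overflows; |n_Y| out of numeric range")
    sgn = 1.0 if n_Y > 0 else -1.0
    eY_a = eta_Y ** a
    alpha0 = (eta_Z / (1.0 + eY_a)) * (sgn + 1.0) / 2.0
    alpha = eta_Z * eY_a / (1.0 + eY_a)
    h = -(n_X * n_Y / 2.0) * (two_a / (two_a - 1.0))
    k_pow_h = ((two_a - 1.0) / (1.0 + eY_a)) ** sgn
    k_eff = k_pow_h ** (1.0 / h)
    return ReducedRegulation(alpha0_eff=alpha0, alpha_eff=alpha, k_eff=k_eff, h=h)


def total_cascade_delay(beta_ratio: float, gamma_steps: Sequence[float]) -> float:
    """Total effective delay of a cascade: beta_z/beta_y plus per-step delays."""
    if beta_ratio < 0 or any(g < 0 for g in gamma_steps):
        raise ValueError("delays and rate ratios must be nonnegative")
    return beta_ratio + float(sum(gamma_steps))
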