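"""Method-of-steps DDE integration with dense output.

The integrator advances an explicit embedded Runge-Kutta 2(3) pair
(Bogacki-Shampine) one step at a time, capping the step size at the
smallest positive delay so that every delayed lookup falls inside the
already-computed span (or the prescribed history for lagged times at or
below zero).  Continuous output is a per-segment cubic Hermite interpolant
built from the accepted states and one-sided derivatives, which is the
dense-output contract of classic DDE solvers of this family.

Derivative discontinuities propagate from the initial point and from input
non-smoothness through every delayed term; breakpoints up to level three
(sums of up to three delays) are inserted as mesh points so the local
polynomial model never straddles a kink.

Ensembles of independent copies of the same system (differing only in
their constant histories) can be integrated in one pass by passing a
2-D constant history of shape ``(n_nodes, n_ensemble)``; the adaptive step
is then controlled by the worst member.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable, Sequence

import numpy as np

from .models import MotifSystem, _hill_sum

__all__ = [
    "HistorySpec",
    "Trajectory",
    "CustomDDE",
    "IntegrationError",
    "integrate",
    "resample_uniform",
]


class IntegrationError(RuntimeError):
    """Step-size underflow or divergence; carries the last valid time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class HistorySpec:
    """State on (-inf, 0]: a constant vector or a callable of time.

    ``constant`` may be shape ``(n_nodes,)`` or ``(n_nodes, n_ens)`` for
    ensemble runs.  ``func(t)`` must accept a scalar ``t <= 0`` and return
    the node-state array.
    """

    constant: np.ndarray | None = None
    func: Callable[[float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if (self.constant is None) == (self.func is None):
            raise ValueError("specify exactly one of constant or func")
        if self.constant is not None:
            arr = np.atleast_1d(np.asarray(self.constant, dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValueError("history values must be finite")
            object.__setattr__(self, "constant", arr)

    def __call__(self, t: float) -> np.ndarray:
        if self.constant is not None:
            return self.constant
        return np.asarray(self.func(t), dtype=float)

    @classmethod
    def from_value(cls, value) -> "HistorySpec":
        if isinstance(value, HistorySpec):
            return value
        if callable(value):
            return cls(func=value)
        return cls(constant=np.atleast_1d(np.asarray(value, dtype=float)))


class _CompiledSystem:
    """Flattened term arrays for fast right-hand-side evaluation."""

    def __init__(self, system: MotifSystem):
        self.system = system
        names = system.node_names
        self.n_nodes = len(names)
        self.epsilon = np.array([nd.epsilon for nd in system.nodes])
        self.beta_ratio = np.array([nd.beta_ratio for nd in system.nodes])
        self.lags = list(system.delays())  # sorted unique positive delays
        lag_index = {g: i for i, g in enumerate(self.lags)}
        self.terms = []  # (target, source_idx|-1, lag_idx|-1, gamma, eta, n, K)
        input_name = system.input.name if system.input is not None else None
        for i, nd in enumerate(system.nodes):
            for tm in nd.terms:
                if tm.source == input_name and tm.source not in names:
                    src = -1
                else:
                    src = names.index(tm.source)
                lag = lag_index.get(tm.gamma, -1) if src >= 0 else -1
                self.terms.append((i, src, lag, tm.gamma, tm.eta, tm.n, tm.K))
        self.input = system.input

    def rhs(self, t: float, y: np.ndarray, delayed: list[np.ndarray]) -> np.ndarray:
        """dy/dT for state ``y`` of shape (n_nodes, n_ens).

        ``delayed[d]`` is the full state at ``t - lags[d]``.  Zero-delay
        terms read the current stage state; input-sourced terms evaluate the
        input signal analytically at the lagged time.
        """
        prod = np.repeat(self.epsilon[:, None], y.shape[1], axis=1)
        for (tgt, src, lag, gamma, eta, n, K) in self.terms:
            if src < 0:
                xv = float(self.input(t - gamma))
                prod[tgt] += _hill_sum(np.asarray(K * xv), eta, n)
            else:
                xsrc = y[src] if lag < 0 else delayed[lag][src]
                prod[tgt] += _hill_sum(K * xsrc, eta, n)
        return (prod - y) / self.beta_ratio[:, None]


@dataclass(frozen=True)
class CustomDDE:
    """A DDE given directly as ``dy/dT = rhs(t, y, delayed)``.

    ``rhs`` receives the current state ``y`` of shape (n_nodes, n_ens) and a
    list ``delayed`` of same-shaped states at ``t - lag`` for each entry of
    ``lags``.  Used for systems outside the summed-Hill motif family (e.g.
    reference linear problems in validation).
    """

    rhs: Callable[[float, np.ndarray, list], np.ndarray]
    lags: tuple[float, ...]
    node_names: tuple[str, ...] = ("X",)
    extra_breakpoints: tuple[float, ...] = ()

    def delays(self) -> tuple[float, ...]:
        return tuple(sorted({g for g in self.lags if g > 0}))


@dataclass
class Trajectory:
    """Dense, interpolable DDE solution on [0, t_end].

    ``values`` has shape (n_points, n_nodes) for single runs and
    (n_points, n_nodes, n_ens) for ensemble runs.  Evaluation at arbitrary
    times (including history times t <= 0) goes through :meth:`__call__`.
    """

    times: np.ndarray
    values: np.ndarray
    _f0: np.ndarray  # right-hand derivative at segment starts
    _f1: np.ndarray  # left-hand derivative at segment ends
    history: HistorySpec
    node_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Continuous cubic-Hermite evaluation; exact at mesh points."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr > self.t_end * (1 + 1e-12) + 1e-12):
            raise ValueError(f"time beyond trajectory end {self.t_end}")
        state_shape = self.values.shape[1:]
        out = np.empty(t_arr.shape + state_shape)
        ts = self.times
        idx = np.clip(np.searchsorted(ts, t_arr, side="right") - 1, 0, len(ts) - 2)
        for j, (tj, i) in enumerate(zip(t_arr, idx)):
            if tj <= 0:
                h = np.asarray(self.history(tj), dtype=float)
                if h.shape != state_shape and h.ndim == 1 and len(state_shape) == 2:
                    h = h[:, None]
                out[j] = np.broadcast_to(h, state_shape)
                continue
            out[j] = _hermite(
                tj, ts[i], ts[i + 1], self.values[i], self.values[i + 1], self._f0[i], self._f1[i]
            )
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    def node(self, name: str) -> np.ndarray:
        """Stored mesh values of one node."""
        return self.values[:, self.node_names.index(name)]


def _hermite(t, t0, t1, y0, y1, f0, f1):
    h = t1 - t0
    if h <= 0:
        return y0
    s = (t - t0) / h
    a = y0
    b = f0 * h
    c = 3 * (y1 - y0) - h * (2 * f0 + f1)
    d = 2 * (y0 - y1) + h * (f0 + f1)
    return a + s * (b + s * (c + s * d))


def _breakpoints(lags: Sequence[float], input_bps: Sequence[float], t_end: float) -> np.ndarray:
    base = {0.0}
    base.update(input_bps)
    pts = set()
    for b in base:
        pts.add(b)
        for level in (1, 2, 3):
            for combo in combinations_with_replacement(lags, level):
                pts.add(b + sum(combo))
    arr = sorted(p for p in pts if 0.0 < p < t_end)
    # dedupe within 1e-12 relative spacing
    out: list[float] = []
    for p in arr:
        if not out or p - out[-1] > 1e-12 * max(1.0, abs(p)):
            out.append(p)
    return np.array(out)


def integrate(
    system: MotifSystem,
    history,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_step: float | None = None,
) -> Trajectory:
    """Solve the DDE initial-history problem for ``system`` on [0, t_end].

    ``history`` may be a HistorySpec, a constant vector (one value per
    node; 2-D for ensembles), or a callable of t <= 0.  Local error is
    controlled to ``rtol``/``atol`` per component.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    hist = HistorySpec.from_value(history)
    if isinstance(system, MotifSystem):
        comp = _CompiledSystem(system)
        rhs_impl = comp.rhs
        lags = comp.lags
        n_nodes = comp.n_nodes
        node_names = system.node_names
        input_bps = system.input.breakpoints() if system.input is not None else ()
    else:
        rhs_impl = system.rhs
        lags = list(system.delays())
        n_nodes = len(system.node_names)
        node_names = tuple(system.node_names)
        input_bps = tuple(system.extra_breakpoints)

    y0 = np.asarray(hist(0.0), dtype=float)
    if y0.ndim == 1:
        y0 = y0[:, None]
        squeeze = True
    else:
        squeeze = False
    if y0.shape[0] != n_nodes:
        raise ValueError(f"history has {y0.shape[0]} components, system has {n_nodes} nodes")
    n_ens = y0.shape[1]

    def hist2d(t: float) -> np.ndarray:
        v = np.asarray(hist(t), dtype=float)
        return v[:, None] if v.ndim == 1 else v

    cap = min(lags) if lags else np.inf
    if max_step is not None:
        cap = min(cap, max_step)
    bps = _breakpoints(lags, input_bps, t_end)

    # growing storage
    ts: list[float] = [0.0]
    ys: list[np.ndarray] = [y0]
    f0s: list[np.ndarray] = []
    f1s: list[np.ndarray] = []

    def lookup(s: float) -> np.ndarray:
        """Full state at time s <= current front."""
        if s <= 0.0:
            return hist2d(s)
        i = bisect_right(ts, s) - 1
        if i >= len(f0s):  # s == current front within rounding
            return ys[-1]
        return _hermite(s, ts[i], ts[i + 1], ys[i], ys[i + 1], f0s[i], f1s[i])

    def frhs(t: float, y: np.ndarray) -> np.ndarray:
        delayed = [lookup(t - g) for g in lags]
        return rhs_impl(t, y, delayed)

    t = 0.0
    y = y0
    h = min(cap, t_end, 0.1 * (1.0 + (min(lags) if lags else 1.0)))
    bp_i = 0
    n_steps = 0
    n_rejected = 0
    while t < t_end * (1 - 1e-14):
        while bp_i < len(bps) and bps[bp_i] <= t * (1 + 1e-14) + 1e-15:
            bp_i += 1
        limit = bps[bp_i] if bp_i < len(bps) else t_end
        h = min(h, cap, limit - t)
        if h < 1e-13 * max(1.0, t):
            raise IntegrationError(f"step size underflow at t={t:.6g}", last_time=t)

        k1 = frhs(t, y)
        k2 = frhs(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = frhs(t + 0.75 * h, y + 0.75 * h * k2)
        y_new = y + h * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
        if not np.all(np.isfinite(y_new)):
            raise IntegrationError(f"non-finite state at t={t:.6g}", last_time=t)
        k4 = frhs(t + h, y_new)
        err = h * ((5.0 / 72.0) * k1 - (1.0 / 12.0) * k2 - (1.0 / 9.0) * k3 + (1.0 / 8.0) * k4)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        enorm = math.sqrt(float(np.mean((err / scale) ** 2)))
        if enorm <= 1.0:
            ts.append(t + h)
            ys.append(y_new)
            f0s.append(k1)
            f1s.append(k4)
            t += h
            y = y_new
            n_steps += 1
        else:
            n_rejected += 1
        factor = 0.9 * enorm ** (-1.0 / 3.0) if enorm > 0 else 5.0
        h = h * min(5.0, max(0.2, factor))

    times = np.array(ts)
    values = np.stack(ys)
    f0 = np.stack(f0s)
    f1 = np.stack(f1s)
    if squeeze:
        values = values[:, :, 0]
        f0 = f0[:, :, 0]
        f1 = f1[:, :, 0]
    return Trajectory(
        times=times,
        values=values,
        _f0=f0,
        _f1=f1,
        history=hist,
        node_names=node_names,
        metadata={
            "rtol": rtol,
            "atol": atol,
            "n_steps": n_steps,
            "n_rejected": n_rejected,
            "n_ens": n_ens,
        },
    )


def resample_uniform(traj: Trajectory, dt: float, t_start: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample the dense solution at t_start, t_start+dt, ... <= t_end."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_start < 0:
        raise ValueError("t_start must be nonnegative")
    n = int(math.floor((traj.t_end - t_start) / dt + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty resampling range")
    times = t_start + dt * np.arange(n)
    return times, traj(times)
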