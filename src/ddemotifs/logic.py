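"""Two-input Hill-sum logic: steady states, truth tables, gate charts.

The output integrates two inputs as a sum of independent Hill terms,

    Z* = etaZ1 / (1 + X^n1) + etaZ2 / (1 + Y^n2),

and is read out against the unity threshold (a downstream reporter with a
steep Hill term binarizes Z around 1).  Which of the 16 two-input logic
gates the motif approximates depends on only two signed parameters,
sgn(n1)*etaZ1 and sgn(n2)*etaZ2: the signs pick the quadrant (which inputs
are negated) and the strengths pick FALSE / single-input / AND-type /
OR-type behavior within it.  The two non-monotonic gates (XOR, XNOR)
cannot be realized by a monotone sum and are never emitted.

Because the two inputs are independent, delays on the two arms shift the
input histories without changing the truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import hill_rate

__all__ = [
    "LogicParams",
    "GateClass",
    "logic_steady_state",
    "truth_table",
    "classify_gate",
    "gate_chart",
    "GATE_NAMES",
]

# truth-table patterns keyed by outputs at (X,Y) in order (0,0),(0,1),(1,0),(1,1)
GATE_NAMES: dict[tuple[int, int, int, int], str] = {
    (0, 0, 0, 0): "FALSE",
    (0, 0, 0, 1): "AND",
    (0, 0, 1, 0): "X_NIMPLY_Y",   # X AND NOT Y
    (0, 0, 1, 1): "X",
    (0, 1, 0, 0): "Y_NIMPLY_X",   # Y AND NOT X
    (0, 1, 1, 1): "OR",
    (0, 1, 0, 1): "Y",
    (1, 0, 0, 0): "NOR",
    (1, 0, 1, 0): "NOT_Y",
    (1, 0, 1, 1): "Y_IMPLY_X",    # X OR NOT Y
    (1, 1, 0, 0): "NOT_X",
    (1, 1, 0, 1): "X_IMPLY_Y",    # NOT X OR Y
    (1, 1, 1, 0): "NAND",
    (1, 1, 1, 1): "TRUE",
    (0, 1, 1, 0): "XOR",
    (1, 0, 0, 1): "XNOR",
}


@dataclass(frozen=True)
class LogicParams:
    """Arm strengths/cooperativities plus optional reporter stage."""

    etaZ1: float
    etaZ2: float
    n1: float
    n2: float
    etaR: float | None = None
    n3: float = -20.0
    gammaZ: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0

    def __post_init__(self) -> None:
        if self.etaZ1 < 0 or self.etaZ2 < 0:
            raise ValueError("arm strengths must be nonnegative")


@dataclass(frozen=True)
class GateClass:
    name: str
    coords: tuple[float, float]  # (sgn(n1) etaZ1, sgn(n2) etaZ2)
    fuzzy_margin: float


def logic_steady_state(etaX: float, etaY: float, p: LogicParams):
    """Steady output Z* for settled input levels etaX, etaY."""
    if etaX < 0 or etaY < 0:
        raise ValueError("input levels must be nonnegative")
    return hill_rate(etaX, p.etaZ1, p.n1) + hill_rate(etaY, p.etaZ2, p.n2)


def truth_table(
    p: LogicParams, low: float = 0.1, high: float = 10.0
) -> tuple[int, int, int, int]:
    """Thresholded steady states over inputs {low, high}^2.

    Order: (low,low), (low,high), (high,low), (high,high); an entry is 1
    when Z* > 1.
    """
    if not (low < 1.0 < high):
        raise ValueError("need low < 1 < high")
    out = []
    for x in (low, high):
        for y in (low, high):
            out.append(int(logic_steady_state(x, y, p) > 1.0))
    return tuple(out)  # type: ignore[return-value]


def _sgn(v: float) -> int:
    return 1 if v > 0 else (-1 if v < 0 else 0)


def classify_gate(p: LogicParams, input_high: float | None = None) -> GateClass:
    """Name the gate from parameters alone (ideal saturated inputs).

    In the ideal limit an activator arm contributes 0 at low input and its
    full eta at high input; a repressor arm the reverse.  The four corner
    sums thresholded at 1 give the truth-table pattern, which fixes the
    name.  TRUE (output on for every input) additionally requires an
    explicit ``input_high``: the all-on criterion depends on how strongly
    a repressor arm can actually be shut off, i.e. on max(X^|n|).
    """
    if p.n1 == 0 or p.n2 == 0:
        raise ValueError("gate classification requires nonzero cooperativities")

    def corner(x_on: bool, y_on: bool) -> float:
        c1 = p.etaZ1 if (x_on if p.n1 < 0 else not x_on) else 0.0
        c2 = p.etaZ2 if (y_on if p.n2 < 0 else not y_on) else 0.0
        return c1 + c2

    corners = [corner(False, False), corner(False, True), corner(True, False), corner(True, True)]
    pattern = tuple(int(c > 1.0) for c in corners)
    name = GATE_NAMES[pattern]  # monotone sums can never hit XOR/XNOR
    if input_high is not None:
        if input_high <= 1:
            raise ValueError("input_high must exceed 1")
        # always-on check at finite saturated inputs: a repressor arm of
        # strength comparable to max(X^|n|) cannot be shut off
        finite = [
            float(logic_steady_state(x, y, p))
            for x in (0.0, input_high)
            for y in (0.0, input_high)
        ]
        if min(finite) > 1.0:
            name = "TRUE"
    margin = min(abs(c - 1.0) for c in corners)
    return GateClass(
        name=name,
        coords=(_sgn(p.n1) * p.etaZ1, _sgn(p.n2) * p.etaZ2),
        fuzzy_margin=margin,
    )


def gate_chart(
    s1_values: np.ndarray, s2_values: np.ndarray, input_high: float = 1e3
) -> list[tuple[float, float, str]]:
    """Gate names over a grid of signed strengths (sgn(n) eta on each axis)."""
    out = []
    for s1 in np.asarray(s1_values, dtype=float):
        for s2 in np.asarray(s2_values, dtype=float):
            if s1 == 0 or s2 == 0:
                continue
            p = LogicParams(abs(s1), abs(s2), n1=2.0 * _sgn(s1), n2=2.0 * _sgn(s2))
            out.append((float(s1), float(s2), classify_gate(p, input_high=input_high).name))
    return out
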