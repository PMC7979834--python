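"""Registered scenario fixtures: the canonical parameter sets.

Each fixture bundles a fully parameterized motif, its history and run
length, so every headline simulation is reproducible offline from a name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import InputSignal, MotifSystem, build_motif

__all__ = ["Fixture", "generate_fixture", "list_fixtures"]


@dataclass(frozen=True)
class Fixture:
    name: str
    system: MotifSystem
    history: np.ndarray
    t_end: float
    description: str
    params: dict = field(default_factory=dict)


def _fig2() -> Fixture:
    # direct repression with a rising exponential input, gamma=2, eps=0.5
    inp = InputSignal("exp_approach", X0=0.01, eta_X=6.0)
    sys_ = build_motif("direct", eta=5.5, n=2, gamma=2.0, epsilon=0.5, input=inp)
    return Fixture(
        name="fig2",
        system=sys_,
        history=np.array([0.01]),
        t_end=20.0,
        description="direct delayed repression under an exponentially approaching input",
        params={"eta": 5.5, "n": 2, "gamma": 2.0, "epsilon": 0.5, "eta_X": 6.0},
    )


def _fig3() -> Fixture:
    # three-step cascade of non-delayed activators with slower output decay
    sys_ = build_motif(
        "cascade",
        eta_X=1.5,
        eta_Y=2.17,
        eta_Z=2.17,
        n_X=-2,
        n_Y=-2,
        beta_x_ratio=0.667,  # beta_z / beta_x
        beta_y_ratio=0.667,  # beta_z / beta_y
    )
    return Fixture(
        name="fig3",
        system=sys_,
        history=np.array([0.01, 0.01, 0.01]),
        t_end=30.0,
        description="activator cascade whose output is approximated by one delayed step",
        params={
            "eta_X": 1.5,
            "eta_Y": 2.17,
            "eta_Z": 2.17,
            "n_X": -2,
            "n_Y": -2,
            "beta_ratio": 0.667,
        },
    )


def _fig5c(gate: str = "AND") -> Fixture:
    eta = 0.9 if gate == "AND" else 1.8
    sys_ = build_motif(
        "logic",
        etaZ1=eta,
        etaZ2=eta,
        n1=-2,
        n2=-2,
        etaR=2 * eta,
        n3=-20,
        etaX=0.0,
        etaY=0.0,
    )
    return Fixture(
        name=f"fig5c_{gate.lower()}",
        system=sys_,
        history=np.array([0.01, 0.01, 0.01, 0.01]),
        t_end=40.0,
        description=f"two-activator summed-Hill {gate} gate with steep reporter",
        params={"etaZ1": eta, "etaZ2": eta, "n1": -2, "n2": -2, "n3": -20, "etaR": 2 * eta},
    )


def _fig6() -> Fixture:
    inp = InputSignal("sinusoid", A=1.0, f=0.05)
    sys_ = build_motif(
        "feedforward", eta1=0.9, eta2=0.7, n1=2, n2=-2, K=1.0, delta_gamma=4.0, input=inp
    )
    return Fixture(
        name="fig6",
        system=sys_,
        history=np.array([0.9]),
        t_end=200.0,
        description="incoherent feedforward motif under sinusoidal input",
        params={
            "eta1": 0.9,
            "eta2": 0.7,
            "n1": 2,
            "n2": -2,
            "n3": -20,
            "K": 1.0,
            "delta_gamma": 4.0,
            "A": 1.0,
            "f": 0.05,
        },
    )


def _fig7(kind: str = "mixed") -> Fixture:
    presets = {
        "repressors": dict(eta1=3.0, eta2=3.0, n1=2, n2=2, gamma1=1.0, gamma2=1.0),
        "activators": dict(eta1=3.0, eta2=3.0, n1=-2, n2=-2, gamma1=1.0, gamma2=1.0),
        "mixed": dict(eta1=5.0, eta2=5.0, n1=2, n2=-2, gamma1=2.0, gamma2=2.0),
    }
    p = presets[kind]
    sys_ = build_motif("loop", **p)
    return Fixture(
        name=f"fig7_{kind}",
        system=sys_,
        history=np.array([0.5, 0.25]),
        t_end=120.0,
        description=f"two-component {kind} feedback loop",
        params=p,
    )


def _fig8() -> Fixture:
    p = dict(eta1=15.0, eta2=1.0, n1=11, n2=-3, gamma1=1.0, gamma2=11.0)
    sys_ = build_motif("double_feedback", **p)
    return Fixture(
        name="fig8",
        system=sys_,
        history=np.array([0.5]),
        t_end=2000.0,
        description="chaotic double positive/negative self-feedback",
        params=p,
    )


_REGISTRY = {
    "fig2": _fig2,
    "fig3": _fig3,
    "fig5c_and": lambda: _fig5c("AND"),
    "fig5c_or": lambda: _fig5c("OR"),
    "fig6": _fig6,
    "fig7_repressors": lambda: _fig7("repressors"),
    "fig7_activators": lambda: _fig7("activators"),
    "fig7_mixed": lambda: _fig7("mixed"),
    "fig8": _fig8,
}


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def generate_fixture(name: str) -> Fixture:
    """Return the fully parameterized registered scenario."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; registered: {', '.join(list_fixtures())}") from None
    return factory()
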