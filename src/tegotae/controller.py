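"""Tegotae-based phase dynamics for hexapod interlimb coordination.

Each leg carries one phase oscillator, dphi_i/dt = omega + f_i, with the
convention that phi in [0, pi) is swing intention and [pi, 2*pi) stance
intention.  The local feedback f_i is the partial derivative with respect to
phi_i of a Tegotae function

    T_i = sigma1 * T_i1 + sigma2 * T_i2,
    T_i1 = (-sin phi_i) * N_i,
    T_i2 = sin phi_i * (1/n_L) * sum_j k_j * N_j   (j over neighbors),

where N are vertical ground reaction forces in newtons.  T_i1 rewards
consistency between stance intention and the leg's own loading; T_i2 rewards
swinging while the neighbors support the body.  Differentiating gives

    f_i = -sigma1 * N_i * cos phi_i + sigma2 * (1/n_L sum_j k_j N_j) * cos phi_i.

There is no direct oscillator-to-oscillator coupling: all coordination is
mediated by the mechanical load distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .legs import Leg, Relation, build_topology, neighbor_set, relation_weights

__all__ = [
    "TWO_PI",
    "ControllerParams",
    "PhaseState",
    "GrfVector",
    "wrap_phase",
    "tegotae_local",
    "tegotae_neighbor",
    "feedback",
    "feedback_vector",
    "step_phases",
    "motor_targets",
    "is_swing",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap phases into the half-open interval [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


def is_swing(phi) -> np.ndarray:
    """Swing intention: 0 <= phi < pi."""
    return wrap_phase(phi) < np.pi


@dataclass(frozen=True)
class ControllerParams:
    """Controller parameters.

    omega : intrinsic angular velocity, rad/s
    sigma1, sigma2 : gains of the local and neighbor Tegotae terms, rad/(s N)
    k_a, k_p, k_c : dimensionless weights for anterior / posterior /
        contralateral neighbor forces
    A, B, B_prime : motor amplitudes in degrees (fore-aft swing, leg lift,
        stance press)
    """

    omega: float = 2.0
    sigma1: float = 0.2
    sigma2: float = 1.2
    k_a: float = 0.7
    k_p: float = 0.1
    k_c: float = 0.2
    A: float = 15.0
    B: float = 20.0
    B_prime: float = 5.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        for name in ("sigma1", "sigma2", "k_a", "k_p", "k_c", "A", "B", "B_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ControllerParams":
        return dataclasses.replace(self, **kw)


@dataclass
class PhaseState:
    """Six oscillator phases (canonical leg order) and the simulation clock."""

    phases: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        phases = np.asarray(self.phases, dtype=float)
        if phases.shape != (6,):
            raise ValueError("phases must have shape (6,)")
        self.phases = wrap_phase(phases)

    def copy(self) -> "PhaseState":
        return PhaseState(self.phases.copy(), self.t)


@dataclass
class GrfVector:
    """Per-leg ground reaction forces, newtons.

    ``n_vertical`` is the sensed quantity fed back to the controller;
    ``n_horizontal`` is an optional diagnostic (propulsion positive) that is
    never used in the coordination law.
    """

    n_vertical: np.ndarray
    n_horizontal: Optional[np.ndarray] = None

    def __post_init__(self):
        nv = np.asarray(self.n_vertical, dtype=float)
        if nv.shape != (6,):
            raise ValueError("n_vertical must have shape (6,)")
        if np.any(nv < 0):
            raise ValueError("vertical forces must be non-negative")
        self.n_vertical = nv
        if self.n_horizontal is not None:
            self.n_horizontal = np.asarray(self.n_horizontal, dtype=float)

    @classmethod
    def zeros(cls) -> "GrfVector":
        return cls(np.zeros(6))


def tegotae_local(phase: float, grf: float) -> float:
    """Local Tegotae term T_i1 = (-sin phi) * N.

    Positive when stance intention (sin phi < 0) coincides with ground
    contact (N > 0).
    """
    if grf < 0:
        raise ValueError("vertical ground reaction force must be non-negative")
    return -np.sin(phase) * grf


def tegotae_neighbor(
    phase: float,
    neighbor_grfs: Sequence[Tuple[float, Relation]],
    params: ControllerParams,
    n_L: int,
) -> float:
    """Neighbor Tegotae term T_i2 = sin phi * (1/n_L) sum_j k_j N_j.

    ``neighbor_grfs`` pairs each neighbor's vertical force with its relation
    to the target leg, which selects the weight (anterior k_a, posterior k_p,
    contralateral k_c).
    """
    weights = relation_weights(params)
    total = 0.0
    for force, relation in neighbor_grfs:
        if relation not in weights:
            raise ValueError(f"unknown neighbor relation: {relation!r}")
        total += weights[relation] * force
    return np.sin(phase) * total / n_L


def _neighbor_pressure(leg: Leg, grfs: GrfVector, params: ControllerParams,
                       amputated: Iterable[Leg] = (),
                       renormalize_nL: bool = False) -> float:
    spec = neighbor_set(leg, amputated, renormalize_nL)
    weights = relation_weights(params)
    total = 0.0
    for other, rel in spec.neighbors:
        if other in spec.amputated_neighbors:
            continue
        total += weights[rel] * grfs.n_vertical[other.index]
    return total / spec.n_L


def feedback(
    leg: Leg,
    state: PhaseState,
    grfs: GrfVector,
    params: ControllerParams,
    amputated: Iterable[Leg] = (),
    renormalize_nL: bool = False,
) -> float:
    """Sensory feedback f_i = dT_i/dphi_i for one leg, rad/s.

    Analytic form: ``-sigma1 * N_i * cos(phi_i) + sigma2 * P_i * cos(phi_i)``
    where P_i is the weighted mean neighbor force.
    """
    i = leg.index
    phi = state.phases[i]
    own = grfs.n_vertical[i]
    pressure = _neighbor_pressure(leg, grfs, params, amputated, renormalize_nL)
    return (-params.sigma1 * own + params.sigma2 * pressure) * np.cos(phi)


def feedback_vector(
    phases: np.ndarray,
    n_vertical: np.ndarray,
    params: ControllerParams,
    W: np.ndarray,
    n_L: np.ndarray,
) -> np.ndarray:
    """Vectorized feedback for all six legs given a prebuilt topology.

    ``W`` and ``n_L`` come from :func:`tegotae.legs.build_topology`.
    """
    pressure = (W @ n_vertical) / n_L
    return (params.sigma2 * pressure - params.sigma1 * n_vertical) * np.cos(phases)


def step_phases(
    state: PhaseState,
    grfs: GrfVector,
    params: ControllerParams,
    dt: float,
    amputated: Iterable[Leg] = (),
    renormalize_nL: bool = False,
    method: str = "euler",
    omega: Optional[float] = None,
) -> PhaseState:
    """Advance the oscillators one step with forces held constant (zero-order
    hold over the control step).

    ``method`` selects fixed-step explicit Euler (default) or classical RK4.
    Amputated legs are frozen.  Phases are wrapped to [0, 2*pi).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    amputated = frozenset(amputated)
    W, n_L = build_topology(params, amputated, renormalize_nL)
    omega_val = params.omega if omega is None else omega

    def rate(phases: np.ndarray) -> np.ndarray:
        return omega_val + feedback_vector(phases, grfs.n_vertical, params, W, n_L)

    phi = state.phases
    if method == "euler":
        new = phi + dt * rate(phi)
    elif method == "rk4":
        k1 = rate(phi)
        k2 = rate(phi + 0.5 * dt * k1)
        k3 = rate(phi + 0.5 * dt * k2)
        k4 = rate(phi + dt * k3)
        new = phi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ValueError(f"unknown integration method: {method!r}")
    new = wrap_phase(new)
    for leg in amputated:
        new[leg.index] = phi[leg.index]
    return PhaseState(new, state.t + dt)


def motor_targets(phase: float, params: ControllerParams) -> Tuple[float, float]:
    """Target joint angles in degrees for one leg at phase ``phase``.

    theta_yaw = -A cos(phi) sweeps the leg fore-aft; theta_roll lifts the leg
    by B sin(phi) during swing and presses it down by B' sin(phi) (negative)
    during stance.
    """
    phi = wrap_phase(phase)
    theta_yaw = -params.A * np.cos(phi)
    amp = params.B if phi < np.pi else params.B_prime
    theta_roll = amp * np.sin(phi)
    return float(theta_yaw), float(theta_roll)
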