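"""Quasi-static body surrogate generating ground reaction forces.

Replaces a physical hexapod (0.40 m x 0.30 m, 2.4 kg) with a rigid body on
six unilateral linear-spring contacts.  The commanded roll angle of each leg
sets how far its foot tip is pressed below (stance) or lifted above (swing)
the nominal ground plane; a three-degree-of-freedom (heave, pitch, roll)
equilibrium solve then distributes the body weight over the feet in contact.
Only the vertical force distribution matters to the coordination law, so
inertia, impacts and fore-aft travel are deliberately absent (treadmill
abstraction): identical inputs give bit-identical forces.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np

from .controller import ControllerParams, GrfVector, PhaseState, wrap_phase
from .legs import LEGS, Leg, Rank, Side

__all__ = [
    "BodyConfig",
    "BodyPose",
    "FootState",
    "EquilibriumResult",
    "default_attachments",
    "foot_height",
    "foot_states",
    "solve_equilibrium",
    "grf_step",
    "apply_load",
    "amputate",
    "BodySurrogate",
]

_DEG = math.pi / 180.0


def default_attachments(body_length: float = 0.40, body_width: float = 0.30
                        ) -> Dict[Leg, Tuple[float, float]]:
    """Leg attachment coordinates (x fore-aft, y lateral) about the body center.

    Fore legs at +0.15 m, middle at 0, hind at -0.15 m; left legs at
    +0.15 m lateral, right at -0.15 m.
    """
    x_by_rank = {Rank.FORE: 0.15, Rank.MIDDLE: 0.0, Rank.HIND: -0.15}
    return {
        leg: (x_by_rank[leg.rank], 0.15 if leg.side is Side.LEFT else -0.15)
        for leg in LEGS
    }


@dataclass(frozen=True)
class BodyConfig:
    """Rigid-body geometry, mass and contact properties of the surrogate."""

    body_mass: float = 2.4          # kg
    body_length: float = 0.40       # m
    body_width: float = 0.30        # m
    leg_length: float = 0.20        # m, nominal standing height
    contact_stiffness: float = 300.0  # N/m, effective vertical leg+contact compliance
    gravity: float = 9.81           # m/s^2
    load_mass: float = 0.0          # kg
    load_position: Tuple[float, float] = (0.0, 0.0)  # m, about body center
    amputated: FrozenSet[Leg] = frozenset()
    leg_attachment: Optional[Dict[Leg, Tuple[float, float]]] = None

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.load_mass < 0:
            raise ValueError("load_mass must be non-negative")
        if self.leg_attachment is None:
            object.__setattr__(self, "leg_attachment", default_attachments())
        object.__setattr__(self, "amputated", frozenset(self.amputated))

    @property
    def total_mass(self) -> float:
        return self.body_mass + self.load_mass

    @property
    def weight(self) -> float:
        return self.total_mass * self.gravity

    @property
    def center_of_mass(self) -> Tuple[float, float]:
        """Combined planar center of mass of body (at the origin) and load."""
        m = self.total_mass
        lx, ly = self.load_position
        return (self.load_mass * lx / m, self.load_mass * ly / m)

    def attachment_array(self) -> np.ndarray:
        """(6, 2) array of attachment coordinates in canonical leg order."""
        return np.array([self.leg_attachment[leg] for leg in LEGS])

    def intact(self) -> Tuple[Leg, ...]:
        return tuple(leg for leg in LEGS if leg not in self.amputated)

    def replace(self, **kw) -> "BodyConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class BodyPose:
    """Body center height above ground plus small pitch/roll angles (rad)."""

    height: float
    pitch: float = 0.0
    roll: float = 0.0

    def __post_init__(self):
        if not all(map(math.isfinite, (self.height, self.pitch, self.roll))):
            raise ValueError("pose must be finite")
        if abs(self.pitch) >= math.pi / 2 or abs(self.roll) >= math.pi / 2:
            raise ValueError("pitch/roll must lie in (-pi/2, pi/2)")


@dataclass
class FootState:
    """Commanded foot-tip geometry at the nominal (level, standing) pose.

    ``drop`` is each foot's vertical distance below its attachment point
    implied by the commanded roll angle; ``foot_z`` the resulting tip height
    at the nominal pose; ``contact`` flags feet at or below the ground plane
    (feet exactly at ground level count as contact at touchdown, phi = pi,
    but not at liftoff, phi = 0).
    """

    drop: np.ndarray       # (6,) m
    foot_z: np.ndarray     # (6,) m
    contact: np.ndarray    # (6,) bool
    theta_roll: np.ndarray  # (6,) deg


@dataclass
class EquilibriumResult:
    pose: Optional[BodyPose]
    grf: GrfVector
    fall: bool
    iterations: int = 0
    residual: float = 0.0


def _attachment_height(pose: BodyPose, x: float, y: float) -> float:
    # small-angle linear pose map; positive pitch raises the nose (+x),
    # positive roll raises the left side (+y)
    return pose.height + x * math.sin(pose.pitch) + y * math.sin(pose.roll)


def _drop_from_roll(theta_roll_deg, leg_length: float):
    """Vertical distance of the foot tip below its attachment.

    The roll servo maps to vertical clearance as drop = L * (1 - sin theta):
    theta = 0 leaves the tip exactly at ground level for a body standing at
    height L; positive theta (swing) lifts the tip, negative theta (stance)
    presses it below the nominal plane.
    """
    return leg_length * (1.0 - np.sin(np.asarray(theta_roll_deg) * _DEG))


def foot_height(theta_roll: float, config: BodyConfig, pose: BodyPose, leg: Leg) -> float:
    """Vertical foot-tip coordinate of ``leg`` (m) for a commanded roll angle
    in degrees under the given body pose.  Negative values mean penetration
    of the ground plane."""
    if leg in config.amputated:
        raise ValueError(f"leg {leg.label} is amputated")
    x, y = config.leg_attachment[leg]
    return _attachment_height(pose, x, y) - float(_drop_from_roll(theta_roll, config.leg_length))


def foot_states(state: PhaseState, params: ControllerParams, config: BodyConfig) -> FootState:
    """Commanded foot geometry for all legs at the nominal standing pose."""
    phi = wrap_phase(state.phases)
    s = np.sin(phi)
    amp = np.where(phi < np.pi, params.B, params.B_prime)
    theta_roll = amp * s
    drop = _drop_from_roll(theta_roll, config.leg_length)
    foot_z = config.leg_length - drop
    # feet exactly at ground level (theta_roll == 0) occur at both touchdown
    # (phi = pi) and liftoff (phi = 0); the boundary is resolved by intention
    contact = (foot_z < -1e-12) | ((foot_z <= 1e-12) & (phi >= np.pi))
    for leg in config.amputated:
        i = leg.index
        contact[i] = False
        foot_z[i] = np.inf
    return FootState(drop=drop, foot_z=foot_z, contact=contact, theta_roll=theta_roll)


def _solve_active_set(u, a, candidates, W, com, k, warm=None):
    """Active-set solve of the unilateral-spring equilibrium.

    Unknowns v = (height, pitch, roll); penetration_i = u_i - a_i . v with
    a_i = (1, x_i, y_i).  Active springs satisfy the linear force/moment
    balance k * sum pen_i a_i = W * (1, x_c, y_c); the active set is updated
    until penetrations and forces are sign-consistent.
    """
    c = np.array([1.0, com[0], com[1]])
    rhs_scale = W / k
    active = candidates.copy() if warm is None else (warm & candidates)
    if not active.any():
        active = candidates.copy()
    seen = set()
    v = None
    for it in range(1, 41):
        key = active.tobytes()
        if key in seen:
            break
        seen.add(key)
        A = a[active]
        M = A.T @ A
        b = A.T @ u[active] - rhs_scale * c
        try:
            v = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            v = np.linalg.lstsq(M, b, rcond=None)[0]
        pen = u - a @ v
        new_active = candidates & (pen > 1e-12)
        if not new_active.any():
            return None, None, it
        if (new_active == active).all():
            return v, pen, it
        active = new_active
    if v is None:
        return None, None, 0
    pen = u - a @ v
    return v, pen, 41


def _equilibrium_forces(drop, stance_candidates, intact_mask, a, att_x, att_y,
                        W, com, k, warm=None):
    """Two-stage unilateral equilibrium.

    Stage 1 balances the body on the stance-intention feet alone.  If their
    support region does not contain the center of mass, the body tips until
    lifted (swing) feet are pressed onto the ground, so stage 2 repeats the
    solve with every intact foot as a candidate spring.  Returns
    ``(forces, v, iterations, residual)`` or ``(None, None, iters, inf)``
    when no balanced contact state exists at all.
    """
    iters_total = 0
    for candidates in (stance_candidates, intact_mask):
        if not candidates.any():
            break
        v, pen, iters = _solve_active_set(drop, a, candidates, W, com, k, warm)
        iters_total += iters
        warm = None
        if v is None:
            continue
        n = np.where(candidates & (pen > 0), k * pen, 0.0)
        np.maximum(n, 0.0, out=n)
        res = max(abs(n.sum() - W),
                  abs(n @ att_x - W * com[0]),
                  abs(n @ att_y - W * com[1]))
        if res / W <= 1e-9:
            return n, v, iters_total, res / W
        if candidates is intact_mask:
            break
    return None, None, iters_total, math.inf


def solve_equilibrium(foot: FootState, config: BodyConfig,
                      warm_active: Optional[np.ndarray] = None) -> EquilibriumResult:
    """Find the body pose balancing weight over the feet in contact.

    Searches (height, pitch, roll) such that the unilateral spring forces
    N_i = max(0, k * penetration_i) over the contact-flagged legs satisfy
    vertical force balance and zero pitch/roll moment about the combined
    center of mass.  If the flagged contacts alone cannot support the center
    of mass the body tips onto the lifted feet and the solve is repeated with
    all intact legs as candidates.  If no contact-flagged candidates exist at
    all (every leg lifted), or no balanced state exists, the body is flagged
    as falling and all forces are zero.
    """
    candidates = foot.contact.copy()
    intact_mask = np.ones(6, dtype=bool)
    for leg in config.amputated:
        candidates[leg.index] = False
        intact_mask[leg.index] = False
    if not candidates.any():
        return EquilibriumResult(None, GrfVector.zeros(), fall=True)

    att = config.attachment_array()
    a = np.column_stack([np.ones(6), att[:, 0], att[:, 1]])
    n, v, iters, rel = _equilibrium_forces(
        foot.drop, candidates, intact_mask, a, att[:, 0], att[:, 1],
        config.weight, config.center_of_mass, config.contact_stiffness,
        warm_active)
    if n is None:
        return EquilibriumResult(None, GrfVector.zeros(), fall=True, iterations=iters)
    clamp = lambda x: max(-1.0, min(1.0, x))
    pose = BodyPose(height=float(v[0]), pitch=float(math.asin(clamp(v[1]))),
                    roll=float(math.asin(clamp(v[2]))))
    return EquilibriumResult(pose, GrfVector(n), fall=False,
                             iterations=iters, residual=rel)


def grf_step(state: PhaseState, params: ControllerParams, config: BodyConfig,
             warm_active: Optional[np.ndarray] = None,
             horizontal: bool = False) -> EquilibriumResult:
    """Map oscillator phases to ground reaction forces for one control step.

    Composes the motor targets, the foot kinematics and the quasi-static
    equilibrium solve.  With ``horizontal=True`` a diagnostic fore-aft force
    estimate (propulsion positive, proportional to the backward foot speed
    times the vertical load) is attached; it is never fed back.
    """
    foot = foot_states(state, params, config)
    result = solve_equilibrium(foot, config, warm_active)
    if horizontal:
        phi = wrap_phase(state.phases)
        nv = result.grf.n_vertical
        # theta_yaw = -A cos phi -> d(theta_yaw)/dt = A sin(phi) * phidot;
        # propulsion ~ -d(theta_yaw)/dt, normalized by the nominal sweep rate
        nh = -np.sin(phi) * nv
        result.grf.n_horizontal = nh
    return result


def apply_load(config: BodyConfig, mass: float, position: Tuple[float, float]) -> BodyConfig:
    """Add a point load of ``mass`` kg at planar ``position`` (m, about the
    body center).  An existing load is merged into an equivalent single load."""
    if mass < 0:
        raise ValueError("load mass must be non-negative")
    if mass == 0:
        return config
    m_old = config.load_mass
    m_new = m_old + mass
    px = (m_old * config.load_position[0] + mass * position[0]) / m_new
    py = (m_old * config.load_position[1] + mass * position[1]) / m_new
    return config.replace(load_mass=m_new, load_position=(px, py))


def amputate(config: BodyConfig, legs: Iterable[Leg]) -> BodyConfig:
    """Remove ``legs`` from the body: their oscillators are disabled and
    their contact forces pinned to zero.  At least three legs must remain."""
    removed = config.amputated | frozenset(legs)
    if 6 - len(removed) < 3:
        raise ValueError(
            f"amputating {sorted(l.label for l in removed)} leaves fewer than "
            "three legs; static support is infeasible")
    return config.replace(amputated=removed)


class BodySurrogate:
    """Stateful wrapper around :func:`grf_step` that warm-starts the
    equilibrium active set from the previous step.  Warm starting changes
    only the iteration count, never the solution (the quasi-static problem
    is convex with a unique force distribution)."""

    def __init__(self, config: BodyConfig):
        self.config = config
        self._active: Optional[np.ndarray] = None

    def forces(self, state: PhaseState, params: ControllerParams,
               horizontal: bool = False) -> EquilibriumResult:
        result = grf_step(state, params, self.config, self._active, horizontal)
        if not result.fall:
            self._active = result.grf.n_vertical > 0
        return result
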