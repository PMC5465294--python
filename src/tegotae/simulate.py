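"""Closed-loop simulation of the oscillator controller on the body surrogate.

Fixed-step integration (explicit Euler by default, dt = 1 ms): at each step
the quasi-static contact model is solved at the current phases, the forces
are held constant over the step (zero-order hold, as in a sensor-sampled
control loop), and the phases advance under dphi/dt = omega + f.  The
intrinsic frequency may follow a piecewise-linear schedule (speed ramp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .body import BodyConfig, _equilibrium_forces
from .controller import TWO_PI, ControllerParams, wrap_phase
from .legs import build_topology

__all__ = ["OmegaRamp", "make_omega_fn", "TrialSeries", "simulate"]


@dataclass(frozen=True)
class OmegaRamp:
    """Linear ramp of the intrinsic angular velocity over [t_start, t_end]."""

    t_start: float
    t_end: float
    omega_from: float
    omega_to: float

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("ramp must have t_end >= t_start")


def make_omega_fn(base_omega: float,
                  ramps: Sequence[OmegaRamp] = ()) -> Callable[[float], float]:
    """Piecewise-linear omega schedule; constant at base_omega before any
    ramp, at each ramp's target after it."""
    ramps = sorted(ramps, key=lambda r: r.t_start)

    def omega(t: float) -> float:
        value = base_omega
        for r in ramps:
            if t < r.t_start:
                break
            if t >= r.t_end:
                value = r.omega_to
            else:
                frac = (t - r.t_start) / max(r.t_end - r.t_start, 1e-12)
                value = r.omega_from + frac * (r.omega_to - r.omega_from)
        return value

    return omega


@dataclass
class TrialSeries:
    """Recorded time series of one closed-loop trial."""

    t: np.ndarray          # (S,)
    phases: np.ndarray     # (S, 6) rad
    forces: np.ndarray     # (S, 6) N, vertical
    feedback: np.ndarray   # (S, 6) rad/s
    omega: np.ndarray      # (S,)
    fall: np.ndarray       # (S,) bool
    dt: float              # integrator step, s
    sample_dt: float       # recording interval, s
    params: ControllerParams
    config: BodyConfig
    max_force_residual: float = 0.0  # worst relative force-balance error
    horizontal: Optional[np.ndarray] = None  # (S, 6) diagnostic N^H


def simulate(
    params: ControllerParams,
    config: BodyConfig,
    duration: float,
    initial_phases: np.ndarray,
    dt: float = 1e-3,
    omega_fn: Optional[Callable[[float], float]] = None,
    record_every: int = 5,
    method: str = "euler",
    renormalize_nL: bool = False,
    horizontal: bool = False,
) -> TrialSeries:
    """Integrate the controller/body loop for ``duration`` seconds.

    Amputated legs (from ``config``) are frozen at their initial phase and
    never bear force.  Returns samples every ``record_every`` steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")

    phi = wrap_phase(np.asarray(initial_phases, dtype=float).copy())
    if phi.shape != (6,):
        raise ValueError("initial_phases must have shape (6,)")

    amputated = config.amputated
    amp_idx = np.array([leg.index for leg in amputated], dtype=int)
    intact_mask = np.ones(6, dtype=bool)
    intact_mask[amp_idx] = False

    W_mat, n_L = build_topology(params, amputated, renormalize_nL)
    sigma1, sigma2 = params.sigma1, params.sigma2
    B, B_prime = params.B, params.B_prime
    leg_length = config.leg_length
    k = config.contact_stiffness
    weight = config.weight
    com = config.center_of_mass
    att = config.attachment_array()
    a_mat = np.column_stack([np.ones(6), att[:, 0], att[:, 1]])
    att_x, att_y = att[:, 0], att[:, 1]

    omega_fn = omega_fn or (lambda t: params.omega)

    n_steps = int(round(duration / dt))
    n_samples = n_steps // record_every + 1
    rec_t = np.empty(n_samples)
    rec_phi = np.empty((n_samples, 6))
    rec_N = np.empty((n_samples, 6))
    rec_f = np.empty((n_samples, 6))
    rec_w = np.empty(n_samples)
    rec_fall = np.zeros(n_samples, dtype=bool)
    rec_nh = np.empty((n_samples, 6)) if horizontal else None

    warm: Optional[np.ndarray] = None
    max_residual = 0.0
    t = 0.0
    sample = 0

    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown integration method: {method!r}")

    for step in range(n_steps + 1):
        # --- contact and force solve at the current phases ---
        s = np.sin(phi)
        theta = np.where(phi < math.pi, B, B_prime) * s
        drop = leg_length * (1.0 - np.sin(theta * math.pi / 180.0))
        candidates = ((theta < -1e-12) | ((theta <= 1e-12) & (phi >= math.pi))) & intact_mask
        N, _, _, rel = _equilibrium_forces(drop, candidates, intact_mask, a_mat,
                                           att_x, att_y, weight, com, k, warm)
        fall = N is None
        if fall:
            N = np.zeros(6)
            warm = None
        else:
            warm = N > 0
            if rel > max_residual:
                max_residual = rel

        omega_t = omega_fn(t)
        cos_phi = np.cos(phi)
        f = (sigma2 * (W_mat @ N) / n_L - sigma1 * N) * cos_phi
        if amp_idx.size:
            f[amp_idx] = 0.0

        if step % record_every == 0:
            rec_t[sample] = t
            rec_phi[sample] = phi
            rec_N[sample] = N
            rec_f[sample] = f
            rec_w[sample] = omega_t
            rec_fall[sample] = fall
            if horizontal:
                rec_nh[sample] = -s * N
            sample += 1
        if step == n_steps:
            break

        # --- phase update with forces held over the step ---
        if method == "euler":
            new_phi = phi + dt * (omega_t + f)
        else:  # rk4, forces frozen; only the cos(phi) factor varies
            coeff = sigma2 * (W_mat @ N) / n_L - sigma1 * N
            if amp_idx.size:
                coeff[amp_idx] = 0.0

            def rate(p):
                return omega_t + coeff * np.cos(p)

            k1 = rate(phi)
            k2 = rate(phi + 0.5 * dt * k1)
            k3 = rate(phi + 0.5 * dt * k2)
            k4 = rate(phi + dt * k3)
            new_phi = phi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        new_phi = np.mod(new_phi, TWO_PI)
        if amp_idx.size:
            new_phi[amp_idx] = phi[amp_idx]
        phi = new_phi
        t = (step + 1) * dt

    return TrialSeries(
        t=rec_t[:sample], phases=rec_phi[:sample], forces=rec_N[:sample],
        feedback=rec_f[:sample], omega=rec_w[:sample], fall=rec_fall[:sample],
        dt=dt, sample_dt=dt * record_every, params=params, config=config,
        max_force_residual=max_residual,
        horizontal=rec_nh[:sample] if horizontal else None,
    )
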