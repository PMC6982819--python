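"""Nonlinear stance dynamics of the compliant walker.

Model: a point mass rides on a massless leg made of (i) a translational
spring spanning the ankle--CoM segment (stiffness ``k_a``, rest length
``l_a``) and (ii) a rigid, off-centered curvy foot (arc radius ``R``,
ankle offset ``d`` posterior of the arc center) that rolls on the ground.
A constraint torque at the ankle keeps the foot aligned with the leg, so
the configuration reduces to two generalized coordinates: the spring
length ``s`` and the leg angle ``theta`` (clockwise-positive from
vertical).

Geometry, with ``c`` the rolling contact position::

    c = c_hs + R*(theta - theta_hs)
    ankle A = (c - d*cos(theta), R + d*sin(theta))
    CoM   P = A + s*(sin(theta), cos(theta))

Because every link is massless, the ground reaction force is a static
function of the configuration: the spring transmits its axial force, and
the ankle constraint adds the unique transverse component that balances
the massless foot's torque about the contact point.  The same balance
yields the ankle torque and the constraint force at the ankle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from comgait.slip_model.params import SlipParams, TouchdownRefs
from comgait.slip_model.types import SlipState, StanceTrajectory


class SimulationError(RuntimeError):
    """Raised when the stance integration fails (blow-up or bad initial state)."""


# ---------------------------------------------------------------------------
# Geometry and static force transmission
# ---------------------------------------------------------------------------

def contact_position(theta: float, refs: TouchdownRefs, params: SlipParams) -> float:
    return refs.c_hs + params.R * (theta - refs.theta_hs)


def com_position(
    s: float, theta: float, refs: TouchdownRefs, params: SlipParams
) -> tuple[float, float]:
    c = contact_position(theta, refs, params)
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    x = c - params.d * cos_t + s * sin_t
    y = params.R + params.d * sin_t + s * cos_t
    return x, y


def solve_configuration(
    x: float, y: float, refs: TouchdownRefs, params: SlipParams,
    theta_guess: float = 0.0,
) -> tuple[float, float]:
    """Invert the geometry: CoM position -> (s, theta) by Newton iteration."""
    R, d = params.R, params.d
    theta = theta_guess
    for _ in range(60):
        sin_t, cos_t = math.sin(theta), math.cos(theta)
        s = (y - R - d * sin_t) / cos_t
        # residual of the x-equation
        c = refs.c_hs + R * (theta - refs.theta_hs)
        g = c - d * cos_t + s * sin_t - x
        # dg/dtheta holding (x, y) fixed; ds/dtheta from the y-equation
        ds = (-d * cos_t * cos_t + (y - R - d * sin_t) * sin_t) / (cos_t * cos_t)
        dg = R + d * sin_t + ds * sin_t + s * cos_t
        step = g / dg
        theta -= step
        if abs(step) < 1e-13:
            break
    else:
        raise SimulationError("configuration solve did not converge")
    s = (y - params.R - params.d * math.sin(theta)) / math.cos(theta)
    return s, theta


def static_kinetics(
    s: float, theta: float, params: SlipParams
) -> tuple[float, float, float, float]:
    """(fx, fy, Ta, fa) transmitted to the ground at configuration (s, theta).

    Axial spring force F = k_a*(l_a - s); the transverse component at the
    CoM end follows from the massless-foot torque balance about the
    contact: f_t = F * (A-C)x(u) / (s - (A-C)x(n)).  Ankle torque
    Ta = s*f_t (extension-positive), constraint force fa = f_t.
    """
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    F = params.k_a * (params.l_a - s)
    lever_u = -(params.d + params.R * sin_t)   # (A-C) x u
    lever_n = -params.R * cos_t                # (A-C) x n
    ft = F * lever_u / (s - lever_n)
    fx = F * sin_t + ft * cos_t
    fy = F * cos_t - ft * sin_t
    ta = s * ft
    return fx, fy, ta, ft


# ---------------------------------------------------------------------------
# Equations of motion (mass-matrix form in q = (s, theta))
# ---------------------------------------------------------------------------

def _accelerations(
    s: float, theta: float, sd: float, thd: float, params: SlipParams
) -> tuple[float, float]:
    m, k, g = params.m, params.k_a, params.g
    R, d, s0 = params.R, params.d, params.l_a
    sin_t, cos_t = math.sin(theta), math.cos(theta)

    a = R * sin_t + d                       # mass-matrix off-diagonal / m
    b = R * R + d * d + s * s + 2.0 * R * (d * sin_t + s * cos_t)
    det = b - a * a                         # = (R*cos_t + s)^2

    rhs1 = k * (s0 - s) / m - g * cos_t + thd * thd * s
    lever = d * cos_t - s * sin_t
    rhs2 = (
        -2.0 * (s + R * cos_t) * sd * thd
        - R * thd * thd * lever
        - g * lever
    )
    sdd = (b * rhs1 - a * rhs2) / det
    thdd = (-a * rhs1 + rhs2) / det
    return sdd, thdd


def _rk4_step(q: np.ndarray, dt: float, params: SlipParams) -> np.ndarray:
    def deriv(state: np.ndarray) -> np.ndarray:
        s, theta, sd, thd = state
        sdd, thdd = _accelerations(s, theta, sd, thd, params)
        return np.array([sd, thd, sdd, thdd])

    k1 = deriv(q)
    k2 = deriv(q + 0.5 * dt * k1)
    k3 = deriv(q + 0.5 * dt * k2)
    k4 = deriv(q + dt * k3)
    return q + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


# ---------------------------------------------------------------------------
# Stance simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Sample:
    t: float
    q: np.ndarray


def _state_from_q(
    q: np.ndarray, refs: TouchdownRefs, params: SlipParams
) -> SlipState:
    s, theta, sd, thd = q
    x, y = com_position(s, theta, refs, params)
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    dx = sd * sin_t + thd * y
    dy = sd * cos_t - thd * (x - contact_position(theta, refs, params))
    return SlipState(
        l=s + params.R, theta=theta, x=x, y=y,
        dl=sd, dtheta=thd, dx=dx, dy=dy,
    )


def initial_state_at_touchdown(
    params: SlipParams, refs: TouchdownRefs, dx: float, dy: float
) -> SlipState:
    """Touchdown state: unloaded spring at the reference leg angle."""
    x, y = com_position(params.l_a, refs.theta_hs, refs, params)
    sin_t, cos_t = math.sin(refs.theta_hs), math.cos(refs.theta_hs)
    # invert the velocity map  (dx, dy) = (sd*sin + thd*y, sd*cos - thd*(x-c))
    c = contact_position(refs.theta_hs, refs, params)
    det = -sin_t * (x - c) - y * cos_t
    sd = (-(x - c) * dx - y * dy) / det
    thd = (-cos_t * dx + sin_t * dy) / det
    return SlipState(
        l=params.l_a + params.R, theta=refs.theta_hs, x=x, y=y,
        dl=sd, dtheta=thd, dx=dx, dy=dy,
    )


def initial_state_loaded(
    params: SlipParams,
    refs: TouchdownRefs,
    dx: float,
    dy: float,
    load_factor: float = 1.0,
) -> SlipState:
    """Touchdown state with the spring pre-compressed to ``load_factor``
    times the static weight share -- the configuration reached after a
    gradual double-support load transfer."""
    th = refs.theta_hs
    s = params.l_a - load_factor * params.m * params.g * math.cos(th) / params.k_a
    x, y = com_position(s, th, refs, params)
    sin_t, cos_t = math.sin(th), math.cos(th)
    c = contact_position(th, refs, params)
    det = -sin_t * (x - c) - y * cos_t
    sd = (-(x - c) * dx - y * dy) / det
    thd = (-cos_t * dx + sin_t * dy) / det
    return SlipState(
        l=s + params.R, theta=th, x=x, y=y, dl=sd, dtheta=thd, dx=dx, dy=dy
    )


def simulate_stance(
    params: SlipParams,
    initial: SlipState,
    refs: TouchdownRefs,
    dt: float = 1e-4,
    max_time: float = 3.0,
) -> StanceTrajectory:
    """Integrate one stance from touchdown until the vertical GRF unloads.

    Fixed-step RK4; liftoff (the first downward zero crossing of fy after
    midstance) is located by bisection to dt/100.  Raises
    :class:`SimulationError` on a non-contact initial state or a numerical
    blow-up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0, y0 = com_position(initial.l - params.R, initial.theta, refs, params)
    if abs(x0 - initial.x) > 1e-6 or abs(y0 - initial.y) > 1e-6:
        raise SimulationError(
            "initial state does not satisfy the rolling-contact geometry"
        )

    q = np.array([initial.l - params.R, initial.theta, initial.dl, initial.dtheta])
    t = 0.0
    samples = [_Sample(t, q.copy())]
    fy_prev = static_kinetics(q[0], q[1], params)[1]
    seen_midstance = q[1] >= 0.0
    n_max = int(math.ceil(max_time / dt))

    lift_t = None
    for _ in range(n_max):
        q_new = _rk4_step(q, dt, params)
        t_new = t + dt
        if not np.all(np.isfinite(q_new)) or q_new[0] <= 0.05 * params.l_a:
            raise SimulationError(
                f"stance integration blew up at t={t_new:.4f}s "
                f"(state={q_new.tolist()})"
            )
        fy_new = static_kinetics(q_new[0], q_new[1], params)[1]
        if q_new[1] >= 0.0:
            seen_midstance = True
        samples.append(_Sample(t_new, q_new.copy()))
        if seen_midstance and fy_prev > 0.0 and fy_new <= 0.0 and t > 0:
            lift_t, lift_q = _bisect_liftoff(q, t, dt, params, tol=dt / 100.0)
            samples[-1] = _Sample(lift_t, lift_q)
            break
        q, fy_prev, t = q_new, fy_new, t_new
    if lift_t is None:
        raise SimulationError("no liftoff detected within max_time")

    times = np.array([s.t for s in samples])
    states = [_state_from_q(s.q, refs, params) for s in samples]
    kin = np.array([static_kinetics(s.q[0], s.q[1], params) for s in samples])
    grf = kin[:, :2].copy()
    grf[-1, 1] = 0.0  # fy is zero at liftoff by construction
    return StanceTrajectory(
        t=times,
        states=states,
        grf=grf,
        ankle_torque=kin[:, 2],
        constraint_force=kin[:, 3],
        events={"touchdown": 0.0, "liftoff": float(times[-1])},
        params=params,
        refs=refs,
    )


def _bisect_liftoff(
    q_lo: np.ndarray, t_lo: float, dt: float, params: SlipParams, tol: float
) -> tuple[float, np.ndarray]:
    """Refine the fy zero crossing inside [t_lo, t_lo + dt] by bisection."""
    lo, hi = 0.0, dt
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        q_mid = _rk4_step(q_lo, mid, params)
        if static_kinetics(q_mid[0], q_mid[1], params)[1] > 0.0:
            lo = mid
        else:
            hi = mid
    q_hit = _rk4_step(q_lo, hi, params)
    return t_lo + hi, q_hit
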