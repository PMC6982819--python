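"""Walking-trial generation from stitched stance simulations.

One nonlinear stance of the compliant walker (started pre-loaded, as
after a gradual double-support transfer) provides the per-leg template of
forces and kinematics.  Copies of the template are placed at successive
heel strikes with a 60% duty factor; cosine load-transfer ramps split the
body weight between the overlapping legs during double support.  The
trial acceleration is the summed force over body mass (plus a short
heel-strike impact transient), so the sacrum kinematics follow from
direct integration and are exactly consistent with the summed forces.

Labels (11 channels) combine the ramped per-leg forces, joint torques
from planar inverse dynamics, and stance/swing segment angles from the
template's inverse kinematics with quintic-Hermite swing interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from comgait.inverse_dynamics import Anthropometrics, planar_inverse_dynamics
from comgait.preprocessing.filters import lowpass_filter
from comgait.slip_model import (
    SlipParams,
    TouchdownRefs,
    default_params,
    inverse_kinematics_multibody,
    simulate_stance,
)
from comgait.slip_model.dynamics import (
    SimulationError,
    initial_state_loaded,
)
from comgait.synthetic_data.noise import NoiseModel, corrupt_to_imu
from comgait.synthetic_data.trial import (
    EventTruth,
    ImuTrial,
    LabelTrack,
    StepLabels,
)

FS_TRIAL = 100.0     # IMU sampling rate [Hz]
FS_LABELS = 200.0    # internal force/label rate [Hz]


class GenerationError(RuntimeError):
    """Raised when a requested gait cannot be generated."""


@dataclass(frozen=True)
class GaitShape:
    """Template-stance shaping parameters (generation-time choices)."""

    dimensionless_k: float = 9.0
    theta_hs: float = -0.38
    vx0: float = 1.4
    vy0: float = -0.08
    load_factor: float = 1.1
    duty_factor: float = 1.2       # stance duration / step time
    hs_impact_amp: float = 2.5     # m/s^2
    hs_impact_width: float = 0.02  # s
    step_jitter_sd: float = 0.008  # fractional step-time jitter
    sim_dt: float = 5e-4

    @staticmethod
    def for_speed(speed: float) -> "GaitShape":
        theta = -(0.40 + 0.05 * (speed - 1.4))
        return GaitShape(theta_hs=float(np.clip(theta, -0.46, -0.34)))


def step_frequency(speed: float, leg_length: float = 0.845) -> float:
    """Human-like step frequency [steps/s], Froude-scaled with leg length
    so subjects of different stature walk dynamically similarly."""
    scale = math.sqrt(0.845 / leg_length)
    return 1.72 * (speed / 1.4 * scale) ** 0.45 * scale


# ---------------------------------------------------------------------------
# Template stance
# ---------------------------------------------------------------------------

@dataclass
class StanceTemplate:
    """One simulated stance resampled onto a uniform label-rate grid."""

    tau: np.ndarray       # local time from heel strike, uniform at FS_LABELS
    fx: np.ndarray
    fy: np.ndarray
    com: np.ndarray       # (n, 2) absolute, contact at x=0 at touchdown
    contact_x: np.ndarray
    thigh: np.ndarray
    shank: np.ndarray
    foot: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.tau[-1])


def _build_template(
    params: SlipParams, shape: GaitShape, time_scale: float
) -> StanceTemplate:
    refs = TouchdownRefs.from_params(params, theta_hs=shape.theta_hs, c_hs=0.0)
    init = initial_state_loaded(
        params, refs, dx=shape.vx0, dy=shape.vy0, load_factor=shape.load_factor
    )
    try:
        traj = simulate_stance(
            params, init, refs, dt=shape.sim_dt, max_time=2.5
        )
    except SimulationError as exc:
        raise GenerationError(f"template stance failed: {exc}") from exc

    theta = np.array([s.theta for s in traj.states])
    # truncate at the mirrored leg angle (toe off of the template)
    end = int(np.searchsorted(theta, -shape.theta_hs))
    end = min(max(end, 10), len(theta) - 1)

    t_src = traj.t[: end + 1] / time_scale
    n_out = max(int(math.floor(t_src[-1] * FS_LABELS)), 8)
    tau = np.arange(n_out + 1) / FS_LABELS

    def rs(values: np.ndarray) -> np.ndarray:
        return np.interp(tau, t_src, values[: end + 1])

    com = np.column_stack(
        [rs(np.array([s.x for s in traj.states])),
         rs(np.array([s.y for s in traj.states]))]
    )
    contact_x = rs(
        np.array(
            [refs.c_hs + params.R * (s.theta - refs.theta_hs)
             for s in traj.states]
        )
    )
    theta_rs = rs(theta)
    # ankle position from the rolling-foot geometry
    ankle = np.column_stack(
        [contact_x - params.d * np.cos(theta_rs),
         params.R + params.d * np.sin(theta_rs)]
    )
    thigh = np.empty(len(tau))
    shank = np.empty(len(tau))
    for i in range(len(tau)):
        ang = inverse_kinematics_multibody(com[i], ankle[i], params)
        thigh[i], shank[i] = ang.theta123[0], ang.theta123[1]
    # Resampling positions onto the stretched clock scales accelerations
    # by time_scale^2; scale the dynamic force components to match so the
    # template stays consistent with F = m*a.
    s2 = time_scale**2
    return StanceTemplate(
        tau=tau,
        fx=s2 * rs(traj.grf[:, 0]),
        fy=s2 * rs(traj.grf[:, 1]) + (1.0 - s2) * params.m * params.g,
        com=com,
        contact_x=contact_x,
        thigh=thigh,
        shank=shank,
        foot=theta_rs,
    )


# ---------------------------------------------------------------------------
# Stitching helpers
# ---------------------------------------------------------------------------

def _transfer_ramp(t: np.ndarray, start: float, stop: float, rising: bool) -> np.ndarray:
    """Cosine 0->1 (or 1->0) ramp over [start, stop], clamped outside."""
    u = np.clip((t - start) / max(stop - start, 1e-9), 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * u))
    return w if rising else 1.0 - w


def _impact_wavelet(t: np.ndarray, t_hs: float, amp: float, width: float) -> np.ndarray:
    """Derivative-of-Gaussian transient whose trough lands at ``t_hs``."""
    tau = (t - (t_hs - width)) / width
    return -amp / math.exp(-0.5) * tau * np.exp(-0.5 * tau * tau)


def _quintic_hermite(
    t: np.ndarray, t0: float, t1: float,
    v0: float, v1: float, d0: float, d1: float,
) -> np.ndarray:
    """Quintic interpolant matching values and slopes (end accelerations 0)."""
    T = max(t1 - t0, 1e-9)
    u = np.clip((t - t0) / T, 0.0, 1.0)
    h0 = 1 - 10 * u**3 + 15 * u**4 - 6 * u**5
    h1 = u - 6 * u**3 + 8 * u**4 - 3 * u**5
    g0 = 10 * u**3 - 15 * u**4 + 6 * u**5
    g1 = -4 * u**3 + 7 * u**4 - 3 * u**5
    return v0 * h0 + d0 * T * h1 + v1 * g0 + d1 * T * g1


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def generate_walking_trial(
    params: SlipParams,
    speed: float,
    n_steps: int,
    seed: int,
    shape: GaitShape | None = None,
    noise: NoiseModel | None = None,
    subject_id: str = "S1",
    speed_label: str = "moderate",
    fall_height_factor: float = 0.5,
) -> ImuTrial:
    """Generate a sacrum-acceleration trial with full ground truth.

    ``n_steps`` detection rounds are recorded (one (apex, HS, TO) triple
    each); the trial holds ``n_steps + 2`` stitched stances including a
    warm-up and tail stance.  Deterministic given ``seed``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if shape is None:
        shape = GaitShape.for_speed(speed)
    rng = np.random.default_rng(seed)

    # -- template stance, time-scaled to the target step frequency --------
    probe = _build_template(params, shape, time_scale=1.0)
    t_step_target = 1.0 / step_frequency(speed, params.l0)
    time_scale = probe.duration / (shape.duty_factor * t_step_target)
    template = _build_template(params, shape, time_scale=time_scale)
    t_stance = template.duration
    t_step = t_stance / shape.duty_factor

    # -- stance timing (stances 0 .. n_steps+1; 0 is warm-up) -------------
    n_stances = n_steps + 2
    jitter = 1.0 + shape.step_jitter_sd * rng.standard_normal(n_stances)
    jitter[0] = 1.0
    hs = np.concatenate([[0.0], np.cumsum(t_step * jitter[:-1])])
    to = hs + t_stance
    for s in range(1, n_stances):
        if hs[s] >= to[s - 1]:
            raise GenerationError(
                f"step {s}: double support vanished (timing jitter too large)"
            )

    t_end = to[-1]
    n_hi = int(math.floor(t_end * FS_LABELS)) + 1
    t_hi = np.arange(n_hi) / FS_LABELS

    # -- summed forces and per-stance load-transfer windows ---------------
    fx_tot = np.zeros(n_hi)
    fy_tot = np.zeros(n_hi)
    t_ds = t_stance - t_step  # nominal double-support duration
    step_forces: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for s in range(n_stances):
        lo = int(np.searchsorted(t_hi, hs[s]))
        hi = int(np.searchsorted(t_hi, to[s], side="right"))
        tw = t_hi[lo:hi]
        tau = tw - hs[s]
        fx_s = np.interp(tau, template.tau, template.fx)
        fy_s = np.interp(tau, template.tau, template.fy)
        up_end = to[s - 1] if s > 0 else hs[s] + t_ds
        down_start = hs[s + 1] if s + 1 < n_stances else to[s] - t_ds
        w = (
            _transfer_ramp(tw, hs[s], up_end, rising=True)
            * _transfer_ramp(tw, down_start, to[s], rising=False)
        )
        fx_w, fy_w = fx_s * w, fy_s * w
        fx_tot[lo:hi] += fx_w
        fy_tot[lo:hi] += fy_w
        step_forces.append((tw, fx_w, fy_w))

    m = params.m
    ax_hi = fx_tot / m
    ay_hi = fy_tot / m - params.g
    for s in range(1, n_stances):
        ay_hi += _impact_wavelet(
            t_hi, hs[s], shape.hs_impact_amp, shape.hs_impact_width
        )

    # steady walking: zero-mean accelerations, and no sub-gait-band
    # content (treadmill-like quasi-periodic CoM; a slow random walk in
    # the truth trajectory would be unrecoverable by any pipeline)
    ax_hi = ax_hi - np.mean(ax_hi)
    ay_hi = ay_hi - np.mean(ay_hi)
    ax_hi -= lowpass_filter(ax_hi, fs=FS_LABELS, fc=0.5, order=2)
    ay_hi -= lowpass_filter(ay_hi, fs=FS_LABELS, fc=0.5, order=2)

    vx = cumulative_trapezoid(ax_hi, t_hi, initial=0.0)
    vx += speed - np.mean(vx)
    vy = cumulative_trapezoid(ay_hi, t_hi, initial=0.0)
    vy -= np.mean(vy)
    x = cumulative_trapezoid(vx, t_hi, initial=0.0)
    y = cumulative_trapezoid(vy, t_hi, initial=0.0)
    y += params.l0 - np.mean(y)
    # Integrated height carries a slow random-walk component (as a real
    # strapdown integration would); judge falls on the gait-band
    # oscillation around the slow baseline.
    baseline = lowpass_filter(y, fs=FS_LABELS, fc=0.5, order=2)
    y_osc = y - baseline
    if np.min(y_osc) < -(1.0 - fall_height_factor) * params.l0:
        s_bad = int(np.searchsorted(hs, t_hi[int(np.argmin(y_osc))])) - 1
        raise GenerationError(
            f"fall detected: CoM height dropped below threshold at step {s_bad}"
        )

    # -- ground-truth events ----------------------------------------------
    apex_t = np.empty(n_stances)
    for s in range(n_stances):
        lo = int(np.searchsorted(t_hi, hs[s] + 0.15 * t_stance))
        hs_next = hs[s + 1] if s + 1 < n_stances else hs[s] + t_step
        hi = int(np.searchsorted(t_hi, hs[s] + 0.95 * (hs_next - hs[s])))
        apex_t[s] = t_hi[lo + int(np.argmax(y_osc[lo:hi]))]
    rounds = np.arange(1, n_steps + 1)
    truth = EventTruth(
        apex_t=apex_t[rounds], hs_t=hs[rounds + 1], to_t=to[rounds]
    )

    # -- per-leg segment-angle tracks --------------------------------------
    tracks = _angle_tracks(t_hi, hs, to, template, n_stances)

    # -- per-stance label blocks -------------------------------------------
    anthro = Anthropometrics(body_mass=params.m)
    steps = []
    for s in range(1, n_steps + 1):
        tw, fx_w, fy_w = step_forces[s]
        tau = tw - hs[s]
        hip = np.column_stack(
            [np.interp(tau, template.tau, template.com[:, 0]),
             np.interp(tau, template.tau, template.com[:, 1])]
        )
        cop = np.interp(tau, template.tau, template.contact_x)
        grf = np.column_stack([fx_w, fy_w])
        th1 = np.interp(tau, template.tau, template.thigh)
        th2 = np.interp(tau, template.tau, template.shank)
        th3 = np.interp(tau, template.tau, template.foot)
        t_ank, t_knee, t_hip = planar_inverse_dynamics(
            tw, hip, th1, th2, th3,
            lengths=(params.l1, params.l2, params.l3),
            anthro=anthro, grf=grf, cop_x=cop, g=params.g,
        )
        sl = slice(
            int(np.searchsorted(t_hi, hs[s])),
            int(np.searchsorted(t_hi, to[s], side="right")),
        )
        own, other = tracks[s % 2], tracks[(s + 1) % 2]
        values = np.vstack([
            fx_w, fy_w, t_ank, t_knee, t_hip,
            th3, th2, th1,
            other["foot"][sl], other["shank"][sl], other["thigh"][sl],
        ])
        steps.append(StepLabels(t=tw, values=values))

    # -- flat label track on the trial clock -------------------------------
    keep = slice(0, n_hi, int(round(FS_LABELS / FS_TRIAL)))
    t_trial = t_hi[keep]
    flat = _flat_label_track(t_trial, hs, steps, n_steps)
    labels = LabelTrack(t=t_trial, values=flat, steps=tuple(steps))

    trial = ImuTrial(
        subject_id=subject_id,
        speed_label=speed_label,
        fs=FS_TRIAL,
        t=t_trial,
        ax=ax_hi[keep],
        ay=ay_hi[keep],
        truth=truth,
        labels=labels,
        speed=speed,
        height=params.h,
        leg_length=params.l0,
        com=np.column_stack([x[keep], y[keep]]),
        meta={
            "seed": seed,
            "n_steps": n_steps,
            "time_scale": time_scale,
            "t_stance": t_stance,
            "t_step": t_step,
            "params": params.to_dict(),
        },
    )
    if noise is not None:
        trial = corrupt_to_imu(trial, noise)
    return trial


def _angle_tracks(
    t_hi: np.ndarray,
    hs: np.ndarray,
    to: np.ndarray,
    template: StanceTemplate,
    n_stances: int,
) -> list[dict[str, np.ndarray]]:
    """Continuous thigh/shank/foot tracks for each leg parity."""
    chans = {
        "thigh": template.thigh, "shank": template.shank, "foot": template.foot
    }
    slopes = {k: np.gradient(v, template.tau) for k, v in chans.items()}
    tracks = []
    for parity in (0, 1):
        track = {k: np.full(len(t_hi), v[0]) for k, v in chans.items()}
        own = [s for s in range(n_stances) if s % 2 == parity]
        for s in own:
            lo = int(np.searchsorted(t_hi, hs[s]))
            hi = int(np.searchsorted(t_hi, to[s], side="right"))
            tau = t_hi[lo:hi] - hs[s]
            for k, v in chans.items():
                track[k][lo:hi] = np.interp(tau, template.tau, v)
        # swing interpolation between consecutive same-leg stances
        for s_prev, s_next in zip(own, own[1:]):
            lo = int(np.searchsorted(t_hi, to[s_prev], side="right"))
            hi = int(np.searchsorted(t_hi, hs[s_next]))
            if hi <= lo:
                continue
            for k, v in chans.items():
                track[k][lo:hi] = _quintic_hermite(
                    t_hi[lo:hi], to[s_prev], hs[s_next],
                    v[-1], v[0], slopes[k][-1], slopes[k][0],
                )
        # clamp edges
        first, last = own[0], own[-1]
        lo_first = int(np.searchsorted(t_hi, hs[first]))
        hi_last = int(np.searchsorted(t_hi, to[last], side="right"))
        for k, v in chans.items():
            track[k][:lo_first] = v[0]
            track[k][hi_last:] = v[-1]
        tracks.append(track)
    return tracks


def _flat_label_track(
    t_trial: np.ndarray,
    hs: np.ndarray,
    steps: list[StepLabels],
    n_steps: int,
) -> np.ndarray:
    """Most-recent-stance assignment of the 11 channels on the trial clock."""
    flat = np.zeros((11, len(t_trial)))
    step_hs = hs[1: n_steps + 1]
    idx = np.clip(np.searchsorted(step_hs, t_trial, side="right") - 1, 0,
                  len(steps) - 1)
    for j, step in enumerate(steps):
        cols = np.nonzero(idx == j)[0]
        if len(cols):
            flat[:, cols] = step.sample(t_trial[cols])
    return flat


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

SPEED_MEANS = {"slow": 1.27, "moderate": 1.42, "fast": 1.81}


@dataclass(frozen=True)
class CohortSpec:
    """Layout of the synthetic study cohort."""

    n_subjects: int = 7
    n_steps: int = 31          # rounds per trial -> n_steps - 1 stance windows
    seed: int = 0
    subject_jitter: float = 0.10
    speed_jitter: float = 0.10
    noise: NoiseModel | None = None


def subject_parameters(spec: CohortSpec, subject: int) -> tuple[SlipParams, float]:
    """(SlipParams, speed multiplier) for one subject, deterministic."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject]))
    j = spec.subject_jitter
    scale = float(rng.uniform(1 - j, 1 + j))
    # jitter enters l0 (via stature) and k (via mass and leg length); the
    # dimensionless stiffness k*l0/(m*g) is kept fixed so every subject
    # walks with the same waveform shape at a given speed
    params = default_params(
        m=72.0 * float(rng.uniform(1 - j, 1 + j)),
        h=1.69 * scale,
        dimensionless_k=9.0,
    )
    speed_mult = float(rng.uniform(1 - spec.speed_jitter, 1 + spec.speed_jitter))
    return params, speed_mult


def generate_cohort(spec: CohortSpec | None = None) -> list[ImuTrial]:
    """Trials for n_subjects x 3 speeds, deterministic given spec.seed."""
    spec = spec or CohortSpec()
    trials = []
    for subject in range(spec.n_subjects):
        params, speed_mult = subject_parameters(spec, subject)
        for speed_idx, (label, mean_speed) in enumerate(SPEED_MEANS.items()):
            speed = mean_speed * speed_mult
            seed = int(
                np.random.SeedSequence(
                    [spec.seed, subject, speed_idx]
                ).generate_state(1)[0]
            )
            noise = spec.noise
            if noise is not None:
                noise = replace(noise, seed=seed + 1)
            trials.append(
                generate_walking_trial(
                    params,
                    speed=speed,
                    n_steps=spec.n_steps,
                    seed=seed,
                    noise=noise,
                    subject_id=f"S{subject + 1}",
                    speed_label=label,
                )
            )
    return trials
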