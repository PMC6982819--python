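"""Planar link-segment inverse dynamics for the stance leg.

Bottom-up Newton--Euler recursion foot -> shank -> thigh.  Segment angles
follow the package convention (measured from the downward vertical,
positive for anterior tilt); a segment pointing along (sin th, -cos th)
has standard-frame orientation th - 90 deg, so its z angular
acceleration equals the plain second derivative of the segment angle.

Joint torques are reported extension-positive: a ground reaction force
acting anterior to the ankle produces a positive (plantarflexing) ankle
torque ``T_ank = fy * delta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SegmentInertia:
    mass_fraction: float   # of body mass
    com_fraction: float    # along the segment from the proximal joint
    gyration_fraction: float  # radius of gyration / segment length

    def __post_init__(self) -> None:
        for name in ("mass_fraction", "com_fraction", "gyration_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"SegmentInertia.{name} must lie in (0, 1)")


@dataclass(frozen=True)
class Anthropometrics:
    """Standard-table segment inertial fractions (Dempster/Winter style)."""

    body_mass: float
    foot: SegmentInertia = SegmentInertia(0.0145, 0.50, 0.475)
    shank: SegmentInertia = SegmentInertia(0.0465, 0.433, 0.302)
    thigh: SegmentInertia = SegmentInertia(0.100, 0.433, 0.323)

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        total = (
            self.foot.mass_fraction
            + self.shank.mass_fraction
            + self.thigh.mass_fraction
        )
        if total > 1.0:
            raise ValueError("segment masses exceed body mass")


def _cross_z(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


def newton_euler_segment(
    mass: float,
    inertia: float,
    com: np.ndarray,
    com_acc: np.ndarray,
    alpha_z: np.ndarray,
    distal_point: np.ndarray,
    distal_force: np.ndarray,
    distal_moment: np.ndarray,
    proximal_point: np.ndarray,
    g: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximal reaction (force, z-moment) of one segment.

    ``distal_force``/``distal_moment`` act *on* this segment at the distal
    point (external load or reaction from the segment below).  All arrays
    are time-major; 2-vectors in the trailing axis.
    """
    weight = np.zeros_like(com_acc)
    weight[..., 1] = -mass * g
    prox_force = mass * com_acc - distal_force - weight
    prox_moment = (
        inertia * alpha_z
        - distal_moment
        - _cross_z(distal_point - com, distal_force)
        - _cross_z(proximal_point - com, prox_force)
    )
    return prox_force, prox_moment


def _derivatives(
    track: np.ndarray, fs: float, fc: float | None
) -> tuple[np.ndarray, np.ndarray]:
    # local import: this module is shared by the preprocessing and
    # synthetic-data packages, so a top-level import would be circular
    from comgait.preprocessing.filters import lowpass_filter

    x = track
    if fc is not None and fc < fs / 2:
        x = lowpass_filter(x, fs=fs, fc=fc)
    v = np.gradient(x, 1.0 / fs, axis=0)
    a = np.gradient(v, 1.0 / fs, axis=0)
    return v, a


def planar_inverse_dynamics(
    t: np.ndarray,
    hip: np.ndarray,
    theta_thigh: np.ndarray,
    theta_shank: np.ndarray,
    theta_foot: np.ndarray,
    lengths: tuple[float, float, float],
    anthro: Anthropometrics,
    grf: np.ndarray,
    cop_x: np.ndarray,
    g: float = 9.81,
    smoothing_fc: float | None = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(T_ank, T_knee, T_hip) over the stance window, extension-positive.

    ``hip`` is (n, 2); ``grf`` is (n, 2); the center of pressure lies on
    the ground (y = 0).  Derivatives are taken by central differences
    after an optional zero-phase low-pass at ``smoothing_fc``.
    """
    t = np.asarray(t, float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples for differentiation")
    fs = 1.0 / float(np.mean(np.diff(t)))
    hip = np.asarray(hip, float)
    grf = np.asarray(grf, float)
    if hip.shape != (len(t), 2) or grf.shape != (len(t), 2):
        raise ValueError("hip and grf must be (n, 2) arrays")
    for name, arr in (
        ("theta_thigh", theta_thigh),
        ("theta_shank", theta_shank),
        ("theta_foot", theta_foot),
    ):
        if len(np.asarray(arr)) != len(t):
            raise ValueError(f"{name} length mismatch with t")

    l1, l2, l3 = lengths
    th1 = np.asarray(theta_thigh, float)
    th2 = np.asarray(theta_shank, float)
    th3 = np.asarray(theta_foot, float)

    def unit(th: np.ndarray) -> np.ndarray:
        return np.stack([np.sin(th), -np.cos(th)], axis=-1)

    knee = hip + l1 * unit(th1)
    ankle = knee + l2 * unit(th2)
    toe = ankle + l3 * unit(th3)
    cop = np.stack([np.asarray(cop_x, float), np.zeros(len(t))], axis=-1)

    m = anthro.body_mass
    segs = {
        "thigh": (anthro.thigh, l1, hip, knee, th1),
        "shank": (anthro.shank, l2, knee, ankle, th2),
        "foot": (anthro.foot, l3, ankle, toe, th3),
    }
    props = {}
    for name, (si, length, prox, dist, th) in segs.items():
        mass = si.mass_fraction * m
        inertia = mass * (si.gyration_fraction * length) ** 2
        com = prox + si.com_fraction * (dist - prox)
        _, com_acc = _derivatives(com, fs, smoothing_fc)
        _, th_acc = _derivatives(th, fs, smoothing_fc)
        # a segment direction (sin th, -cos th) has standard-frame
        # orientation th - 90 deg, so the z angular acceleration is +th''
        alpha_z = th_acc
        props[name] = (mass, inertia, com, com_acc, alpha_z, prox, dist)

    zeros = np.zeros(len(t))
    # Foot: external GRF at the CoP, reaction solved at the ankle.
    mass, inertia, com, acc, alz, prox, _ = props["foot"]
    f_ank, m_ank = newton_euler_segment(
        mass, inertia, com, acc, alz,
        distal_point=cop, distal_force=grf, distal_moment=zeros,
        proximal_point=prox, g=g,
    )
    # Shank: reaction from the foot acts at the ankle with flipped sign.
    mass, inertia, com, acc, alz, prox, dist = props["shank"]
    f_knee, m_knee = newton_euler_segment(
        mass, inertia, com, acc, alz,
        distal_point=dist, distal_force=-f_ank, distal_moment=-m_ank,
        proximal_point=prox, g=g,
    )
    mass, inertia, com, acc, alz, prox, dist = props["thigh"]
    _, m_hip = newton_euler_segment(
        mass, inertia, com, acc, alz,
        distal_point=dist, distal_force=-f_knee, distal_moment=-m_knee,
        proximal_point=prox, g=g,
    )
    # Internal z-moments are counterclockwise-positive; report
    # extension-positive torques (anterior CoP -> positive ankle torque).
    return -m_ank, -m_knee, -m_hip
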