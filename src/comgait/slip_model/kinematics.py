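"""Exact multibody inverse kinematics for the thigh/shank/foot chain.

The hip coincides with the point-mass CoM.  Segment angles are measured
clockwise-positive from the downward vertical of the segment's proximal
joint; a straight, vertical leg has theta1 = theta2 = 0.
"""

from __future__ import annotations

import math

import numpy as np

from comgait.slip_model.params import SlipParams
from comgait.slip_model.types import SegmentAngles


class KinematicsError(ValueError):
    """Raised for unreachable targets or degenerate chain geometry."""


def inverse_kinematics_multibody(
    com,
    ankle,
    params: SlipParams,
    leg: str = "stance",
    knee_sign: float = 1.0,
) -> SegmentAngles:
    """Segment angles (thigh, shank, foot) from CoM (hip) and ankle positions.

    ``knee_sign=+1`` bends the knee anteriorly (human convention).  The
    foot angle follows the leg direction (the rolling foot is locked to
    the leg by the ankle constraint); the ``leg`` selector is accepted for
    interface symmetry with the affine map and does not alter the knee
    convention.
    """
    if leg not in ("stance", "swing"):
        raise ValueError(f"leg must be 'stance' or 'swing', got {leg!r}")
    com = np.asarray(com, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    l1, l2 = params.l1, params.l2
    v = ankle - com
    D = float(np.hypot(v[0], v[1]))
    if D > l1 + l2 + 1e-12:
        raise KinematicsError(
            f"ankle target at distance {D:.6f} m exceeds reach {l1 + l2:.6f} m"
        )
    if D < abs(l1 - l2) - 1e-12:
        raise KinematicsError("ankle target inside the inner workspace boundary")
    D = min(D, l1 + l2)

    # Leg-line angle, clockwise-positive from the downward vertical.
    phi = math.atan2(v[0], -v[1])
    cos_b1 = (l1 * l1 + D * D - l2 * l2) / (2.0 * l1 * D)
    cos_b2 = (l2 * l2 + D * D - l1 * l1) / (2.0 * l2 * D)
    b1 = math.acos(min(max(cos_b1, -1.0), 1.0))
    b2 = math.acos(min(max(cos_b2, -1.0), 1.0))
    theta1 = phi + knee_sign * b1
    theta2 = phi - knee_sign * b2
    theta3 = phi  # foot locked to the leg line
    return SegmentAngles(np.array([theta1, theta2, theta3]))


def is_near_singular(com, ankle, params: SlipParams, rel_tol: float = 1e-3) -> bool:
    """True when the knee is within ``rel_tol`` of the straight-leg singularity."""
    com = np.asarray(com, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    D = float(np.hypot(*(ankle - com)))
    return D > (params.l1 + params.l2) * (1.0 - rel_tol)


def forward_kinematics(
    com, angles: SegmentAngles, params: SlipParams
) -> tuple[np.ndarray, np.ndarray]:
    """(knee, ankle) positions from the hip (CoM) and segment angles."""
    com = np.asarray(com, dtype=float)
    t1, t2, _ = angles.theta123
    knee = com + params.l1 * np.array([math.sin(t1), -math.cos(t1)])
    ankle = knee + params.l2 * np.array([math.sin(t2), -math.cos(t2)])
    return knee, ankle
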