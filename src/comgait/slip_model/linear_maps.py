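"""Affine maps from CoM position to state, kinetics and segment angles.

The compliant walker linearized about its touchdown reference yields three
stacked affine maps:

* ``z = W1 x + b1`` -- CoM position to augmented state z = (l, theta, l*theta)
* ``f = W2 z + b2`` -- augmented state to kinetics f = (fx, fy, Ta)
* ``th = W3 z + b3`` -- augmented state to segment angles (thigh/shank rows)

The sign-alternating rows of the angle map distinguish the two legs; the
``leg`` selector resolves them (upper sign = swing leg, lower = stance).
Composition of the maps collapses into a single affine map from the CoM
position to the full output stack, see :func:`com_to_outputs`.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from comgait.slip_model.params import SlipParams, TouchdownRefs
from comgait.slip_model.types import AugmentedState, KineticsVector, SegmentAngles

Leg = Literal["stance", "swing"]


def state_map_matrices(refs: TouchdownRefs) -> tuple[np.ndarray, np.ndarray]:
    """(W1, b1) of the CoM-position to augmented-state map."""
    if refs.y_hs <= 0:
        raise ValueError("invalid touchdown reference: y_hs must be positive")
    inv_y = 1.0 / refs.y_hs
    W1 = np.array([
        [0.0, 1.0],
        [inv_y, 0.0],
        [1.0, 0.0],
    ])
    b1 = np.array([0.0, refs.alpha * inv_y, refs.alpha])
    return W1, b1


def kinetics_matrices(params: SlipParams) -> tuple[np.ndarray, np.ndarray]:
    """(W2, b2) of the augmented-state to kinetics map.

    Entries are written in terms of the total-leg stiffness k, rest length
    l0, foot radius R, ankle offset d and the linearization coefficient cl.
    The bias is chosen so the kinetics vanish at the unloaded vertical
    reference z = (l0, 0, 0).
    """
    k, d, l0, R = params.k, params.d, params.l0, params.R
    cl = params.cl_eff
    W2 = np.array([
        [k * d / l0,  k * (l0 - R),   k * (R / l0 - 1.0)],
        [-k,          k * d,          -k * d / l0],
        [-k * d * cl, k * R * l0 * cl, -k * R * cl],
    ])
    b2 = np.array([-k * d, k * l0, k * d * l0 * cl])
    return W2, b2


def angle_matrices(params: SlipParams, leg: Leg) -> tuple[np.ndarray, np.ndarray]:
    """(W3, b3) of the augmented-state to segment-angle map.

    Row 1 is the thigh-like row (same for both legs); rows 2-3 carry the
    leg-dependent signs.  ``leg='swing'`` takes the upper signs of the
    alternating entries, ``leg='stance'`` the lower ones.
    """
    if params.l1 <= 0 or params.l2 <= 0:
        raise ValueError("degenerate segment lengths: l1, l2 must be positive")
    if leg not in ("stance", "swing"):
        raise ValueError(f"leg must be 'stance' or 'swing', got {leg!r}")
    l0, l1, l2 = params.l0, params.l1, params.l2
    cl, ck = params.cl_eff, params.ck_eff
    s = 1.0 if leg == "swing" else -1.0  # upper sign for the swing leg

    q = 0.25 * cl * ck * l0 / l2**2
    r = 0.5 * (cl - ck) * l0 / l2
    u = 0.5 * ck / l2
    bias23 = 1.0 - 0.125 * cl * (cl - 2.0 * ck) * l0**2 / l2**2
    W3 = np.array([
        [(1.0 - ck) / l1, 1.0, 0.0],
        [-s * q, r, u],
        [s * q, r, u],
    ])
    b3 = np.array([
        -(1.0 - ck) * l0 / l1,
        s * bias23,
        -s * bias23,
    ])
    return W3, b3


def linearized_state_map(x, refs: TouchdownRefs) -> AugmentedState:
    """Map a CoM position 2-vector to the augmented state z = W1 x + b1."""
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError("CoM position must be a 2-vector")
    W1, b1 = state_map_matrices(refs)
    return AugmentedState(W1 @ x + b1, exact=False)


def state_to_kinetics(z: AugmentedState, params: SlipParams) -> KineticsVector:
    """Affine kinetics f = W2 z + b2."""
    W2, b2 = kinetics_matrices(params)
    return KineticsVector(W2 @ z.z + b2)


def state_to_segment_angles(
    z: AugmentedState, params: SlipParams, leg: Leg
) -> SegmentAngles:
    """Affine segment angles th = W3 z + b3 for the selected leg."""
    W3, b3 = angle_matrices(params, leg)
    return SegmentAngles(W3 @ z.z + b3)


def stacked_matrices(
    refs: TouchdownRefs, params: SlipParams
) -> tuple[np.ndarray, np.ndarray]:
    """Single 9x2 affine map [f; th_stance; th_swing] = W x + b."""
    W1, b1 = state_map_matrices(refs)
    W2, b2 = kinetics_matrices(params)
    W3s, b3s = angle_matrices(params, "stance")
    W3w, b3w = angle_matrices(params, "swing")
    W = np.vstack([W2 @ W1, W3s @ W1, W3w @ W1])
    b = np.concatenate([W2 @ b1 + b2, W3s @ b1 + b3s, W3w @ b1 + b3w])
    return W, b


def com_to_outputs(
    x, refs: TouchdownRefs, params: SlipParams
) -> tuple[KineticsVector, SegmentAngles, SegmentAngles]:
    """Kinetics and stance/swing segment angles from the CoM position.

    Identical (to round-off) to composing :func:`linearized_state_map`
    with the two downstream affine maps.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError("CoM position must be a 2-vector")
    W, b = stacked_matrices(refs, params)
    out = W @ x + b
    return (
        KineticsVector(out[:3]),
        SegmentAngles(out[3:6]),
        SegmentAngles(out[6:9]),
    )
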