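"""Drift-removed integration of stance-phase acceleration."""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid


def integrate_drift_removed(
    accel: np.ndarray, T: float, fs: float
) -> np.ndarray:
    """Velocity track with the linear-in-time integration drift removed.

    Cumulative trapezoidal integration from zero, then subtraction of the
    secular ramp implied by the net velocity change over the stance::

        v_hat(t) = v(t) - (v(T) - v(0)) * t / T

    so that ``v_hat(T) == v_hat(0)`` to machine precision.  ``accel`` may
    be 1-D or (n, channels).
    """
    if T <= 0:
        raise ValueError("stance duration T must be positive")
    a = np.asarray(accel, dtype=float)
    n = a.shape[0]
    t = np.arange(n) / fs
    v = cumulative_trapezoid(a, t, axis=0, initial=0.0)
    ramp = (t / T).reshape((n,) + (1,) * (a.ndim - 1))
    return v - (v[-1] - v[0]) * ramp
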