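"""Zero-phase Butterworth filtering.

Event timing must not be phase-shifted, so the filter is applied forward
and backward (``filtfilt``); the quoted order is the single-pass order.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt


def lowpass_filter(
    signal: np.ndarray, fs: float, fc: float, order: int = 5, axis: int = 0
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    Parameters
    ----------
    signal : array
        Input samples (filtered along ``axis``).
    fs : float
        Sampling rate [Hz].
    fc : float
        Cutoff frequency [Hz]; must satisfy 0 < fc < fs/2.
    order : int
        Single-pass Butterworth order (default 5).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff fc={fc} must lie in (0, Nyquist={fs / 2})")
    x = np.asarray(signal, dtype=float)
    b, a = butter(order, fc / (fs / 2), btype="low")
    padlen = min(3 * (max(len(b), len(a)) - 1), x.shape[axis] - 1)
    return filtfilt(b, a, x, axis=axis, padlen=padlen)
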