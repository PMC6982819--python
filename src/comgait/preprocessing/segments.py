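"""Stance segmentation and per-segment summary quantities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from comgait.preprocessing.events import EventSet
from comgait.synthetic_data.trial import ImuTrial


class SegmentationError(ValueError):
    """Raised for inconsistent (overlapping) stance windows."""


@dataclass
class StanceSegment:
    """One stance phase [HS, TO] of a trial.

    Velocity and position tracks are filled in by the integration stage;
    ``T`` is the stance duration, ``A`` the mean acceleration magnitude
    and ``f_gait`` the gait frequency (1/stride time between consecutive
    ipsilateral heel strikes, falling back to 1/(2 * step time)).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    T: float
    A: float
    f_gait: float
    hs_index: int
    to_index: int
    subject_id: str = ""
    speed_label: str = ""
    height: float | None = None
    leg_length: float | None = None
    speed: float | None = None
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    px: np.ndarray | None = None
    py: np.ndarray | None = None
    # apex-to-apex integration window enclosing [hs, to]: acceleration
    # samples plus the location of the stance within the window
    win_ax: np.ndarray | None = None
    win_ay: np.ndarray | None = None
    win_hs: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t)))


def segment_trial(
    trial: ImuTrial, events: EventSet, kinematic_cutoff_hz: float | None = 10.0
) -> list[StanceSegment]:
    """One :class:`StanceSegment` per validated (HS, TO) stance window.

    The acceleration carried by the segments is low-passed at
    ``kinematic_cutoff_hz`` (zero phase) before slicing: heel-strike
    impact transients belong to the event-detection path, not to the
    integration path.
    """
    windows = events.stance_windows()
    for (h1, t1), (h2, _) in zip(windows, windows[1:]):
        if h2 < h1:
            raise SegmentationError("stance windows out of order")
    fs = events.fs
    hs_all = events.hs_i
    if kinematic_cutoff_hz is not None:
        from comgait.preprocessing.filters import lowpass_filter

        ax_f = lowpass_filter(trial.ax, fs=fs, fc=kinematic_cutoff_hz)
        ay_f = lowpass_filter(trial.ay, fs=fs, fc=kinematic_cutoff_hz)
    else:
        ax_f, ay_f = trial.ax, trial.ay
    apex_all = events.apex_i
    segments: list[StanceSegment] = []
    for j, (hs, to) in enumerate(windows):
        if to <= hs:
            raise SegmentationError(f"segment {j}: empty window [{hs}, {to}]")
        sl = slice(hs, to + 1)
        ax, ay = ax_f[sl], ay_f[sl]
        # drift-removal window anchored at the enclosing CoM apexes,
        # where the true vertical velocity crosses zero
        w_lo = int(apex_all[j]) if j < len(apex_all) else hs
        w_hi = int(apex_all[j + 2]) if j + 2 < len(apex_all) else to
        w_lo = min(w_lo, hs)
        w_hi = max(w_hi, to)
        T = (to - hs) / fs
        A = float(np.mean(np.hypot(ax, ay)))
        # stride time between consecutive ipsilateral heel strikes
        if j + 2 < len(hs_all):
            stride = (hs_all[j + 2] - hs_all[j]) / fs
        elif j >= 2:
            stride = (hs_all[j] - hs_all[j - 2]) / fs
        elif j + 1 < len(hs_all):
            stride = 2.0 * (hs_all[j + 1] - hs_all[j]) / fs
        else:
            stride = 2.0 * T / 1.2  # lone stance: assume 60% duty factor
        segments.append(
            StanceSegment(
                t=trial.t[sl],
                ax=ax,
                ay=ay,
                T=T,
                A=A,
                f_gait=1.0 / stride,
                hs_index=hs,
                to_index=to,
                win_ax=ax_f[w_lo: w_hi + 1],
                win_ay=ay_f[w_lo: w_hi + 1],
                win_hs=hs - w_lo,
                subject_id=trial.subject_id,
                speed_label=trial.speed_label,
                height=trial.height,
                leg_length=trial.leg_length,
                speed=trial.speed,
            )
        )
    return segments
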