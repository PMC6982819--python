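"""Per-stance feature and label blocks for the network.

A stance segment becomes a 7 x 200 feature block with rows
``(t, x, y, vx, vy, ax, ay)``: time as stance-phase fraction, positions
from integrating the compensated velocity (horizontal reset to zero at
heel strike, vertical offset equal to the subject's leg length), each
kinematic row min--max scaled to [0, 1] with extrema frozen on the
training fold, and every row linearly resampled to 200 phase points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from comgait.preprocessing.integration import integrate_drift_removed
from comgait.preprocessing.segments import StanceSegment
from comgait.preprocessing.speed_offset import OffsetModel, apply_speed_offset
from comgait.synthetic_data.trial import LABEL_CHANNELS, StepLabels

logger = logging.getLogger(__name__)

RESAMPLE_POINTS = 200
FEATURE_ROWS = ["t", "x", "y", "vx", "vy", "ax", "ay"]


@dataclass(frozen=True)
class FeatureBlock:
    values: np.ndarray       # (7, n_points)
    subject_id: str = ""
    speed_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != len(FEATURE_ROWS):
            raise ValueError("FeatureBlock.values must be (7, n)")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabelBlock:
    values: np.ndarray       # (11, n_points), physical units
    subject_id: str = ""
    speed_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != len(LABEL_CHANNELS):
            raise ValueError("LabelBlock.values must be (11, n)")
        object.__setattr__(self, "values", v)


@dataclass
class ChannelScaler:
    """Min--max scaling with extrema frozen on the training fold.

    Degenerate channels (max == min) map to 0.5 with a warning.
    """

    lo: np.ndarray = field(default_factory=lambda: np.array([]))
    hi: np.ndarray = field(default_factory=lambda: np.array([]))

    def fit(self, stacked: np.ndarray) -> "ChannelScaler":
        """``stacked``: (channels, n_total) training data."""
        self.lo = stacked.min(axis=1)
        self.hi = stacked.max(axis=1)
        return self

    @property
    def fitted(self) -> bool:
        return self.lo.size > 0

    def transform(self, block: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = np.empty_like(block, dtype=float)
        for i in range(block.shape[0]):
            if span[i] <= 0:
                logger.warning("degenerate channel %d: left at 0.5", i)
                out[i] = 0.5
            else:
                out[i] = (block[i] - self.lo[i]) / span[i]
        return out

    def inverse(self, block: np.ndarray) -> np.ndarray:
        span = np.where(self.hi - self.lo > 0, self.hi - self.lo, 1.0)
        return block * span[:, None] + self.lo[:, None]


def resample_phase(rows: np.ndarray, n_points: int = RESAMPLE_POINTS) -> np.ndarray:
    """Linear interpolation of (channels, n) rows onto n_points phase samples."""
    rows = np.asarray(rows, float)
    n = rows.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.vstack([np.interp(dst, src, row) for row in rows])


def integrate_segment(
    segment: StanceSegment, offset_model: OffsetModel | None = None
) -> StanceSegment:
    """Fill vx, vy, px, py of a segment in place (returns it for chaining).

    Velocities are drift-removed; the forward speed offset from
    ``offset_model`` is added to vx (vertical offset 0).  Positions come
    from trapezoidal integration of the compensated velocity, horizontal
    reset to 0 at heel strike and vertical offset equal to the leg length.
    """
    fs = segment.fs
    n = len(segment)
    if segment.win_ax is not None:
        # integrate over the apex-to-apex window: true vertical velocity
        # is ~0 at both apexes, so the linear drift ramp absorbs the
        # integration error without biasing the vertical channel
        acc = np.column_stack([segment.win_ax, segment.win_ay])
        t_win = (len(acc) - 1) / fs
        v_win = integrate_drift_removed(acc, T=t_win, fs=fs)
        v = v_win[segment.win_hs: segment.win_hs + n]
    else:
        acc = np.column_stack([segment.ax, segment.ay])
        v = integrate_drift_removed(acc, T=segment.T, fs=fs)
    v0 = apply_speed_offset(offset_model, segment) if offset_model else 0.0
    # steady walking: the horizontal channel is centered so the regressed
    # offset is the segment's mean forward speed; the vertical offset is
    # zero (apex anchoring already fixes its level)
    vx = v[:, 0] - np.mean(v[:, 0]) + v0
    vy = v[:, 1]
    tloc = np.arange(len(vx)) / fs
    px = cumulative_trapezoid(vx, tloc, initial=0.0)
    py = cumulative_trapezoid(vy, tloc, initial=0.0)
    py = py + (segment.leg_length if segment.leg_length is not None else 0.0)
    segment.vx, segment.vy = vx, vy
    segment.px, segment.py = px, py
    return segment


def raw_feature_rows(segment: StanceSegment) -> np.ndarray:
    """(7, n) unscaled feature rows; requires an integrated segment."""
    if segment.vx is None or segment.px is None:
        raise ValueError("segment not integrated; call integrate_segment first")
    n = len(segment)
    phase = np.arange(n) / max(n - 1, 1)
    return np.vstack(
        [phase, segment.px, segment.py, segment.vx, segment.vy,
         segment.ax, segment.ay]
    )


def fit_feature_scaler(segments: list[StanceSegment]) -> ChannelScaler:
    """Extrema of the 6 kinematic rows over a training fold (row 0 is phase)."""
    stacked = np.hstack([raw_feature_rows(s)[1:] for s in segments])
    return ChannelScaler().fit(stacked)


def assemble_features(
    segment: StanceSegment,
    scaler: ChannelScaler,
    step_labels: StepLabels | None = None,
    n_points: int = RESAMPLE_POINTS,
) -> FeatureBlock | tuple[FeatureBlock, LabelBlock]:
    """Build the 7 x n_points feature block (and label block if supplied)."""
    rows = raw_feature_rows(segment)
    scaled = np.vstack([rows[:1], scaler.transform(rows[1:])])
    feat = FeatureBlock(
        resample_phase(scaled, n_points),
        subject_id=segment.subject_id,
        speed_label=segment.speed_label,
    )
    if step_labels is None:
        return feat
    lab = StepLabelsResampler.sample(step_labels, segment, n_points)
    return feat, LabelBlock(
        lab, subject_id=segment.subject_id, speed_label=segment.speed_label
    )


class StepLabelsResampler:
    @staticmethod
    def sample(
        step_labels: StepLabels, segment: StanceSegment, n_points: int
    ) -> np.ndarray:
        t_query = np.linspace(segment.t[0], segment.t[-1], n_points)
        return step_labels.sample(t_query)
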