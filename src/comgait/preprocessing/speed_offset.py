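"""Gait-speed offset regression.

Drift-removed integration fixes velocity only up to a constant; the
missing forward-speed offset is regressed from the mean acceleration
magnitude ``A`` and the gait frequency ``f``::

    v0 = (a*A + b*f + c) * sqrt(h*g)

with the speed normalized by the height--gravity scale sqrt(h*g) to
suppress subject-size effects.  The vertical offset is zero (steady
walking).  The model must be fitted on training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from comgait.preprocessing.segments import StanceSegment

G_DEFAULT = 9.81


class FitError(ValueError):
    """Raised when the regression design is rank deficient."""


@dataclass(frozen=True)
class OffsetModel:
    a: float
    b: float
    c: float
    g: float = G_DEFAULT

    def predict(self, A: float, f_gait: float, h: float) -> float:
        """Forward-speed offset [m/s] for a segment of a subject of height h."""
        scale = np.sqrt(h * self.g)
        return float((self.a * A + self.b * f_gait + self.c) * scale)


def fit_speed_offset_model(
    segments: list[StanceSegment],
    speeds: np.ndarray | None = None,
    g: float = G_DEFAULT,
) -> OffsetModel:
    """Least-squares fit of the normalized speed on (A, f_gait, 1).

    ``speeds`` defaults to each segment's known gait speed.  Requires at
    least 3 segments with non-degenerate (A, f) variation.
    """
    if speeds is None:
        speeds = np.array([s.speed for s in segments], dtype=float)
        if np.any(np.isnan(speeds)):
            raise ValueError("segments lack known speeds; pass them explicitly")
    speeds = np.asarray(speeds, dtype=float)
    if len(segments) < 3:
        raise FitError("need at least 3 segments to fit the offset model")
    if len(speeds) != len(segments):
        raise ValueError("speeds length mismatch with segments")
    A = np.array([s.A for s in segments])
    f = np.array([s.f_gait for s in segments])
    h = np.array([s.height for s in segments], dtype=float)
    if np.any(np.isnan(h)):
        raise ValueError("segments lack subject heights")
    if np.ptp(A) < 1e-12 and np.ptp(f) < 1e-12:
        raise FitError("degenerate design: A and f_gait constant across segments")
    X = np.column_stack([A, f, np.ones_like(A)])
    y = speeds / np.sqrt(h * g)
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("rank-deficient regression design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return OffsetModel(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]), g=g)


def apply_speed_offset(model: OffsetModel, segment: StanceSegment) -> float:
    """Forward-speed offset v0 for one segment (vertical offset is zero)."""
    if segment.height is None:
        raise ValueError("segment lacks subject height")
    return model.predict(segment.A, segment.f_gait, segment.height)
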