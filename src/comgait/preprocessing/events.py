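"""Gait-event detection from sacrum acceleration.

Per detection round, working on low-passed copies of the trial:

1. CoM apex: next local minimum of the 10 Hz vertical acceleration.
2. Heel strike: first local minimum of the 40 Hz vertical acceleration
   following the positive local maximum after the apex.
3. Toe off: first local minimum of the 10 Hz horizontal acceleration
   after the apex.
4. Validation: if the heel strike lands after the toe off it is
   re-identified as the preceding 40 Hz local minimum.

The cursor then advances to the toe off and the next round starts from
there.  A round records (apex, next-leg HS, current-leg TO); stances pair
the HS of round i with the TO of round i+1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from comgait.preprocessing.filters import lowpass_filter
from comgait.synthetic_data.trial import ImuTrial

logger = logging.getLogger(__name__)

DEFAULT_HS_CUTOFF_HZ = 40.0
DEFAULT_TO_CUTOFF_HZ = 10.0
DEFAULT_APEX_CUTOFF_HZ = 10.0
REFRACTORY_S = 0.05  # extrema closer than this to a stronger rival are spurious


@dataclass(frozen=True)
class EventSet:
    """Detected events, one row per detection round (see module docstring)."""

    apex_i: np.ndarray
    hs_i: np.ndarray
    to_i: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        for name in ("apex_i", "hs_i", "to_i"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=int)
            )
        if not (len(self.apex_i) == len(self.hs_i) == len(self.to_i)):
            raise ValueError("event index arrays must have equal length")

    def __len__(self) -> int:
        return len(self.apex_i)

    @property
    def apex_t(self) -> np.ndarray:
        return self.apex_i / self.fs

    @property
    def hs_t(self) -> np.ndarray:
        return self.hs_i / self.fs

    @property
    def to_t(self) -> np.ndarray:
        return self.to_i / self.fs

    def stance_windows(self) -> list[tuple[int, int]]:
        """Validated (hs_i, to_i) sample bounds of complete stances."""
        out = []
        for i in range(len(self) - 1):
            hs, to = int(self.hs_i[i]), int(self.to_i[i + 1])
            if hs < to:
                out.append((hs, to))
        return out


def local_extrema(
    x: np.ndarray, kind: str, fs: float, refractory_s: float = REFRACTORY_S
) -> np.ndarray:
    """Indices of strict local extrema, pruned by a refractory window.

    Ties resolve to the earliest index.  Within ``refractory_s`` of a
    stronger extremum of the same kind, the weaker one is discarded.
    """
    if kind not in ("min", "max"):
        raise ValueError("kind must be 'min' or 'max'")
    s = -x if kind == "min" else x
    idx = np.nonzero((s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:]))[0] + 1
    if len(idx) == 0:
        return idx
    window = max(int(round(refractory_s * fs)), 1)
    keep = []
    for i in idx:
        rivals = [j for j in idx if j != i and abs(j - i) <= window]
        if all(s[i] > s[j] or (s[i] == s[j] and i < j) for j in rivals):
            keep.append(i)
    return np.asarray(keep, dtype=int)


def _next_after(candidates: np.ndarray, start: int) -> int | None:
    after = candidates[candidates > start]
    return int(after[0]) if len(after) else None


def _prev_before(candidates: np.ndarray, stop: int) -> int | None:
    before = candidates[candidates < stop]
    return int(before[-1]) if len(before) else None


def detect_gait_events(
    trial: ImuTrial,
    hs_cutoff_hz: float = DEFAULT_HS_CUTOFF_HZ,
    to_cutoff_hz: float = DEFAULT_TO_CUTOFF_HZ,
    apex_cutoff_hz: float = DEFAULT_APEX_CUTOFF_HZ,
) -> EventSet:
    """Detect (apex, HS, TO) rounds on a sacrum acceleration trial."""
    fs = trial.fs
    if fs < 100.0 - 1e-9:
        raise ValueError("event detection requires fs >= 100 Hz")
    ay10 = lowpass_filter(trial.ay, fs=fs, fc=apex_cutoff_hz)
    ay40 = lowpass_filter(trial.ay, fs=fs, fc=min(hs_cutoff_hz, 0.98 * fs / 2))
    ax10 = lowpass_filter(trial.ax, fs=fs, fc=to_cutoff_hz)

    apex_cands = local_extrema(ay10, "min", fs)
    hs_min_cands = local_extrema(ay40, "min", fs)
    hs_max_cands = local_extrema(ay40, "max", fs)
    to_cands = local_extrema(ax10, "min", fs)

    apexes: list[int] = []
    hss: list[int] = []
    tos: list[int] = []
    cursor = 0
    n = len(trial)
    while cursor < n - 2:
        apex = _next_after(apex_cands, cursor)
        if apex is None:
            break
        to = _next_after(to_cands, apex)
        peak = _next_after(hs_max_cands, apex)
        hs = _next_after(hs_min_cands, peak) if peak is not None else None
        if hs is None or to is None:
            # normal termination at the end of the stream
            logger.debug(
                "incomplete round after apex at sample %d; stopping", apex
            )
            break
        if hs > to:
            # Validation rule: HS must precede TO; fall back to the
            # preceding 40 Hz local minimum.
            hs_prev = _prev_before(hs_min_cands, hs)
            if hs_prev is None or hs_prev <= apex:
                warnings.warn(
                    f"round at apex sample {apex}: no valid HS before TO; "
                    "step skipped",
                    stacklevel=2,
                )
                cursor = to
                continue
            hs = hs_prev
        if hs <= apex or hs >= to:
            cursor = to
            continue
        apexes.append(apex)
        hss.append(hs)
        tos.append(to)
        cursor = to
    return EventSet(
        apex_i=np.array(apexes, dtype=int),
        hs_i=np.array(hss, dtype=int),
        to_i=np.array(tos, dtype=int),
        fs=fs,
    )
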