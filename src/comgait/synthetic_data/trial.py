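"""Trial containers: sacrum acceleration streams with optional ground truth.

Event bookkeeping follows the detection-round convention: each round
records the CoM apex of the current stance, the heel strike of the *next*
leg and the toe off of the current leg, so ``apex_t < hs_t < to_t`` holds
within a round.  One full stance therefore pairs the heel strike of round
``i`` with the toe off of round ``i+1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_CHANNELS = [
    "GRFx", "GRFy",
    "T_ank", "T_knee", "T_hip",
    "th_foot_st", "th_shank_st", "th_thigh_st",
    "th_foot_sw", "th_shank_sw", "th_thigh_sw",
]


class TrialFormatError(ValueError):
    """Raised for malformed trial files."""


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth gait events, one row per detection round."""

    apex_t: np.ndarray
    hs_t: np.ndarray
    to_t: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.apex_t, float)
        h = np.asarray(self.hs_t, float)
        o = np.asarray(self.to_t, float)
        if not (len(a) == len(h) == len(o)):
            raise ValueError("event arrays must have equal length")
        if len(a) and not (np.all(a < h) and np.all(h < o)):
            raise ValueError("event ordering apex < hs < to violated")
        object.__setattr__(self, "apex_t", a)
        object.__setattr__(self, "hs_t", h)
        object.__setattr__(self, "to_t", o)

    def __len__(self) -> int:
        return len(self.apex_t)

    def stance_windows(self) -> list[tuple[float, float]]:
        """(hs, to) bounds of complete stances, pairing rounds i and i+1."""
        return [
            (float(self.hs_t[i]), float(self.to_t[i + 1]))
            for i in range(len(self) - 1)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": np.arange(len(self)), "apex_t": self.apex_t,
             "hs_t": self.hs_t, "to_t": self.to_t}
        )


@dataclass(frozen=True)
class StepLabels:
    """11-channel label block for one stance, on its own time grid."""

    t: np.ndarray           # absolute trial time over [hs, to]
    values: np.ndarray      # (11, len(t))

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        v = np.asarray(self.values, float)
        if v.shape != (len(LABEL_CHANNELS), len(t)):
            raise ValueError(
                f"StepLabels.values must be (11, {len(t)}), got {v.shape}"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)

    def sample(self, t_query: np.ndarray) -> np.ndarray:
        """(11, len(t_query)) linear interpolation, edge-clamped."""
        out = np.empty((len(LABEL_CHANNELS), len(t_query)))
        for i in range(len(LABEL_CHANNELS)):
            out[i] = np.interp(t_query, self.t, self.values[i])
        return out


@dataclass(frozen=True)
class LabelTrack:
    """11 channels on the trial clock plus per-stance label blocks.

    The flat track assigns each instant to the most recently started
    stance; the per-stance blocks resolve the double-support overlap and
    are what the training pipeline consumes.
    """

    t: np.ndarray
    values: np.ndarray                 # (11, len(t))
    steps: tuple[StepLabels, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        v = np.asarray(self.values, float)
        if v.shape != (len(LABEL_CHANNELS), len(t)):
            raise ValueError("LabelTrack.values must be (11, len(t))")
        if not np.all(np.isfinite(v)):
            raise ValueError("label channels must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "steps", tuple(self.steps))


@dataclass(frozen=True)
class ImuTrial:
    """A sampled sacrum acceleration stream with optional ground truth."""

    subject_id: str
    speed_label: str        # slow | moderate | fast
    fs: float               # sampling rate [Hz]
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    truth: EventTruth | None = None
    labels: LabelTrack | None = None
    speed: float | None = None      # commanded treadmill-equivalent speed [m/s]
    height: float | None = None     # subject stature [m]
    leg_length: float | None = None  # position offset used downstream [m]
    com: np.ndarray | None = None   # (n, 2) noise-free CoM track (not serialized)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        ax = np.asarray(self.ax, float)
        ay = np.asarray(self.ay, float)
        if not (len(t) == len(ax) == len(ay)):
            raise ValueError("t, ax, ay must have equal length")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trial must be uniformly sampled")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ax", ax)
        object.__setattr__(self, "ay", ay)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_acceleration(self, ax: np.ndarray, ay: np.ndarray) -> "ImuTrial":
        return replace(self, ax=np.asarray(ax, float), ay=np.asarray(ay, float))


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("t", "ax", "ay")


def write_trial(trial: ImuTrial, directory: str | Path) -> Path:
    """Write trial.csv plus sidecars (labels, events, manifest, step labels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    pd.DataFrame({"t": trial.t, "ax": trial.ax, "ay": trial.ay}).to_csv(
        directory / "trial.csv", index=False, float_format=fmt
    )
    if trial.truth is not None:
        trial.truth.to_frame().to_csv(
            directory / "events.csv", index=False, float_format=fmt
        )
    if trial.labels is not None:
        df = pd.DataFrame({"t": trial.labels.t})
        for i, name in enumerate(LABEL_CHANNELS):
            df[name] = trial.labels.values[i]
        df.to_csv(directory / "labels.csv", index=False, float_format=fmt)
        for j, step in enumerate(trial.labels.steps):
            sdf = pd.DataFrame({"t": step.t})
            for i, name in enumerate(LABEL_CHANNELS):
                sdf[name] = step.values[i]
            sdf.to_csv(
                directory / f"step_labels_{j:03d}.csv",
                index=False, float_format=fmt,
            )
    manifest = {
        "subject_id": trial.subject_id,
        "speed_label": trial.speed_label,
        "fs": trial.fs,
        "speed": trial.speed,
        "height": trial.height,
        "leg_length": trial.leg_length,
        "meta": trial.meta,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_trial(directory: str | Path) -> ImuTrial:
    """Read a trial written by :func:`write_trial`."""
    directory = Path(directory)
    path = directory / "trial.csv"
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"{path}: missing column {col!r}")
    t = df["t"].to_numpy()
    dt = np.diff(t)
    if len(dt):
        bad = np.nonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))[0]
        if len(bad):
            raise TrialFormatError(
                f"{path}: non-uniform timestamps at row {int(bad[0]) + 1}"
            )
    truth = None
    if (directory / "events.csv").exists():
        edf = pd.read_csv(directory / "events.csv")
        truth = EventTruth(
            apex_t=edf["apex_t"].to_numpy(),
            hs_t=edf["hs_t"].to_numpy(),
            to_t=edf["to_t"].to_numpy(),
        )
    labels = None
    if (directory / "labels.csv").exists():
        ldf = pd.read_csv(directory / "labels.csv")
        steps = []
        for spath in sorted(directory.glob("step_labels_*.csv")):
            sdf = pd.read_csv(spath)
            steps.append(
                StepLabels(
                    t=sdf["t"].to_numpy(),
                    values=sdf[LABEL_CHANNELS].to_numpy().T,
                )
            )
        labels = LabelTrack(
            t=ldf["t"].to_numpy(),
            values=ldf[LABEL_CHANNELS].to_numpy().T,
            steps=tuple(steps),
        )
    manifest = {}
    if (directory / "manifest.json").exists():
        manifest = json.loads((directory / "manifest.json").read_text())
    fs = manifest.get("fs") or (1.0 / dt[0] if len(dt) else 0.0)
    return ImuTrial(
        subject_id=manifest.get("subject_id", "unknown"),
        speed_label=manifest.get("speed_label", "moderate"),
        fs=fs,
        t=t,
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        truth=truth,
        labels=labels,
        speed=manifest.get("speed"),
        height=manifest.get("height"),
        leg_length=manifest.get("leg_length"),
        meta=manifest.get("meta", {}),
    )


def trial_io(
    trial: ImuTrial | None, path: str | Path, direction: str
) -> ImuTrial | Path:
    """Dispatch helper: ``direction='write'`` stores, ``'read'`` loads."""
    if direction == "write":
        if trial is None:
            raise ValueError("trial required for direction='write'")
        return write_trial(trial, path)
    if direction == "read":
        return read_trial(path)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")
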