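"""Prediction-quality metrics: NRMSE (percent of observed range), MAE and
Pearson correlation, reported per output channel, subject and speed."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from comgait.synthetic_data.trial import LABEL_CHANNELS


class UndefinedMetricError(ValueError):
    """Raised when the NRMSE normalizer is not positive."""


def compute_nrmse(
    pred: np.ndarray, obs: np.ndarray, normalizer: float | None = None
) -> float:
    """100 * RMSE(pred, obs) / normalizer, normalizer defaulting to
    max(obs) - min(obs)."""
    pred = np.asarray(pred, float).ravel()
    obs = np.asarray(obs, float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal lengths")
    if normalizer is None:
        normalizer = float(np.max(obs) - np.min(obs))
    if normalizer <= 0:
        raise UndefinedMetricError("NRMSE normalizer must be positive")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return 100.0 * rmse / normalizer


def compute_mae(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, float).ravel()
    obs = np.asarray(obs, float).ravel()
    return float(np.mean(np.abs(pred - obs)))


def compute_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, float).ravel()
    obs = np.asarray(obs, float).ravel()
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


@dataclass
class MetricsReport:
    """Tidy per-(channel, subject, speed) metric table."""

    frame: pd.DataFrame

    @classmethod
    def from_records(cls, records: list[dict]) -> "MetricsReport":
        df = pd.DataFrame.from_records(
            records,
            columns=["channel", "subject", "speed", "nrmse", "mae", "pearson"],
        )
        bad = df[(df["nrmse"] < 0)]
        if len(bad):
            raise ValueError("negative NRMSE in report")
        return cls(df)

    def per_channel(self) -> pd.Series:
        """Mean NRMSE per channel over subjects and speeds."""
        return self.frame.groupby("channel", sort=False)["nrmse"].mean()

    def mean_nrmse(self) -> float:
        return float(self.frame["nrmse"].mean())

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "MetricsReport":
        return cls(pd.read_csv(path))


def channel_index(name: str) -> int:
    return LABEL_CHANNELS.index(name)
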