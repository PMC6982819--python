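"""Sensor corruption: white noise, constant bias and slow bias drift."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from comgait.synthetic_data.trial import ImuTrial


@dataclass(frozen=True)
class NoiseModel:
    """Additive accelerometer error model.

    ``accel_noise_sd`` is the white-noise standard deviation, ``bias`` a
    constant offset and ``bias_drift_rate`` the slope of a linearly
    growing offset -- the component the drift-removed integration has to
    cancel.  Generation is reproducible given ``seed``.
    """

    accel_noise_sd: float = 0.03   # m/s^2 (~0.003 g sensor floor)
    bias: float = 0.01             # m/s^2
    bias_drift_rate: float = 0.005  # m/s^3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0:
            raise ValueError("accel_noise_sd must be nonnegative")

    def is_null(self) -> bool:
        return (
            self.accel_noise_sd == 0.0
            and self.bias == 0.0
            and self.bias_drift_rate == 0.0
        )


def corrupt_to_imu(trial: ImuTrial, noise: NoiseModel) -> ImuTrial:
    """Return a copy of ``trial`` with corrupted accelerations; truth unchanged."""
    if noise.is_null():
        return trial
    rng = np.random.default_rng(noise.seed)
    t = trial.t - trial.t[0]
    n = len(t)
    ax = trial.ax + noise.bias + noise.bias_drift_rate * t
    ay = trial.ay + noise.bias + noise.bias_drift_rate * t
    if noise.accel_noise_sd > 0:
        ax = ax + rng.normal(0.0, noise.accel_noise_sd, n)
        ay = ay + rng.normal(0.0, noise.accel_noise_sd, n)
    return replace(trial, ax=ax, ay=ay)
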