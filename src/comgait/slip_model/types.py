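"""State, kinetics and trajectory containers for the compliant walker."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from comgait.slip_model.params import SlipParams, TouchdownRefs

TRAJECTORY_COLUMNS = ["t", "x", "y", "l", "theta", "fx", "fy", "Ta", "fa"]


@dataclass(frozen=True)
class SlipState:
    """Instantaneous model state: spring geometry plus CoM kinematics."""

    l: float       # total spring length, contact->CoM [m]
    theta: float   # leg angle, clockwise-positive from vertical [rad]
    x: float       # CoM anterior position [m]
    y: float       # CoM height [m]
    dl: float = 0.0
    dtheta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("SlipState.l must be positive")
        if self.y <= 0:
            raise ValueError("SlipState.y must be positive during stance")


@dataclass(frozen=True)
class AugmentedState:
    """3-vector z = (l, theta, l*theta).

    ``exact`` records whether the third component was built as the literal
    product (nonlinear construction) or produced by a linearized map, in
    which case the product identity is not required to hold.
    """

    z: np.ndarray
    exact: bool = True

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.shape != (3,):
            raise ValueError("AugmentedState.z must be a 3-vector")
        object.__setattr__(self, "z", z)
        if self.exact and not math.isclose(
            z[2], z[0] * z[1], rel_tol=1e-9, abs_tol=1e-9
        ):
            raise ValueError("z[2] must equal z[0]*z[1] for an exact state")

    @classmethod
    def from_state(cls, state: SlipState) -> "AugmentedState":
        return cls(np.array([state.l, state.theta, state.l * state.theta]))


@dataclass(frozen=True)
class KineticsVector:
    """f = (fx, fy, Ta): horizontal GRF, vertical GRF, ankle torque."""

    f: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (3,):
            raise ValueError("KineticsVector.f must be a 3-vector")
        if not np.all(np.isfinite(f)):
            raise ValueError("KineticsVector entries must be finite")
        object.__setattr__(self, "f", f)

    @property
    def fx(self) -> float:
        return float(self.f[0])

    @property
    def fy(self) -> float:
        return float(self.f[1])

    @property
    def Ta(self) -> float:
        return float(self.f[2])


@dataclass(frozen=True)
class SegmentAngles:
    """theta123 = (theta1, theta2, theta3) segment angles, clockwise-positive."""

    theta123: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.theta123, dtype=float)
        if a.shape != (3,):
            raise ValueError("SegmentAngles.theta123 must be a 3-vector")
        if np.any(np.abs(a) >= math.pi):
            raise ValueError("segment angles must lie in (-pi, pi)")
        object.__setattr__(self, "theta123", a)


@dataclass
class StanceTrajectory:
    """Sampled single-stance solution of the nonlinear walker.

    All arrays share the time grid ``t``.  ``events`` holds the located
    touchdown and liftoff times.
    """

    t: np.ndarray
    states: list[SlipState]
    grf: np.ndarray            # (n, 2): fx, fy
    ankle_torque: np.ndarray   # (n,)
    constraint_force: np.ndarray  # (n,)
    events: dict[str, float] = field(default_factory=dict)
    params: SlipParams | None = None
    refs: TouchdownRefs | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("StanceTrajectory.t must be strictly increasing")
        self.t = t

    @property
    def duration(self) -> float:
        return float(self.events.get("liftoff", self.t[-1]) - self.t[0])

    def energy(self) -> np.ndarray:
        """Total mechanical energy ledger (kinetic + gravitational + elastic)."""
        if self.params is None:
            raise ValueError("params required for the energy ledger")
        p = self.params
        e = np.empty(len(self.t))
        for i, s in enumerate(self.states):
            v2 = s.dx * s.dx + s.dy * s.dy
            ls = s.l - p.R
            e[i] = (
                0.5 * p.m * v2
                + p.m * p.g * s.y
                + 0.5 * p.k_a * (p.l_a - ls) ** 2
            )
        return e

    # -- CSV round trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t": self.t,
            "x": [s.x for s in self.states],
            "y": [s.y for s in self.states],
            "l": [s.l for s in self.states],
            "theta": [s.theta for s in self.states],
            "fx": self.grf[:, 0],
            "fy": self.grf[:, 1],
            "Ta": self.ankle_torque,
            "fa": self.constraint_force,
        }
        return pd.DataFrame(data, columns=TRAJECTORY_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        """Write the trajectory plus a JSON sidecar for params/refs/events."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        sidecar = {
            "events": self.events,
            "params": self.params.to_dict() if self.params else None,
            "refs": self.refs.to_dict() if self.refs else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path) -> "StanceTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
        sidecar_path = path.with_suffix(".json")
        events, params, refs = {}, None, None
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            events = sidecar.get("events", {})
            if sidecar.get("params"):
                params = SlipParams.from_dict(sidecar["params"])
            if sidecar.get("refs"):
                refs = TouchdownRefs.from_dict(sidecar["refs"])
        t = df["t"].to_numpy()
        dt = np.gradient(df["x"].to_numpy(), t), np.gradient(df["y"].to_numpy(), t)
        states = [
            SlipState(
                l=row.l, theta=row.theta, x=row.x, y=row.y,
                dx=dt[0][i], dy=dt[1][i],
            )
            for i, row in enumerate(df.itertuples())
        ]
        return cls(
            t=t,
            states=states,
            grf=df[["fx", "fy"]].to_numpy(),
            ankle_torque=df["Ta"].to_numpy(),
            constraint_force=df["fa"].to_numpy(),
            events=events,
            params=params,
            refs=refs,
        )
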