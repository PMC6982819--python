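"""Physical parameters of the compliant walking model and touchdown references.

Conventions used throughout the package: ``x`` anterior, ``y`` up, angles
measured from the vertical with a positive sign for clockwise (anterior)
tilt when the subject walks towards +x.  The leg angle at touchdown is
therefore negative (CoM behind the fresh contact).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

G_DEFAULT = 9.81


@dataclass(frozen=True)
class SlipParams:
    """Parameters of the compliant walker (leg spring + off-centered curvy foot).

    The translational leg spring spans the ankle--CoM segment: stiffness
    ``k_a``, rest length ``l_a``.  The affine state-to-kinetics map is
    written in terms of the *total* leg (contact to CoM): stiffness ``k``
    and rest length ``l0``, which for this model reduce to ``k = k_a`` and
    ``l0 = l_a + R``.  ``cl`` and ``ck`` are dimensionless linearization
    coefficients evaluated at the reference configuration (vertical,
    unloaded leg); when left ``None`` they are computed from the model
    geometry, see :func:`linearization_coefficients`.
    """

    m: float = 72.0          # body mass [kg]
    h: float = 1.69          # stature [m]
    k: float = 15_000.0      # total-leg stiffness used in the affine maps [N/m]
    l0: float = 0.845        # total-leg rest length, contact->CoM [m]
    k_a: float = 15_000.0    # ankle--CoM spring stiffness [N/m]
    l_a: float = 0.545       # ankle--CoM spring rest length [m]
    R: float = 0.3           # curvy-foot radius [m]
    d: float = 0.05          # ankle offset (posterior) from the foot-arc center [m]
    l1: float = 0.30         # thigh length [m]
    l2: float = 0.30         # shank length [m]
    l3: float = 0.20         # foot length [m]
    g: float = G_DEFAULT     # gravitational acceleration [m/s^2]
    cl: float | None = None  # kinetics linearization coefficient (dimensionless)
    ck: float | None = None  # kinematics linearization coefficient (dimensionless)

    def __post_init__(self) -> None:
        for name in ("m", "k", "l0", "k_a", "l_a", "R", "l1", "l2", "l3", "h", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SlipParams.{name} must be positive")
        if self.R >= self.l0:
            raise ValueError("foot radius R must be smaller than leg rest length l0")
        if self.l1 + self.l2 < self.l_a:
            raise ValueError(
                "thigh + shank must reach the ankle: l1 + l2 >= l_a required"
            )
        if self.l1 + self.l2 > self.l0 + 1e-6:
            raise ValueError("l1 + l2 must not exceed the total leg length l0")

    # -- derived values ----------------------------------------------------

    @property
    def cl_eff(self) -> float:
        return self.cl if self.cl is not None else linearization_coefficients(self)[0]

    @property
    def ck_eff(self) -> float:
        return self.ck if self.ck is not None else linearization_coefficients(self)[1]

    def dimensionless_stiffness(self) -> float:
        """k*l0/(m*g), ~20 for human-like walking."""
        return self.k * self.l0 / (self.m * self.g)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SlipParams":
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SlipParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_params(
    m: float = 72.0,
    h: float = 1.69,
    dimensionless_k: float = 20.0,
    R: float = 0.3,
    d: float = 0.05,
    g: float = G_DEFAULT,
) -> SlipParams:
    """Anthropometrically scaled defaults for a subject of mass ``m``, height ``h``.

    Leg rest length l0 = 0.9*h/1.8 (≈ trochanter height plus foot arc),
    stiffness set through the dimensionless group k*l0/(m*g).
    """
    l0 = 0.9 * h / 1.8
    k = dimensionless_k * m * g / l0
    l_a = l0 - R
    # Slight knee slack so the two-link chain is never singular at full reach.
    seg = 0.515 * l_a
    return SlipParams(
        m=m, h=h, k=k, l0=l0, k_a=k, l_a=l_a, R=R, d=d,
        l1=seg, l2=seg, l3=0.152 * h, g=g,
    )


def linearization_coefficients(params: SlipParams) -> tuple[float, float]:
    """(cl, ck) from the model's exact linearization at the reference.

    Reference configuration: vertical, unloaded leg (theta = 0, l = l0).

    * ``cl`` calibrates the ankle-torque row of the state-to-kinetics map:
      the exact first-order ankle torque is k*d*(1 - R/l0)*(l - l0), while
      the affine map carries -k*d*cl*(l - l0); hence cl = R/l0 - 1.
    * ``ck`` calibrates the thigh row of the state-to-angles map: the
      two-link inverse kinematics gives d(theta_thigh)/dl = beta'(D) at
      reference reach D = l0 - R, and the affine map carries (1-ck)/l1,
      hence ck = 1 - l1*beta'(D).
    """
    cl = params.R / params.l0 - 1.0
    D = params.l0 - params.R
    l1, l2 = params.l1, params.l2
    cos_b = (l1 * l1 + D * D - l2 * l2) / (2.0 * l1 * D)
    cos_b = min(max(cos_b, -1.0), 1.0)
    sin_b = math.sqrt(max(1.0 - cos_b * cos_b, 1e-12))
    dcos_dD = (D * D - l1 * l1 + l2 * l2) / (2.0 * l1 * D * D)
    dbeta_dD = -dcos_dD / sin_b
    ck = 1.0 - l1 * dbeta_dD
    return cl, ck


@dataclass(frozen=True)
class TouchdownRefs:
    """Geometric references frozen at heel strike for one stance.

    ``alpha = R*theta_hs - c_hs + d`` is the composite horizontal offset
    appearing in the CoM-to-state map.
    """

    theta_hs: float  # leg angle at heel strike [rad]
    y_hs: float      # CoM height at heel strike [m]
    c_hs: float      # ground contact position at heel strike [m]
    R: float = 0.3
    d: float = 0.05
    alpha: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.y_hs <= 0:
            raise ValueError("TouchdownRefs.y_hs must be positive")
        expected = self.R * self.theta_hs - self.c_hs + self.d
        if math.isnan(self.alpha):
            object.__setattr__(self, "alpha", expected)
        elif abs(self.alpha - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                f"stored alpha={self.alpha} inconsistent with "
                f"R*theta_hs - c_hs + d = {expected}"
            )

    @classmethod
    def from_params(
        cls, params: SlipParams, theta_hs: float, c_hs: float = 0.0,
        y_hs: float | None = None,
    ) -> "TouchdownRefs":
        if y_hs is None:
            # CoM height at touchdown from the model geometry.
            y_hs = (
                params.R
                + params.d * math.sin(theta_hs)
                + params.l_a * math.cos(theta_hs)
            )
        return cls(theta_hs=theta_hs, y_hs=y_hs, c_hs=c_hs, R=params.R, d=params.d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TouchdownRefs":
        return cls(**data)
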