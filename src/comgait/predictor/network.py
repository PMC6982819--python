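"""A small fully connected network: 7 inputs, sigmoid hidden layer, 11
linear outputs.  Implemented directly on numpy so that weights serialize
to plain JSON and training is deterministic given a seed."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class NetworkSpec:
    input_dim: int = 7
    hidden_dim: int = 20
    output_dim: int = 11
    hidden_activation: str = "sigmoid"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_dim, self.output_dim) < 1:
            raise ValueError("network dimensions must be positive")
        if self.hidden_activation != "sigmoid":
            raise ValueError("only sigmoid hidden activation is supported")
        if self.output_activation != "linear":
            raise ValueError("only linear output activation is supported")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Weights live in ``params`` as (W_h, b_h, W_out, b_out)."""

    def __init__(self, spec: NetworkSpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(input_dim, n) -> (output_dim, n); also accepts a single column."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        if x.shape[0] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} input rows, got {x.shape[0]}"
            )
        p = self.params
        h = _sigmoid(p["W_h"] @ x + p["b_h"])
        y = p["W_out"] @ h + p["b_out"]
        return y[:, 0] if squeeze else y

    __call__ = forward

    def copy(self) -> "MLP":
        return MLP(self.spec, {k: v.copy() for k, v in self.params.items()})

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec.__dict__,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLP":
        payload = json.loads(Path(path).read_text())
        spec = NetworkSpec(**payload["spec"])
        params = {k: np.asarray(v, float) for k, v in payload["params"].items()}
        return cls(spec, params)


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> MLP:
    """Glorot-uniform initialized network, deterministic given ``seed``."""
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)

    def glorot(fan_out: int, fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    params = {
        "W_h": glorot(spec.hidden_dim, spec.input_dim),
        "b_h": np.zeros((spec.hidden_dim, 1)),
        "W_out": glorot(spec.output_dim, spec.hidden_dim),
        "b_out": np.zeros((spec.output_dim, 1)),
    }
    return MLP(spec, params)
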