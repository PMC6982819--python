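"""Adam training loop over per-phase-sample (7-in, 11-out) pairs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from comgait.predictor.network import MLP, _sigmoid


class DivergenceError(RuntimeError):
    """Raised when the loss turns non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 256
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    shuffle: bool = True


@dataclass
class TrainResult:
    model: MLP
    loss_curve: np.ndarray = field(default_factory=lambda: np.array([]))


def _forward_backward(
    model: MLP, x: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    p = model.params
    h = _sigmoid(p["W_h"] @ x + p["b_h"])
    pred = p["W_out"] @ h + p["b_out"]
    err = pred - y
    n = x.shape[1]
    loss = float(np.mean(err * err))
    # d(mean squared error)/d(pred), averaged over outputs and samples
    g_pred = 2.0 * err / (err.size)
    grads = {
        "W_out": g_pred @ h.T,
        "b_out": g_pred.sum(axis=1, keepdims=True),
    }
    g_h = (p["W_out"].T @ g_pred) * h * (1.0 - h)
    grads["W_h"] = g_h @ x.T
    grads["b_h"] = g_h.sum(axis=1, keepdims=True)
    return loss, grads


def train_network(
    model: MLP,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainResult:
    """Train in place on column-aligned (input_dim, N) / (output_dim, N) data.

    Mean squared error over all outputs, Adam updates, minibatch order
    shuffled with the seeded generator.  Returns the per-epoch loss curve.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError("features and labels must be column-aligned 2-D arrays")
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[1]
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            cols = order[lo: lo + cfg.batch_size]
            loss, grads = _forward_backward(model, x[:, cols], y[:, cols])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "loss became non-finite; try a lower learning rate"
                )
            step += 1
            for k, g in grads.items():
                m_state[k] = cfg.beta1 * m_state[k] + (1 - cfg.beta1) * g
                v_state[k] = cfg.beta2 * v_state[k] + (1 - cfg.beta2) * g * g
                m_hat = m_state[k] / (1 - cfg.beta1**step)
                v_hat = v_state[k] / (1 - cfg.beta2**step)
                model.params[k] -= (
                    cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)
                )
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return TrainResult(model=model, loss_curve=np.asarray(losses))


def predict_outputs(model: MLP, features: np.ndarray) -> np.ndarray:
    """Per-column forward pass: (input_dim, n) -> (output_dim, n)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] != model.spec.input_dim:
        raise ValueError(
            f"feature block must be ({model.spec.input_dim}, n), got {x.shape}"
        )
    return model.forward(x)
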