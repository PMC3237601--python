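"""A small one-hidden-layer logistic network trained by mini-batch SGD.

This is the stage-1 learner: logistic hidden units, a logistic output in
(0, 1), 0/1 targets, squared-error loss by default (cross-entropy via
config), trained for a fixed number of cycles through the data.  Everything
stochastic (weight initialisation, per-epoch shuffling) is driven by one
explicit seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkParams", "LogisticMLP"]


@dataclass(frozen=True)
class NetworkParams:
    """Stage-1 training hyper-parameters (defaults are deliberately small)."""

    hidden_units: int = 5
    learning_rate: float = 1.0  # batch-averaged gradients: ~lr/batch per sample
    epochs: int = 100
    batch_size: int = 32
    loss: str = "mse"  # "mse" or "cross_entropy"

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive (fixed-cycle training)")
        if self.hidden_units < 1 or self.batch_size < 1:
            raise ValueError("hidden_units and batch_size must be >= 1")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clip to keep exp() finite; saturates at ~1e-300 either side
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class LogisticMLP:
    """input -> logistic hidden layer -> logistic scalar output."""

    def __init__(self, n_inputs: int, params: NetworkParams, seed: int):
        self.n_inputs = int(n_inputs)
        self.params = params
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        h = params.hidden_units
        # small random init scaled by fan-in
        self.w1 = rng.normal(0.0, 1.0 / np.sqrt(max(n_inputs, 1)), size=(n_inputs, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        self.b2 = 0.0
        self._rng = rng
        self.loss_history: list = []

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores in (0, 1) for an (n, n_inputs) pattern matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        hidden = _sigmoid(X @ self.w1 + self.b1)
        return _sigmoid(hidden @ self.w2 + self.b2)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticMLP":
        """Train for exactly ``params.epochs`` cycles over the data."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(f"expected (n, {self.n_inputs}) patterns, got {X.shape}")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
            raise ValueError("training set must contain both classes with 0/1 targets")
        n = X.shape[0]
        p = self.params
        lr = p.learning_rate
        for _ in range(p.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, p.batch_size):
                idx = order[start:start + p.batch_size]
                xb, yb = X[idx], y[idx]
                hidden = _sigmoid(xb @ self.w1 + self.b1)
                out = _sigmoid(hidden @ self.w2 + self.b2)
                if p.loss == "mse":
                    delta_out = (out - yb) * out * (1.0 - out)
                    epoch_loss += float(((out - yb) ** 2).sum())
                else:  # cross-entropy with logistic output
                    delta_out = out - yb
                    eps = 1e-12
                    epoch_loss += float(
                        -(yb * np.log(out + eps) + (1 - yb) * np.log(1 - out + eps)).sum()
                    )
                grad_w2 = hidden.T @ delta_out / len(idx)
                grad_b2 = delta_out.mean()
                delta_hidden = np.outer(delta_out, self.w2) * hidden * (1.0 - hidden)
                grad_w1 = xb.T @ delta_hidden / len(idx)
                grad_b1 = delta_hidden.mean(axis=0)
                self.w2 -= lr * grad_w2
                self.b2 -= lr * grad_b2
                self.w1 -= lr * grad_w1
                self.b1 -= lr * grad_b1
            self.loss_history.append(epoch_loss / n)
        return self

    # -- serialization ------------------------------------------------------

    def state(self) -> dict:
        return {
            "w1": self.w1, "b1": self.b1, "w2": self.w2,
            "b2": np.array(self.b2), "seed": np.array(self.seed),
        }

    @classmethod
    def from_state(cls, n_inputs: int, params: NetworkParams, state: dict) -> "LogisticMLP":
        net = cls(n_inputs, params, int(state["seed"]))
        net.w1 = np.asarray(state["w1"], dtype=float)
        net.b1 = np.asarray(state["b1"], dtype=float)
        net.w2 = np.asarray(state["w2"], dtype=float)
        net.b2 = float(state["b2"])
        return net
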