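"""Adam optimization with accuracy-monitored early stopping.

Training minimizes binary cross-entropy on the sigmoid output (computed in
logit form for numerical stability) and monitors validation accuracy: if it
has not increased for ``patience`` epochs the run stops and the parameters of
the best epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chickcall.errors import DataError, TrainingError
from chickcall.nn.autograd import Tensor, bce_with_logits
from chickcall.nn.layers import Module


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    """Per-epoch record of one training run (epochs are 1-based)."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def predict_logits(model: Module, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Forward pass in eval mode, batched; returns flat logits."""
    model.eval()
    outs = [model(Tensor(x[i : i + batch_size])).data.ravel()
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs) if outs else np.zeros(0)


def _evaluate(model: Module, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    logits = predict_logits(model, x, batch_size)
    yf = y.astype(np.float64)
    loss = float(np.mean(np.maximum(logits, 0) - logits * yf + np.log1p(np.exp(-np.abs(logits)))))
    acc = float(np.mean((logits > 0) == (yf > 0.5)))
    return loss, acc


def fit(
    model: Module,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    max_epochs: int = 2000,
    patience: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Train with Adam + early stopping on validation accuracy.

    The model is left holding the parameters of the best epoch.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise DataError("training and validation sets must be non-empty")
    if len(x_train) != len(y_train) or len(x_val) != len(y_val):
        raise DataError("features and labels disagree in length")

    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=lr)
    history = TrainHistory()
    best_acc, best_state, wait = -np.inf, None, 0

    for epoch in range(1, max_epochs + 1):
        model.train()
        order = rng.permutation(len(x_train))
        losses, hits, total = [], 0, 0
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model(Tensor(xb))
            loss = bce_with_logits(logits, yb.reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} (lr={lr}, batch={len(idx)}); "
                    "try a lower learning rate"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            hits += int(np.sum((logits.data.ravel() > 0) == (yb > 0.5)))
            total += len(idx)
        val_loss, val_acc = _evaluate(model, x_val, y_val, batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(hits / total)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if verbose:
            print(f"epoch {epoch}: loss {history.train_loss[-1]:.4f} "
                  f"val_acc {val_acc:.3f}")
        if val_acc > best_acc:
            best_acc, wait = val_acc, 0
            history.best_epoch = epoch
            best_state = model.state_dict()
        else:
            wait += 1
        history.stopped_epoch = epoch
        if wait >= patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history
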