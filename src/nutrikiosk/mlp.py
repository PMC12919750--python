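"""Minimal feed-forward network for the triage classifier.

A deliberately small, fully deterministic numpy implementation of the exact
architecture the recommendation engine uses: dense layers with
batch-normalization, ReLU and inverted dropout, a softmax head, categorical
cross-entropy with L2 weight decay, Adam, and early stopping on validation
loss with best-weight restoration.

Layer order per hidden block is dense -> batch-norm -> ReLU -> dropout.
All randomness (initialization, shuffling, dropout masks) flows from one
seeded generator, so training is bit-reproducible on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["MLPSpec", "TrainingHistory", "NeuralNet", "train_network"]

_EPS = 1e-5  # batch-norm variance floor


@dataclass(frozen=True)
class MLPSpec:
    """Hyperparameters of the triage network (defaults are the shipped model)."""

    input_dim: int = 15
    hidden_layers: tuple[int, ...] = (64, 64, 64)
    output_dim: int = 3
    batch_norm: bool = True
    dropout_rate: float = 0.3
    l2_lambda: float = 1e-4
    learning_rate: float = 0.001
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 32
    lr_decay_factor: float = 0.5   # reduce-on-plateau step when val loss stalls
    lr_decay_patience: int = 3
    lr_floor: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be > 0")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based epoch whose weights were restored

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


class NeuralNet:
    """Parameter store plus forward/backward passes for the MLP."""

    def __init__(self, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_layers, spec.output_dim]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        n_hidden = len(spec.hidden_layers)
        self.gamma = [np.ones(h) for h in spec.hidden_layers]
        self.beta = [np.zeros(h) for h in spec.hidden_layers]
        self.run_mean = [np.zeros(h) for h in spec.hidden_layers]
        self.run_var = [np.ones(h) for h in spec.hidden_layers]
        self.bn_momentum = 0.9
        self.n_hidden = n_hidden

    # -- parameter bookkeeping -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, *self.gamma, *self.beta]

    def layer_shapes(self) -> list[tuple[int, int]]:
        return [w.shape for w in self.W]

    def snapshot(self) -> dict:
        return {
            "W": [w.copy() for w in self.W],
            "b": [b.copy() for b in self.b],
            "gamma": [g.copy() for g in self.gamma],
            "beta": [b.copy() for b in self.beta],
            "run_mean": [m.copy() for m in self.run_mean],
            "run_var": [v.copy() for v in self.run_var],
        }

    def restore(self, snap: dict) -> None:
        for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
            setattr(self, name, [a.copy() for a in snap[name]])

    # -- forward ---------------------------------------------------------------
    def forward(
        self, X: np.ndarray, training: bool, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[dict]]:
        """Softmax probabilities and, in training mode, a per-layer cache."""
        spec = self.spec
        caches: list[dict] = []
        a = X
        for i in range(self.n_hidden):
            z = a @ self.W[i] + self.b[i]
            cache: dict = {"a_in": a}
            if spec.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean[i] = self.bn_momentum * self.run_mean[i] + (1 - self.bn_momentum) * mu
                    self.run_var[i] = self.bn_momentum * self.run_var[i] + (1 - self.bn_momentum) * var
                else:
                    mu, var = self.run_mean[i], self.run_var[i]
                inv_std = 1.0 / np.sqrt(var + _EPS)
                zhat = (z - mu) * inv_std
                h = self.gamma[i] * zhat + self.beta[i]
                cache.update(zhat=zhat, inv_std=inv_std)
            else:
                h = z
            relu_mask = h > 0
            a = h * relu_mask
            cache["relu_mask"] = relu_mask
            if training and spec.dropout_rate > 0:
                keep = 1.0 - spec.dropout_rate
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
                cache["drop_mask"] = mask
            caches.append(cache)
        logits = a @ self.W[-1] + self.b[-1]
        caches.append({"a_in": a})
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, caches

    def backward(
        self, probs: np.ndarray, Y: np.ndarray, caches: list[dict]
    ) -> list[np.ndarray]:
        """Gradients in the same order as :meth:`parameters`."""
        spec = self.spec
        B = probs.shape[0]
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gGamma = [np.zeros_like(g) for g in self.gamma]
        gBeta = [np.zeros_like(b) for b in self.beta]

        delta = (probs - Y) / B
        gW[-1] = caches[-1]["a_in"].T @ delta + 2 * spec.l2_lambda * self.W[-1]
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for i in range(self.n_hidden - 1, -1, -1):
            cache = caches[i]
            if "drop_mask" in cache:
                da = da * cache["drop_mask"]
            dh = da * cache["relu_mask"]
            if spec.batch_norm:
                zhat, inv_std = cache["zhat"], cache["inv_std"]
                gGamma[i] = (dh * zhat).sum(axis=0)
                gBeta[i] = dh.sum(axis=0)
                dzhat = dh * self.gamma[i]
                dz = inv_std / B * (
                    B * dzhat
                    - dzhat.sum(axis=0)
                    - zhat * (dzhat * zhat).sum(axis=0)
                )
            else:
                dz = dh
            gW[i] = cache["a_in"].T @ dz + 2 * spec.l2_lambda * self.W[i]
            gb[i] = dz.sum(axis=0)
            da = dz @ self.W[i].T
        return [*gW, *gb, *gGamma, *gBeta]

    # -- inference -------------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(np.asarray(X, dtype=float), training=False)
        return probs

    def loss_acc(self, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
        probs = self.predict_proba(X)
        ce = -np.mean(np.log(np.clip((probs * Y).sum(axis=1), 1e-12, None)))
        l2 = self.spec.l2_lambda * sum(float((w**2).sum()) for w in self.W)
        acc = float((probs.argmax(axis=1) == Y.argmax(axis=1)).mean())
        return float(ce + l2), acc


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train_network(
    spec: MLPSpec,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
) -> tuple[NeuralNet, TrainingHistory]:
    """Mini-batch Adam with early stopping on validation loss.

    The learning rate is reduced on plateau (halved after
    ``lr_decay_patience`` stale epochs, floored at ``lr_floor``), which lets
    the network sharpen the hard decision thresholds late in training.
    Stops after ``early_stop_patience`` epochs without improvement or at
    ``max_epochs``, then restores the best-validation-loss weights.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(spec.seed)
    net = NeuralNet(spec, rng)
    opt = _Adam(net.parameters(), spec.learning_rate)
    hist = TrainingHistory()
    best_loss = np.inf
    best_snap = net.snapshot()
    best_epoch = 0
    stale = 0
    lr_stale = 0
    n = len(X_train)
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            if len(idx) < 2 and spec.batch_norm:
                continue  # batch statistics undefined on a single sample
            probs, caches = net.forward(X_train[idx], training=True, rng=rng)
            grads = net.backward(probs, Y_train[idx], caches)
            opt.step(net.parameters(), grads)
        tr_loss, tr_acc = net.loss_acc(X_train, Y_train)
        va_loss, va_acc = net.loss_acc(X_val, Y_val)
        hist.train_loss.append(tr_loss)
        hist.train_acc.append(tr_acc)
        hist.val_loss.append(va_loss)
        hist.val_acc.append(va_acc)
        if va_loss < best_loss - 1e-6:
            best_loss = va_loss
            best_snap = net.snapshot()
            best_epoch = epoch
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if lr_stale >= spec.lr_decay_patience:
                opt.lr = max(opt.lr * spec.lr_decay_factor, spec.lr_floor)
                lr_stale = 0
            if stale >= spec.early_stop_patience:
                break
    net.restore(best_snap)
    hist.best_epoch = best_epoch
    return net, hist
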