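"""Minimal neural-network engine: dense regression networks (tanh or
ReLU hidden layers) and an LSTM regressor with mean-absolute-error loss
and Adam, in plain numpy.

Training here is deterministic under a seed (fixed initialization, fixed
shuffling stream, sequential updates), which the surrogate determinism
contracts require.  Backward passes are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivergenceError",
    "Adam",
    "MLP",
    "LSTMRegressor",
    "TrainingHistory",
    "fit_network",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class Adam:
    """Adaptive moment estimation with the conventional defaults
    (beta1 = 0.9, beta2 = 0.999, eps = 1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mae_loss_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its subgradient w.r.t. the predictions."""
    r = pred - y
    return float(np.mean(np.abs(r))), np.sign(r) / r.size


class MLP:
    """Fully connected regression network with a linear scalar output.

    Hidden activation is ``tanh`` (default; Glorot-uniform init) or
    ``relu`` (He-uniform init); seeded and deterministic.
    """

    def __init__(self, layer_sizes: list[int], seed: int = 0,
                 activation: str = "tanh", dtype=np.float64):
        if layer_sizes[-1] != 1:
            raise ValueError("output layer must have width 1")
        if activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.activation = activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            if activation == "relu":
                s = math.sqrt(6.0 / fan_in)
            else:
                s = math.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-s, s, size=(fan_in, fan_out)).astype(dtype))
            self.b.append(np.zeros(fan_out, dtype=dtype))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def forward(self, X: np.ndarray, cache: bool = False):
        a = X.astype(self.dtype, copy=False)
        acts = [a]
        n = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i == n - 1:
                a = z
            elif self.activation == "relu":
                a = np.maximum(z, 0.0)
            else:
                a = np.tanh(z)
            acts.append(a)
        return (a[:, 0], acts) if cache else a[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def backward(self, acts: list[np.ndarray], dout: np.ndarray) -> list[np.ndarray]:
        """Gradients in the order of ``params`` given d(loss)/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout[:, None].astype(self.dtype, copy=False)
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = acts[i]
            gW[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                if self.activation == "relu":
                    delta = (delta @ self.W[i].T) * (acts[i] > 0.0)
                else:
                    delta = (delta @ self.W[i].T) * (1.0 - acts[i] * acts[i])
        return [*gW, *gb]


class LSTMRegressor:
    """Single-layer LSTM over a scalar history channel, concatenated with
    static features into a linear head.

    The carry and hidden states are reset at every window; context enters
    only through the fixed-length history.  Gate order: input, forget,
    cell, output.  Forget-gate bias initialized to 1.
    """

    def __init__(self, units: int = 32, n_static: int = 0, seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.units = units
        self.n_static = n_static
        self.dtype = dtype
        u = units
        sx = math.sqrt(6.0 / (1 + u))
        sh = math.sqrt(6.0 / (u + u))
        self.Wx = rng.uniform(-sx, sx, size=(1, 4 * u)).astype(dtype)
        self.Wh = rng.uniform(-sh, sh, size=(u, 4 * u)).astype(dtype)
        self.bg = np.zeros(4 * u, dtype=dtype)
        self.bg[u: 2 * u] = 1.0  # forget bias
        so = math.sqrt(6.0 / (u + n_static))
        self.Wo = rng.uniform(-so, so, size=(u + n_static, 1)).astype(dtype)
        self.bo = np.zeros(1, dtype=dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.bg, self.Wo, self.bo]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, history: np.ndarray, static: np.ndarray,
                cache: bool = False):
        """history: (B, T) scalar sequence; static: (B, n_static)."""
        B, T = history.shape
        u = self.units
        h = np.zeros((B, u), dtype=self.dtype)
        c = np.zeros((B, u), dtype=self.dtype)
        caches = []
        for t in range(T):
            x = history[:, t: t + 1].astype(self.dtype, copy=False)
            z = x @ self.Wx + h @ self.Wh + self.bg
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u: 2 * u])
            g = np.tanh(z[:, 2 * u: 3 * u])
            o = self._sigmoid(z[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if cache:
                caches.append((x, h_prev, c_prev, i, f, g, o, tc))
        feat = np.concatenate(
            [h, static.astype(self.dtype, copy=False)], axis=1
        )
        out = (feat @ self.Wo + self.bo)[:, 0]
        return (out, (caches, feat)) if cache else out

    def predict(self, history: np.ndarray, static: np.ndarray) -> np.ndarray:
        return self.forward(history, static)

    def backward(self, cache, dout: np.ndarray) -> list[np.ndarray]:
        caches, feat = cache
        u = self.units
        d = dout[:, None].astype(self.dtype, copy=False)
        gWo = feat.T @ d
        gbo = d.sum(axis=0)
        dh = d @ self.Wo[:u].T
        dc = np.zeros_like(dh)
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gbg = np.zeros_like(self.bg)
        for t in range(len(caches) - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, tc = caches[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            gWx += x.T @ dz
            gWh += h_prev.T @ dz
            gbg += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [gWx, gWh, gbg, gWo, gbo]


@dataclass
class TrainingHistory:
    """Per-epoch training and monitoring losses; the best epoch minimizes
    the monitored loss (validation for feed-forward, training for the
    sequence model)."""

    train_loss: np.ndarray
    val_loss: np.ndarray | None = None
    monitor: str = "val"

    @property
    def monitored(self) -> np.ndarray:
        return self.val_loss if self.monitor == "val" else self.train_loss

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.monitored))


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start: start + batch_size]


def fit_network(
    net,
    forward_backward,
    evaluate,
    n_train: int,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
    monitor: str = "val",
) -> tuple[TrainingHistory, list[np.ndarray]]:
    """Generic seeded training loop with best-epoch snapshotting.

    ``forward_backward(batch_idx) -> (loss, grads)`` performs one batch;
    ``evaluate() -> val_loss or None`` scores the monitored set after each
    epoch.  Returns the loss history and the parameter snapshot of the
    epoch minimizing the monitored loss (training loss if ``monitor`` is
    "train").  Raises DivergenceError on a non-finite loss.
    """
    opt = Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed + 1_000_003)
    train_losses = np.empty(epochs)
    val_losses = np.empty(epochs) if monitor == "val" else None
    best = math.inf
    best_state = net.get_state()
    best_epoch = 0
    for epoch in range(epochs):
        tot, nb = 0.0, 0
        for bidx in _iter_batches(n_train, batch_size, rng):
            loss, grads = forward_backward(bidx)
            if not math.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.step(net.params, grads)
            tot += loss
            nb += 1
        train_losses[epoch] = tot / max(nb, 1)
        if monitor == "val":
            vl = evaluate()
            if not math.isfinite(vl):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            val_losses[epoch] = vl
            score = vl
        else:
            score = train_losses[epoch]
        if score < best:
            best = score
            best_state = net.get_state()
            best_epoch = epoch
    hist = TrainingHistory(train_loss=train_losses, val_loss=val_losses,
                           monitor=monitor)
    assert hist.best_epoch == best_epoch
    return hist, best_state
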