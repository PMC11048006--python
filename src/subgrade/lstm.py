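"""Minimal LSTM binary classifier in NumPy.

The tabular feature vector is treated as a length-F sequence of scalars fed
through a single LSTM layer; the final hidden state drives a logistic
output unit.  Trained with Adam on binary cross-entropy via full
backpropagation through time.  This is a deliberately small, dependency-free
implementation: the recurrent model plays a cameo role in the classifier
zoo and only needs a train/predict contract with probability outputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMClassifier:
    """Single-layer LSTM over scalar feature sequences.

    Parameters mirror the usual deep-learning conventions: Adam optimiser,
    binary cross-entropy loss, mini-batches, fixed epoch count.
    """

    def __init__(
        self,
        hidden_size: int = 16,
        epochs: int = 1000,
        batch_size: int = 16,
        learning_rate: float = 0.01,
        random_state: int = 42,
    ) -> None:
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.classes_ = np.array([0, 1])

    # -- parameter handling -------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        h = self.hidden_size
        scale = 1.0 / np.sqrt(h + 1)
        self.W_ = rng.uniform(-scale, scale, size=(4 * h, h + 1))
        self.b_ = np.zeros(4 * h)
        self.b_[h : 2 * h] = 1.0  # forget-gate bias: remember by default
        self.w_out_ = rng.uniform(-scale, scale, size=h)
        self.b_out_ = np.zeros(1)

    def _params(self) -> list[np.ndarray]:
        return [self.W_, self.b_, self.w_out_, self.b_out_]

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray):
        n, F = X.shape
        h = self.hidden_size
        hs = np.zeros((F + 1, n, h))
        cs = np.zeros((F + 1, n, h))
        cache = []
        for t in range(F):
            inp = np.concatenate([hs[t], X[:, t : t + 1]], axis=1)  # (n, h+1)
            z = inp @ self.W_.T + self.b_
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            cache.append((inp, i, f, g, o))
        logits = hs[F] @ self.w_out_ + self.b_out_
        return _sigmoid(logits), hs, cs, cache

    def _backward(self, X, y, p, hs, cs, cache):
        n, F = X.shape
        h = self.hidden_size
        dlogit = (p - y) / n
        dW = np.zeros_like(self.W_)
        db = np.zeros_like(self.b_)
        dw_out = hs[F].T @ dlogit
        db_out = dlogit.sum()
        dh = np.outer(dlogit, self.w_out_)
        dc = np.zeros((n, h))
        for t in range(F - 1, -1, -1):
            inp, i, f, g, o = cache[t]
            tanh_c = np.tanh(cs[t + 1])
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * cs[t]
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += dz.T @ inp
            db += dz.sum(axis=0)
            dinp = dz @ self.W_
            dh = dinp[:, :h]
            dc = dc * f
        return [dW, db, dw_out, np.atleast_1d(db_out)]

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.random_state)
        self._init_params(rng)
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                p, hs, cs, cache = self._forward(X[idx])
                grads = self._backward(X[idx], y[idx], p, hs, cs, cache)
                step += 1
                for j, (par, gr) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * gr
                    v[j] = beta2 * v[j] + (1 - beta2) * gr**2
                    mh = m[j] / (1 - beta1**step)
                    vh = v[j] / (1 - beta2**step)
                    par -= self.learning_rate * mh / (np.sqrt(vh) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, *_ = self._forward(np.asarray(X, dtype=np.float64))
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden_size": self.hidden_size,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "random_state": self.random_state,
        }

    def set_params(self, **kwargs) -> "LSTMClassifier":
        for k, val in kwargs.items():
            setattr(self, k, val)
        return self
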