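"""Single-hidden-layer tanh/softmax network trained with Adam.

This is the sub-classifier building block of the staging cascades: input
layer → one hyperbolic-tangent hidden layer → softmax output. It supports
per-class loss weights (inverse class frequency) and early stopping on a
development set, and is fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxNetwork:
    """Feedforward net: ``n_in → tanh(n_hidden) → softmax(n_out)``.

    Parameters
    ----------
    n_hidden : int
        Hidden units. Must be ≥ 1 (rule-based cascade periods bypass the net).
    l2 : float
        Weight decay on the linear maps.
    """

    def __init__(self, n_in: int, n_hidden: int, n_out: int, seed: int = 0,
                 l2: float = 1e-4):
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(6.0 / (n_in + n_hidden))
        s2 = np.sqrt(6.0 / (n_hidden + n_out))
        self.W1 = rng.uniform(-s1, s1, (n_in, n_hidden)).astype(np.float32)
        self.b1 = np.zeros(n_hidden, dtype=np.float32)
        self.W2 = rng.uniform(-s2, s2, (n_hidden, n_out)).astype(np.float32)
        self.b2 = np.zeros(n_out, dtype=np.float32)
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.l2 = l2
        self.seed = seed

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        h = np.tanh(X @ self.W1 + self.b1)
        return softmax((h @ self.W2 + self.b2).astype(np.float64))

    # -- training ----------------------------------------------------------
    def _loss(self, X, y_onehot, w) -> float:
        p = self.predict_proba(X)
        return float(-np.sum(w * np.log(np.sum(p * y_onehot, axis=1) + _EPS))
                     / (np.sum(w) + _EPS))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        class_weight: np.ndarray | None = None,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        max_iter: int = 120,
        batch_size: int = 256,
        lr: float = 1e-3,
        patience: int = 10,
    ) -> "SoftmaxNetwork":
        """Minibatch Adam on weighted cross-entropy.

        If a validation set is given, training keeps the parameters with the
        lowest validation loss and stops after ``patience`` epochs without
        improvement; otherwise it runs for ``max_iter`` epochs.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        cw = (np.ones(self.n_out) if class_weight is None
              else np.asarray(class_weight, dtype=np.float64))
        w_all = cw[y]
        Y = np.zeros((n, self.n_out), dtype=np.float32)
        Y[np.arange(n), y] = 1.0

        val = X_val is not None and y_val is not None and len(y_val) > 0
        if val:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=int)
            Yv = np.zeros((len(y_val), self.n_out), dtype=np.float32)
            Yv[np.arange(len(y_val)), y_val] = 1.0
            wv = cw[y_val]

        rng = np.random.default_rng(self.seed + 1)
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1m, b2m = 0.9, 0.999
        step = 0
        best_loss, best_params, bad = np.inf, None, 0

        for _ in range(max_iter):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb, wb = X[idx], Y[idx], w_all[idx].astype(np.float32)
                h = np.tanh(xb @ self.W1 + self.b1)
                p = softmax((h @ self.W2 + self.b2).astype(np.float64))
                # weighted cross-entropy gradient
                g_out = ((p - yb) * wb[:, None] / max(wb.sum(), _EPS)
                         ).astype(np.float32)
                gW2 = h.T @ g_out + self.l2 * self.W2
                gb2 = g_out.sum(axis=0)
                g_h = (g_out @ self.W2.T) * (1.0 - h * h)
                gW1 = xb.T @ g_h + self.l2 * self.W1
                gb1 = g_h.sum(axis=0)
                step += 1
                for p_, m_, v_, g_ in zip(params, m, v, (gW1, gb1, gW2, gb2)):
                    m_ *= b1m
                    m_ += (1 - b1m) * g_
                    v_ *= b2m
                    v_ += (1 - b2m) * g_ * g_
                    mhat = m_ / (1 - b1m ** step)
                    vhat = v_ / (1 - b2m ** step)
                    p_ -= (lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32)
            if val:
                loss = self._loss(X_val, Yv, wv)
                if loss < best_loss - 1e-6:
                    best_loss, bad = loss, 0
                    best_params = [p.copy() for p in params]
                else:
                    bad += 1
                    if bad >= patience:
                        break
        if val and best_params is not None:
            self.W1, self.b1, self.W2, self.b2 = best_params
        return self

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "l2": self.l2, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SoftmaxNetwork":
        obj = cls.__new__(cls)
        obj.W1, obj.b1, obj.W2, obj.b2 = d["W1"], d["b1"], d["W2"], d["b2"]
        obj.n_in, obj.n_hidden = obj.W1.shape
        obj.n_out = obj.W2.shape[1]
        obj.l2, obj.seed = d["l2"], d["seed"]
        return obj
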