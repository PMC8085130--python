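"""A small fully connected network trained with scaled conjugate gradient.

One hidden layer with logistic-sigmoid activation and a softmax output,
initialized with the Nguyen–Widrow rule and trained full-batch by Møller's
scaled conjugate gradient (SCG) on the mean cross-entropy.  Deterministic
given the seed.  Shared by the nucleus classifier and the patch QC model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def nguyen_widrow(n_in: np.intp, n_hidden: int, rng: np.random.Generator):
    """Nguyen–Widrow initialization for a sigmoid hidden layer.

    Random directions are normalized and scaled to ``0.7 * H**(1/D)`` so the
    active regions of the hidden units tile the (standardized) input range;
    biases are spread evenly across it.
    """
    w = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    beta = 0.7 * n_hidden ** (1.0 / max(n_in, 1))
    w = beta * w / norms
    b = beta * np.linspace(-1.0, 1.0, n_hidden)
    return w, b


def scg_minimize(fun_grad, w0: np.ndarray, max_iter: int, tol: float = 1e-8) -> np.ndarray:
    """Møller's scaled conjugate gradient on a differentiable objective.

    ``fun_grad(w) -> (f, g)``.  Runs at most ``max_iter`` weight updates
    (epochs); no stochastic line search, hence fully deterministic.
    """
    sigma0 = 1.0e-4
    lamb, lamb_bar = 1.0e-6, 0.0
    w = w0.copy()
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    success = True
    n = w.size
    delta = p_norm2 = 1.0
    for k in range(1, max_iter + 1):
        if success:
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-300:
                break
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sigma = fun_grad(w + sigma * p)
            s = (g_sigma - (-r)) / sigma
            delta = float(p @ s)
        delta += (lamb - lamb_bar) * p_norm2
        if delta <= 0:
            lamb_bar = 2.0 * (lamb - delta / p_norm2)
            delta = -delta + lamb * p_norm2
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        big_delta = 2.0 * delta * (f - f_new) / (mu * mu)
        if big_delta >= 0:
            w = w + alpha * p
            f = f_new
            r_new = -g_new
            lamb_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta_cg = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta_cg * p
            r = r_new
            if big_delta >= 0.75:
                lamb *= 0.25
        else:
            lamb_bar = lamb
            success = False
        if big_delta < 0.25:
            lamb += delta * (1.0 - big_delta) / p_norm2
        if float(np.linalg.norm(r)) < tol:
            break
    return w


@dataclass
class TinyMLP:
    """Weights of a 1-hidden-layer sigmoid/softmax network."""

    W1: np.ndarray  # (hidden, in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (classes, hidden)
    b2: np.ndarray  # (classes,)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a1 = _sigmoid(X @ self.W1.T + self.b1)
        return _softmax(a1 @ self.W2.T + self.b2)

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("W1", "b1", "W2", "b2")}

    @classmethod
    def from_dict(cls, d: dict) -> "TinyMLP":
        return cls(**{k: np.asarray(d[k], dtype=np.float64) for k in ("W1", "b1", "W2", "b2")})

    # -- training ----------------------------------------------------------

    @staticmethod
    def _unpack(w: np.ndarray, d: int, h: int, k: int):
        i = 0
        W1 = w[i : i + h * d].reshape(h, d); i += h * d
        b1 = w[i : i + h]; i += h
        W2 = w[i : i + k * h].reshape(k, h); i += k * h
        b2 = w[i : i + k]
        return W1, b1, W2, b2

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        n_classes: int,
        hidden: int = 20,
        seed: int = 0,
        epochs: int = 1000,
        l2: float = 1e-4,
    ) -> "TinyMLP":
        """Fit by SCG on mean cross-entropy with a small L2 penalty."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n, d = X.shape
        k = n_classes
        Y = np.eye(k)[y]
        rng = np.random.default_rng(seed)
        W1, b1 = nguyen_widrow(d, hidden, rng)
        W2 = rng.uniform(-0.5, 0.5, size=(k, hidden)) / np.sqrt(hidden)
        b2 = np.zeros(k)
        w0 = np.concatenate([W1.ravel(), b1, W2.ravel(), b2])

        def fun_grad(w: np.ndarray):
            W1, b1, W2, b2 = cls._unpack(w, d, hidden, k)
            a1 = _sigmoid(X @ W1.T + b1)
            p = _softmax(a1 @ W2.T + b2)
            f = -np.mean(np.sum(Y * np.log(p + 1e-300), axis=1))
            f += 0.5 * l2 * float(w @ w)
            dz2 = (p - Y) / n  # (n, k)
            gW2 = dz2.T @ a1
            gb2 = dz2.sum(axis=0)
            da1 = dz2 @ W2
            dz1 = da1 * a1 * (1.0 - a1)
            gW1 = dz1.T @ X
            gb1 = dz1.sum(axis=0)
            g = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2]) + l2 * w
            return f, g

        w = scg_minimize(fun_grad, w0, max_iter=epochs)
        return cls(*cls._unpack(w, d, hidden, k))
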