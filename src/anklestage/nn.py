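"""Minimal NumPy neural-network layers for the stage classifier.

Implements exactly the pieces the CNN-GRU decision model needs —
1-D convolution over time with same padding, ReLU, max-pooling,
a single-layer GRU, a linear head, softmax cross-entropy with an L2
penalty, and Adam — with hand-derived backward passes.  Everything is
dense float64 and seeded; model sizes here are small (tens of
thousands of parameters), so clarity wins over kernel-level speed.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


# ---------------------------------------------------------------- conv / pool

def conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded conv over time. X (B,T,Cin); W (Cout, K*Cin); b (Cout,)."""
    B, T, Cin = X.shape
    K = W.shape[1] // Cin
    pad = (K - 1) // 2
    Xp = np.zeros((B, T + 2 * pad, Cin))
    Xp[:, pad:pad + T] = X
    col = np.empty((B, T, K * Cin))
    for k in range(K):
        col[:, :, k * Cin:(k + 1) * Cin] = Xp[:, k:k + T]
    out = col @ W.T + b
    return out, col


def conv1d_backward(dout: np.ndarray, col: np.ndarray, W: np.ndarray, Cin: int):
    B, T, Cout = dout.shape
    K = W.shape[1] // Cin
    pad = (K - 1) // 2
    dW = dout.reshape(-1, Cout).T @ col.reshape(-1, K * Cin)
    db = dout.sum(axis=(0, 1))
    dcol = dout @ W
    dXp = np.zeros((B, T + 2 * pad, Cin))
    for k in range(K):
        dXp[:, k:k + T] += dcol[:, :, k * Cin:(k + 1) * Cin]
    return dXp[:, pad:pad + T], dW, db


def maxpool2_forward(X: np.ndarray):
    """Non-overlapping max pool of size 2 over time (trailing odd step dropped)."""
    B, T, C = X.shape
    Tp = T // 2
    Xr = X[:, :2 * Tp].reshape(B, Tp, 2, C)
    idx = Xr.argmax(axis=2)
    out = np.take_along_axis(Xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx, T)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, T = cache
    B, Tp, C = dout.shape
    dXr = np.zeros((B, Tp, 2, C))
    np.put_along_axis(dXr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    dX = np.zeros((B, T, C))
    dX[:, :2 * Tp] = dXr.reshape(B, 2 * Tp, C)
    return dX


# ------------------------------------------------------------------------ GRU

def gru_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                bx: np.ndarray, bh: np.ndarray):
    """Single-layer GRU; returns the final hidden state.

    Gate layout along the 3H axis is (reset, update, candidate); the
    candidate uses the reset gate on the recurrent term,
    n = tanh(x Wxn + bxn + r * (h Whn + bhn)).
    """
    B, T, D = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    caches = []
    for t in range(T):
        x_t = X[:, t]
        gx = x_t @ Wx + bx
        gh = h @ Wh + bh
        r = _sigmoid(gx[:, :H] + gh[:, :H])
        z = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
        ghn = gh[:, 2 * H:]
        n = np.tanh(gx[:, 2 * H:] + r * ghn)
        h_new = (1.0 - z) * n + z * h
        caches.append((x_t, h, r, z, n, ghn))
        h = h_new
    return h, caches


def gru_backward(dh: np.ndarray, caches, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop through time from a gradient on the final hidden state."""
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    dbx = np.zeros(3 * H)
    dbh = np.zeros(3 * H)
    dX = []
    for x_t, h_prev, r, z, n, ghn in reversed(caches):
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        da_n = dn * (1.0 - n**2)
        dghn = da_n * r
        dr = da_n * ghn
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        dgx = np.concatenate([da_r, da_z, da_n], axis=1)
        dgh = np.concatenate([da_r, da_z, dghn], axis=1)
        dWx += x_t.T @ dgx
        dWh += h_prev.T @ dgh
        dbx += dgx.sum(axis=0)
        dbh += dgh.sum(axis=0)
        dX.append(dgx @ Wx.T)
        dh = dh_prev + dgh @ Wh.T
    dX.reverse()
    return np.stack(dX, axis=1), dWx, dWh, dbx, dbh


# ----------------------------------------------------------------------- loss

def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    expo = np.exp(shifted)
    probs = expo / expo.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    return loss, dlogits, probs


# ----------------------------------------------------------------------- Adam

class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
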