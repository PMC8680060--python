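"""Minimal numpy neural-network layers with hand-derived backpropagation.

Only what the sequence tagger needs: an LSTM (run forwards or backwards
over padded batches with per-sequence lengths), embedding lookup, a linear
projection, and inverted dropout.  Every layer exposes ``forward`` and a
matching ``backward`` that returns parameter gradients and input gradients;
the analytic gradients are covered by numerical gradient-check tests.

Array conventions: a batch of sequences is a (T, B, D) array (time-major)
with an integer ``lengths`` vector of shape (B,); positions at or beyond a
sequence's length are padding and never influence outputs or gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["LSTM", "BiLSTM", "Embedding", "Linear", "dropout_mask", "clip_gradients"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], scale: Optional[float] = None) -> np.ndarray:
    """Glorot-style uniform initialization."""
    if scale is None:
        fan = sum(shape[-2:]) if len(shape) > 1 else shape[0]
        scale = np.sqrt(6.0 / fan)
    return rng.uniform(-scale, scale, size=shape)


@dataclass
class Linear:
    W: np.ndarray  # (D_in, D_out)
    b: np.ndarray  # (D_out,)

    @classmethod
    def create(cls, rng: np.random.Generator, d_in: int, d_out: int) -> "Linear":
        return cls(uniform_init(rng, (d_in, d_out)), np.zeros(d_out))

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        dW = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dx = dy @ self.W.T
        return dx, {"W": dW, "b": db}

    def params(self):
        return {"W": self.W, "b": self.b}


@dataclass
class Embedding:
    table: np.ndarray  # (V, D)
    trainable: bool = True

    @classmethod
    def create(cls, rng: np.random.Generator, n: int, dim: int, trainable: bool = True) -> "Embedding":
        return cls(uniform_init(rng, (n, dim), scale=np.sqrt(3.0 / dim)), trainable)

    def forward(self, idx: np.ndarray) -> np.ndarray:
        return self.table[idx]

    def backward(self, idx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(self.table)
        np.add.at(grad, idx.reshape(-1), dy.reshape(-1, dy.shape[-1]))
        return grad


class LSTM:
    """Single-direction LSTM over a padded batch.

    Gate layout along the last axis of the packed parameters is
    (input, forget, output, candidate).
    """

    def __init__(self, W: np.ndarray, U: np.ndarray, b: np.ndarray):
        self.W, self.U, self.b = W, U, b
        self.hidden = U.shape[0]

    @classmethod
    def create(cls, rng: np.random.Generator, d_in: int, hidden: int) -> "LSTM":
        W = uniform_init(rng, (d_in, 4 * hidden), scale=np.sqrt(6.0 / (d_in + hidden)))
        U = uniform_init(rng, (hidden, 4 * hidden), scale=np.sqrt(6.0 / (2 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        return cls(W, U, b)

    def params(self):
        return {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, X: np.ndarray, lengths: Optional[np.ndarray] = None):
        """X: (T, B, D) → H: (T, B, hidden).  Padded steps emit zeros."""
        T, B, _ = X.shape
        H = self.hidden
        if lengths is None:
            lengths = np.full(B, T, dtype=np.intp)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((T, B, H))
        cache = {"X": X, "lengths": lengths, "steps": []}
        for t in range(T):
            active = (t < lengths).astype(float)[:, None]
            pre = X[t] @ self.W + h @ self.U + self.b
            i = _sigmoid(pre[:, :H])
            f = _sigmoid(pre[:, H:2 * H])
            o = _sigmoid(pre[:, 2 * H:3 * H])
            g = np.tanh(pre[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache["steps"].append(
                {"i": i, "f": f, "o": o, "g": g, "c_prev": c, "h_prev": h,
                 "tanh_c": tanh_c, "active": active}
            )
            h = active * h_new + (1 - active) * h
            c = active * c_new + (1 - active) * c
            Hs[t] = h * (t < lengths).astype(float)[:, None]
        cache["Hs"] = Hs
        return Hs, cache

    def backward(self, dHs: np.ndarray, cache):
        """dHs: (T, B, hidden) upstream gradient on every emitted h."""
        X, lengths = cache["X"], cache["lengths"]
        T, B, D = X.shape
        H = self.hidden
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            s = cache["steps"][t]
            active = s["active"]
            dh_t = (dh + dHs[t]) * active
            dc_t = dc * active
            i, f, o, g = s["i"], s["f"], s["o"], s["g"]
            tanh_c = s["tanh_c"]
            do = dh_t * tanh_c
            dc_t = dc_t + dh_t * o * (1.0 - tanh_c ** 2)
            di = dc_t * g
            dg = dc_t * i
            df = dc_t * s["c_prev"]
            dc_prev = dc_t * f
            dpre = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g ** 2),
                ],
                axis=1,
            )
            dW += X[t].T @ dpre
            dU += s["h_prev"].T @ dpre
            db += dpre.sum(axis=0)
            dX[t] = dpre @ self.W.T
            dh_prev = dpre @ self.U.T
            # inactive samples pass state gradients straight through
            dh = dh_prev + dh * (1 - active)
            dc = dc_prev + dc * (1 - active)
        return dX, {"W": dW, "U": dU, "b": db}


def reverse_padded(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its own length (padding stays put)."""
    T, B = X.shape[:2]
    out = np.zeros_like(X)
    for b in range(B):
        n = int(lengths[b])
        out[:n, b] = X[:n, b][::-1]
    return out


class BiLSTM:
    """Bidirectional LSTM; outputs the concatenation of both directions."""

    def __init__(self, fwd: LSTM, bwd: LSTM):
        self.fwd, self.bwd = fwd, bwd
        self.hidden = fwd.hidden

    @classmethod
    def create(cls, rng: np.random.Generator, d_in: int, hidden: int) -> "BiLSTM":
        return cls(LSTM.create(rng, d_in, hidden), LSTM.create(rng, d_in, hidden))

    def params(self):
        return {"fwd": self.fwd.params(), "bwd": self.bwd.params()}

    def forward(self, X: np.ndarray, lengths: Optional[np.ndarray] = None):
        T, B, _ = X.shape
        if lengths is None:
            lengths = np.full(B, T, dtype=np.intp)
        Hf, cf = self.fwd.forward(X, lengths)
        Xr = reverse_padded(X, lengths)
        Hb_r, cb = self.bwd.forward(Xr, lengths)
        Hb = reverse_padded(Hb_r, lengths)
        return np.concatenate([Hf, Hb], axis=-1), (cf, cb, lengths)

    def backward(self, dH: np.ndarray, cache):
        cf, cb, lengths = cache
        H = self.hidden
        dHf = dH[..., :H]
        dHb = reverse_padded(dH[..., H:], lengths)
        dXf, gf = self.fwd.backward(dHf, cf)
        dXb_r, gb = self.bwd.backward(dHb, cb)
        dX = dXf + reverse_padded(dXb_r, lengths)
        return dX, {"fwd": gf, "bwd": gb}

    def final_states(self, Hs: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Concatenated last forward state and first backward state per
        sequence: the standard fixed-size encoding of a variable-length
        string (used by the character encoder)."""
        B = Hs.shape[1]
        H = self.hidden
        idx = np.arange(B)
        fwd_last = Hs[lengths - 1, idx, :H]
        bwd_first = Hs[0, idx, H:]
        return np.concatenate([fwd_last, bwd_first], axis=-1)

    def final_states_backward(
        self, dfinal: np.ndarray, Hs_shape: tuple, lengths: np.ndarray
    ) -> np.ndarray:
        dHs = np.zeros(Hs_shape)
        B = Hs_shape[1]
        H = self.hidden
        idx = np.arange(B)
        dHs[lengths - 1, idx, :H] = dfinal[:, :H]
        dHs[0, idx, H:] = dfinal[:, H:]
        return dHs


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], p: float) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with probability p, else 1/(1-p)."""
    if p <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p).astype(float) / (1.0 - p)


def _iter_arrays(tree):
    if isinstance(tree, np.ndarray):
        yield tree
    elif isinstance(tree, dict):
        for v in tree.values():
            yield from _iter_arrays(v)


def clip_gradients(grads: dict, max_norm: float) -> float:
    """Scale a gradient tree in place to a global L2 norm cap."""
    total = np.sqrt(sum(float((a ** 2).sum()) for a in _iter_arrays(grads)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for a in _iter_arrays(grads):
            a *= scale
    return total
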