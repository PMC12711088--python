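"""NumPy building blocks for the masked bidirectional LSTM regressor.

Implements the forward and backward passes of an LSTM layer with timestep
masking, a bidirectional wrapper, inverted dropout, a dense head, mean-squared
error, and the Adam optimizer.  Masked timesteps carry the hidden and cell
state through unchanged, which makes predictions exactly invariant to the
amount of right-padding; sequence outputs are zero at masked positions.

Gate layout in the fused weight matrices is [input, forget, candidate, output].
Gradients are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class LSTMCellDirection:
    """A single-direction LSTM over (B, T, F) inputs with a (B, T) mask."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.units = units
        h = units
        self.Wx = glorot_uniform(rng, n_in, 4 * h, (n_in, 4 * h))
        self.Wh = glorot_uniform(rng, h, 4 * h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray, mask: np.ndarray, store: bool = True):
        """Returns (seq_out (B,T,H) with zeros at pads, final state (B,H))."""
        b_sz, t_len, _ = x.shape
        h_dim = self.units
        xg = x.reshape(b_sz * t_len, self.n_in) @ self.Wx
        xg = xg.reshape(b_sz, t_len, 4 * h_dim)
        m = mask.astype(x.dtype)

        h = np.zeros((b_sz, h_dim))
        c = np.zeros((b_sz, h_dim))
        seq = np.zeros((b_sz, t_len, h_dim))
        cache = [] if store else None
        for t in range(t_len):
            z = xg[:, t] + h @ self.Wh + self.b
            i = sigmoid(z[:, :h_dim])
            f = sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = sigmoid(z[:, 3 * h_dim :])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            mt = m[:, t : t + 1]
            seq[:, t] = mt * h_new
            if store:
                cache.append((h, c, i, f, g, o, hc, mt))
            c = mt * c_new + (1.0 - mt) * c
            h = mt * h_new + (1.0 - mt) * h
        if store:
            self._cache = (x, cache)
        return seq, h

    def backward(self, d_seq: np.ndarray | None, d_final: np.ndarray | None):
        """Backprop through time; returns (dx, grads dict)."""
        x, cache = self._cache
        b_sz, t_len, _ = x.shape
        h_dim = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        d_xg = np.zeros((b_sz, t_len, 4 * h_dim))
        dh = np.zeros((b_sz, h_dim)) if d_final is None else d_final.copy()
        dc = np.zeros((b_sz, h_dim))
        for t in range(t_len - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, hc, mt = cache[t]
            dh_new = mt * dh
            if d_seq is not None:
                dh_new = dh_new + mt * d_seq[:, t]
            dh_prev = (1.0 - mt) * dh
            dc_new = mt * dc
            dc_prev = (1.0 - mt) * dc

            do = dh_new * hc
            dc_new = dc_new + dh_new * o * (1.0 - hc * hc)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dc_prev = dc_prev + dc_new * f

            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            d_xg[:, t] = dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dh_prev + dz @ self.Wh.T
            dc = dc_prev
        dWx = x.reshape(b_sz * t_len, self.n_in).T @ d_xg.reshape(b_sz * t_len, 4 * h_dim)
        dx = (d_xg.reshape(b_sz * t_len, 4 * h_dim) @ self.Wx.T).reshape(x.shape)
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTMLayer:
    """Bidirectional LSTM: forward and time-reversed passes, concatenated."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool):
        self.fwd = LSTMCellDirection(n_in, units, rng)
        self.bwd = LSTMCellDirection(n_in, units, rng)
        self.return_sequences = return_sequences
        self.units = units

    @property
    def params(self):
        out = {}
        for tag, cell in (("f", self.fwd), ("b", self.bwd)):
            for k, v in cell.params.items():
                out[f"{tag}_{k}"] = v
        return out

    def set_params(self, params):
        for tag, cell in (("f", self.fwd), ("b", self.bwd)):
            cell.Wx = params[f"{tag}_Wx"]
            cell.Wh = params[f"{tag}_Wh"]
            cell.b = params[f"{tag}_b"]

    def forward(self, x: np.ndarray, mask: np.ndarray, store: bool = True) -> np.ndarray:
        seq_f, fin_f = self.fwd.forward(x, mask, store=store)
        seq_b, fin_b = self.bwd.forward(x[:, ::-1], mask[:, ::-1], store=store)
        if self.return_sequences:
            return np.concatenate([seq_f, seq_b[:, ::-1]], axis=2)
        return np.concatenate([fin_f, fin_b], axis=1)

    def backward(self, d_out: np.ndarray):
        h = self.units
        if self.return_sequences:
            dx_f, g_f = self.fwd.backward(d_out[:, :, :h], None)
            dx_b, g_b = self.bwd.backward(d_out[:, ::-1, h:], None)
        else:
            dx_f, g_f = self.fwd.backward(None, d_out[:, :h])
            dx_b, g_b = self.bwd.backward(None, d_out[:, h:])
        dx = dx_f + dx_b[:, ::-1]
        grads = {f"f_{k}": v for k, v in g_f.items()}
        grads.update({f"b_{k}": v for k, v in g_b.items()})
        return dx, grads


class Dropout:
    """Inverted dropout; active during training and during MC-dropout passes."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, active: bool, rng: np.random.Generator) -> np.ndarray:
        if not active or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        return d_out * self._mask


class Dense:
    """Affine output head."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def set_params(self, params):
        self.W = params["W"]
        self.b = params["b"]

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        if store:
            self._x = x
        return x @ self.W + self.b

    def backward(self, d_out: np.ndarray):
        grads = {"W": self._x.T @ d_out, "b": d_out.sum(axis=0)}
        return d_out @ self.W.T, grads


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. predictions."""
    diff = pred.ravel() - target.ravel()
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff.reshape(pred.shape)
    return loss, grad


class Adam:
    """Adam optimizer over a flat name->array parameter mapping."""

    def __init__(self, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * (g * g)
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
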