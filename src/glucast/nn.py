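"""Minimal numpy neural-network kernels: LSTM, dense layers, Adam.

Implements exactly what the forecasting model needs — single-channel LSTM
encoders read out at the final hidden state, fully-connected combiners and
a scalar head — with analytic backpropagation through time. Gradients are
exercised against central finite differences in the test suite. Everything
is deterministic given the seed and runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_lstm", "lstm_forward", "lstm_backward",
           "init_dense", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_lstm(rng: np.random.Generator, hidden: int, input_dim: int = 1) -> dict[str, np.ndarray]:
    """LSTM weights; gate order i, f, g, o along the last axis. Forget-gate
    bias starts at 1 so early training does not wash out the cell state."""
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0
    return {
        "Wx": _glorot(rng, input_dim, 4 * hidden),
        "Wh": _glorot(rng, hidden, 4 * hidden),
        "b": b,
    }


def init_dense(rng: np.random.Generator, fan_in: int, fan_out: int) -> dict[str, np.ndarray]:
    return {"W": _glorot(rng, fan_in, fan_out), "b": np.zeros(fan_out)}


def lstm_forward(params: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the LSTM over x of shape (B, T) (single input channel).

    Returns the final hidden state (B, H) and a cache for backprop.
    """
    B, T = x.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {"x": x, "gates": [], "c": [np.zeros((B, H))], "h": [np.zeros((B, H))]}
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    for t in range(T):
        a = x[:, t : t + 1] @ Wx + h @ Wh + b
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        h = o * np.tanh(c)
        cache["gates"].append((i, f, g, o))
        cache["c"].append(c)
        cache["h"].append(h)
    return h, cache


def lstm_backward(params: dict, cache: dict, dh_final: np.ndarray) -> dict[str, np.ndarray]:
    """Backprop-through-time from a gradient on the final hidden state."""
    x = cache["x"]
    B, T = x.shape
    H = params["Wh"].shape[0]
    Wx, Wh = params["Wx"], params["Wh"]
    grads = {"Wx": np.zeros_like(Wx), "Wh": np.zeros_like(Wh),
             "b": np.zeros_like(params["b"])}
    dh = dh_final.copy()
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["gates"][t]
        c_t = cache["c"][t + 1]
        c_prev = cache["c"][t]
        h_prev = cache["h"][t]
        tanh_c = np.tanh(c_t)
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += x[:, t : t + 1].T @ da
        grads["Wh"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dh = da @ Wh.T
        dc = dc * f
    return grads


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
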