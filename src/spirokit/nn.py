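"""Minimal NumPy neural-network core: 1-D convolution, BiLSTM, pooling,
linear layers, and Adam, with hand-derived reverse-mode gradients.

Layout conventions: convolutional tensors are (batch, channels, time);
recurrent tensors are (batch, time, features).  All layers keep the caches
needed for a single backward pass; gradients accumulate into ``grads``
dictionaries keyed like ``params``.  Correctness of every backward pass is
pinned by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "ReLU",
    "AvgPool2",
    "LSTM",
    "BiLSTM",
    "Linear",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "mask_from_lengths",
]


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy; returns (loss, dlogits)."""
    logits = np.asarray(logits, float)
    targets = np.asarray(targets, float)
    # softplus(z) - y*z, computed stably
    loss = np.mean(np.logaddexp(0.0, logits) - targets * logits)
    dlogits = (sigmoid(logits) - targets) / logits.size
    return float(loss), dlogits


def mask_from_lengths(lengths, t_max):
    """(B, T) float mask: 1 where t < length."""
    lengths = np.asarray(lengths)
    return (np.arange(t_max)[None, :] < lengths[:, None]).astype(float)


class Conv1d:
    """Same-padded 1-D convolution over (B, C_in, T); odd kernel size."""

    def __init__(self, c_in, c_out, kernel, rng):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.kernel = kernel
        self._cache = None

    def forward(self, x):
        k = self.kernel
        pad = k // 2
        x_p = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        t = x.shape[2]
        w = self.params["W"]
        y = np.zeros((x.shape[0], w.shape[0], t))
        for j in range(k):
            y += np.einsum("oc,bct->bot", w[:, :, j], x_p[:, :, j : j + t])
        y += self.params["b"][None, :, None]
        self._cache = x_p
        return y

    def backward(self, dy):
        x_p = self._cache
        k, pad = self.kernel, self.kernel // 2
        t = dy.shape[2]
        w = self.params["W"]
        dx_p = np.zeros_like(x_p)
        for j in range(k):
            self.grads["W"][:, :, j] += np.einsum(
                "bot,bct->oc", dy, x_p[:, :, j : j + t]
            )
            dx_p[:, :, j : j + t] += np.einsum("oc,bot->bct", w[:, :, j], dy)
        self.grads["b"] += dy.sum(axis=(0, 2))
        return dx_p[:, :, pad : pad + t]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2:
    """Stride-2 average pooling with ceil length: an odd tail element is
    averaged against an implicit zero so that output positions align with
    time-origin-anchored windows regardless of batch padding."""

    def __init__(self):
        self._t_in = None

    def forward(self, x):
        t = x.shape[2]
        self._t_in = t
        if t % 2:
            x = np.pad(x, ((0, 0), (0, 0), (0, 1)))
        return 0.5 * (x[:, :, 0::2] + x[:, :, 1::2])

    def backward(self, dy):
        t = self._t_in
        dx = np.zeros(dy.shape[:2] + (t + (t % 2),))
        dx[:, :, 0::2] = 0.5 * dy
        dx[:, :, 1::2] = 0.5 * dy
        return dx[:, :, :t]

    @staticmethod
    def out_length(t):
        return (t + 1) // 2


class LSTM:
    """Unidirectional LSTM over (B, T, D) -> (B, T, H); gate order i,f,g,o.

    The forget-gate bias is initialised at +1 (standard remedy for early
    vanishing of the cell gradient).
    """

    def __init__(self, d_in, hidden, rng):
        h = hidden
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / h)
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params = {
            "Wx": rng.normal(0.0, sx, size=(d_in, 4 * h)),
            "Wh": rng.normal(0.0, sh, size=(h, 4 * h)),
            "b": b,
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.hidden = h
        self._cache = None

    def forward(self, x):
        b_sz, t_max, _ = x.shape
        h = self.hidden
        wx, wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        h_prev = np.zeros((b_sz, h))
        c_prev = np.zeros((b_sz, h))
        hs = np.zeros((b_sz, t_max, h))
        cache = []
        xw = x @ wx  # precompute input contributions
        for t in range(t_max):
            z = xw[:, t] + h_prev @ wh + bias
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_t = o * tc
            cache.append((h_prev, c_prev, i, f, g, o, tc))
            hs[:, t] = h_t
            h_prev, c_prev = h_t, c
        self._cache = (x, cache)
        return hs

    def backward(self, dhs):
        x, cache = self._cache
        b_sz, t_max, d_in = x.shape
        h = self.hidden
        wx, wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_sz, h))
        dc_next = np.zeros((b_sz, h))
        for t in range(t_max - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += x[:, t].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * f
        return dx


def _reversal_index(lengths, t_max):
    """Per-sequence time reversal indices; an involution that reverses the
    first `length` steps and leaves padding in place."""
    lengths = np.asarray(lengths)
    t = np.arange(t_max)[None, :]
    rev = lengths[:, None] - 1 - t
    return np.where(t < lengths[:, None], rev, t)


class BiLSTM:
    """Bidirectional LSTM; output concatenates forward and backward hidden
    states to width 2*hidden.  The backward pass runs over each sequence's
    own valid length, so padding never leaks into valid positions."""

    def __init__(self, d_in, hidden, rng):
        self.fwd = LSTM(d_in, hidden, rng)
        self.bwd = LSTM(d_in, hidden, rng)
        self.hidden = hidden
        self._rev = None

    @property
    def params(self):
        return {"fwd": self.fwd.params, "bwd": self.bwd.params}

    @property
    def grads(self):
        return {"fwd": self.fwd.grads, "bwd": self.bwd.grads}

    def forward(self, x, lengths):
        b_sz, t_max, _ = x.shape
        rev = _reversal_index(lengths, t_max)
        self._rev = rev
        bidx = np.arange(b_sz)[:, None]
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[bidx, rev])[bidx, rev]
        return np.concatenate([h_f, h_b], axis=2)

    def backward(self, dy):
        h = self.hidden
        rev = self._rev
        bidx = np.arange(dy.shape[0])[:, None]
        dx = self.fwd.backward(dy[:, :, :h])
        db_rev = dy[:, :, h:][bidx, rev]
        dx += self.bwd.backward(db_rev)[bidx, rev]
        return dx


class Linear:
    def __init__(self, d_in, d_out, rng):
        self.params = {
            "W": rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        self.grads["W"] += x.reshape(-1, x.shape[-1]).T @ dy.reshape(
            -1, dy.shape[-1]
        )
        self.grads["b"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.params["W"].T


def _walk(tree, out, prefix=""):
    for k, v in tree.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            _walk(v, out, key + ".")
        else:
            out[key] = v
    return out


def flatten_params(tree):
    """Flatten a nested params/grads dict to {dotted_name: array}."""
    return _walk(tree, {})


class Adam:
    """Adam over a nested parameter tree (updates arrays in place)."""

    def __init__(self, params_tree, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = flatten_params(params_tree)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.t = 0

    def step(self, grads_tree):
        grads = flatten_params(grads_tree)
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    @staticmethod
    def zero_grads(grads_tree):
        for v in flatten_params(grads_tree).values():
            v[...] = 0.0
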