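"""NumPy sequence network: BatchNorm → stacked LSTMs → Dense logits.

The production-size configuration mirrors the six-layer recurrent language
model used for SMILES generation (input BatchNormalization, LSTM 1024/512/256
with dropout on their inputs, BatchNormalization, Dense(vocab)); tests and
desk-scale runs shrink the hidden sizes. Forward, backpropagation through
time, and Adam are implemented here directly so that parameter counting,
layer freezing, and checkpointing are fully transparent.

Conventions: activations are (batch, time, features); gate order inside the
LSTM weight matrices is input, forget, cell, output; BatchNorm statistics are
computed over valid (non-padded) positions only and tracked with momentum for
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, shape, dtype):
    # stack of orthogonal blocks for (U, 4U)
    rows, cols = shape
    blocks = []
    done = 0
    while done < cols:
        a = rng.standard_normal((rows, rows))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q[:, : min(rows, cols - done)])
        done += rows
    return np.concatenate(blocks, axis=1)[:, :cols].astype(dtype)


class Layer:
    """Base class: holds ``params`` and matching ``grads`` dicts."""

    trainable_keys: tuple[str, ...] = ()

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grads(self):
        self.grads = {k: np.zeros_like(self.params[k]) for k in self.trainable_keys}

    def forward(self, x, mask, training):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class BatchNorm(Layer):
    """Feature-wise batch normalization over all valid sequence positions."""

    trainable_keys = ("gamma", "beta")

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
            "moving_mean": np.zeros(n_features, dtype=dtype),
            "moving_var": np.ones(n_features, dtype=dtype),
        }

    def forward(self, x, mask, training):
        if training:
            m = mask[..., None]
            n = m.sum()
            mean = (x * m).sum(axis=(0, 1)) / n
            var = (((x - mean) ** 2) * m).sum(axis=(0, 1)) / n
            self.params["moving_mean"] = (
                self.momentum * self.params["moving_mean"] + (1 - self.momentum) * mean
            ).astype(x.dtype)
            self.params["moving_var"] = (
                self.momentum * self.params["moving_var"] + (1 - self.momentum) * var
            ).astype(x.dtype)
            self._cache = (x, mean, var, m, n)
        else:
            mean = self.params["moving_mean"]
            var = self.params["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = self._cache + (xhat, inv)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        x, mean, var, m, n, xhat, inv = self._cache
        dy = dy * m  # gradients only flow through valid positions
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        # batch-norm backward over the masked population of size n
        dvar = (dxhat * (x - mean)).sum(axis=(0, 1)) * (-0.5) * inv**3
        dmean = -(dxhat * inv).sum(axis=(0, 1)) + dvar * (-2.0 / n) * ((x - mean) * m).sum(axis=(0, 1))
        dx = dxhat * inv + (dvar * 2.0 * (x - mean) / n + dmean / n)
        return dx * m

    def step(self, x):
        """Single-position inference-mode normalization (generation)."""
        inv = 1.0 / np.sqrt(self.params["moving_var"] + self.eps)
        return self.params["gamma"] * (x - self.params["moving_mean"]) * inv + self.params["beta"]


class LSTM(Layer):
    """LSTM layer with optional (inverted) dropout on its inputs.

    The dropout mask is sampled once per sequence and shared across
    timesteps; it is disabled at inference.
    """

    trainable_keys = ("Wx", "Wh", "b")

    def __init__(self, n_in: int, n_units: int, dropout: float = 0.0, rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_in, self.n_units = n_in, n_units
        self.dropout = dropout
        b = np.zeros(4 * n_units, dtype=dtype)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.params = {
            "Wx": _glorot(rng, (n_in, 4 * n_units), dtype),
            "Wh": _orthogonal(rng, (n_units, 4 * n_units), dtype),
            "b": b,
        }
        self._dropout_rng = rng

    def forward(self, x, mask, training):
        B, T, _ = x.shape
        U = self.n_units
        if training and self.dropout > 0:
            keep = 1.0 - self.dropout
            dmask = (self._dropout_rng.random((B, 1, self.n_in)) < keep) / keep
            x = x * dmask.astype(x.dtype)
        else:
            dmask = None
        gx = x @ self.params["Wx"] + self.params["b"]
        Wh = self.params["Wh"]
        h = np.zeros((B, U), dtype=x.dtype)
        c = np.zeros((B, U), dtype=x.dtype)
        H = np.empty((B, T, U), dtype=x.dtype)
        cache_steps = []
        for t in range(T):
            g = gx[:, t] + h @ Wh
            i = _sigmoid(g[:, :U])
            f = _sigmoid(g[:, U : 2 * U])
            cbar = np.tanh(g[:, 2 * U : 3 * U])
            o = _sigmoid(g[:, 3 * U :])
            c_new = f * c + i * cbar
            tc = np.tanh(c_new)
            h_new = o * tc
            cache_steps.append((h, c, i, f, cbar, o, tc))
            h, c = h_new, c_new
            H[:, t] = h
        self._cache = (x, dmask, cache_steps)
        return H

    def backward(self, dH):
        x, dmask, cache_steps = self._cache
        B, T, _ = x.shape
        U = self.n_units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U), dtype=x.dtype)
        dc_next = np.zeros((B, U), dtype=x.dtype)
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, cbar, o, tc = cache_steps[t]
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc**2)
            do = dh * tc
            di = dc * cbar
            df = dc * c_prev
            dcbar = dc * i
            dg = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dcbar * (1 - cbar**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dg
            dWh += h_prev.T @ dg
            db += dg.sum(axis=0)
            dx[:, t] = dg @ Wx.T
            dh_next = dg @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        if dmask is not None:
            dx *= dmask
        return dx

    def init_state(self, batch: int, dtype=None):
        dtype = dtype or self.params["Wx"].dtype
        return (np.zeros((batch, self.n_units), dtype=dtype), np.zeros((batch, self.n_units), dtype=dtype))

    def step(self, x, state):
        """One inference timestep; returns (h, new_state)."""
        h, c = state
        U = self.n_units
        g = x @ self.params["Wx"] + self.params["b"] + h @ self.params["Wh"]
        i = _sigmoid(g[:, :U])
        f = _sigmoid(g[:, U : 2 * U])
        cbar = np.tanh(g[:, 2 * U : 3 * U])
        o = _sigmoid(g[:, 3 * U :])
        c = f * c + i * cbar
        h = o * np.tanh(c)
        return h, (h, c)


class Dense(Layer):
    """Per-position affine map to logits."""

    trainable_keys = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {"W": _glorot(rng, (n_in, n_out), dtype), "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x, mask, training):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._cache
        self.grads["W"] += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T

    def step(self, x):
        return x @ self.params["W"] + self.params["b"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the sequence network."""

    vocab_size: int
    hidden_sizes: tuple[int, ...] = (1024, 512, 256)
    dropout: float = 0.4

    @property
    def layer_plan(self) -> list[str]:
        plan = ["BatchNorm"]
        plan += [f"LSTM({u})" for u in self.hidden_sizes]
        plan += ["BatchNorm", f"Dense({self.vocab_size})"]
        return plan


class Network:
    """Ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def recurrent_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if isinstance(l, LSTM)]

    def forward(self, x, mask, training=True):
        for layer in self.layers:
            x = layer.forward(x, mask, training)
        return x

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]):
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()

    # -- single-token stepping for autoregressive decoding ----------------
    def init_state(self, batch: int):
        return [l.init_state(batch) for l in self.layers if isinstance(l, LSTM)]

    def step(self, x_onehot, state):
        """Advance one timestep at inference. ``x_onehot``: (batch, vocab)."""
        new_state = []
        si = 0
        h = x_onehot
        for layer in self.layers:
            if isinstance(layer, LSTM):
                h, s = layer.step(h, state[si])
                new_state.append(s)
                si += 1
            else:
                h = layer.step(h)
        return h, new_state


def build_network(spec: ModelSpec, rng: np.random.Generator | None = None, dtype=np.float32) -> Network:
    """Instantiate the six-layer stack for a given vocabulary width."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [BatchNorm(spec.vocab_size, dtype=dtype)]
    n_in = spec.vocab_size
    for u in spec.hidden_sizes:
        layers.append(LSTM(n_in, u, dropout=spec.dropout, rng=rng, dtype=dtype))
        n_in = u
    layers.append(BatchNorm(n_in, dtype=dtype))
    layers.append(Dense(n_in, spec.vocab_size, rng=rng, dtype=dtype))
    return Network(layers)


def count_parameters(spec: ModelSpec) -> int:
    """Total parameters (trainable plus BatchNorm moving statistics) of the
    instantiated network, one-hot input width equal to ``vocab_size``."""
    return build_network(spec).param_count()


def count_parameters_closed_form(spec: ModelSpec) -> int:
    """Closed-form cross-check: 4f per BatchNorm, 4u(d+u+1) per LSTM,
    (u+1)v for the Dense output."""
    total = 4 * spec.vocab_size
    d = spec.vocab_size
    for u in spec.hidden_sizes:
        total += 4 * u * (d + u + 1)
        d = u
    total += 4 * d
    total += (d + 1) * spec.vocab_size
    return total


def masked_softmax_cross_entropy(logits, targets, mask):
    """Mean next-token cross-entropy over valid positions.

    Returns ``(loss, dlogits)``; the gradient is already divided by the
    number of valid positions.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n = mask.sum()
    B, T = targets.shape
    p_target = probs[np.arange(B)[:, None], np.arange(T)[None, :], targets]
    loss = -(np.log(np.clip(p_target, 1e-12, None)) * mask).sum() / n
    dlogits = probs.copy()
    dlogits[np.arange(B)[:, None], np.arange(T)[None, :], targets] -= 1.0
    dlogits *= (mask / n)[..., None]
    return float(loss), dlogits.astype(logits.dtype)


class Adam:
    """Adam over a network's trainable parameters with layer freezing."""

    def __init__(self, network: Network, learning_rate: float, beta1=0.9, beta2=0.999, eps=1e-7, frozen_layers: Sequence[int] = ()):
        self.network = network
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.frozen = set(frozen_layers)
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for li, layer in enumerate(network.layers):
            for k in layer.trainable_keys:
                self.m[(li, k)] = np.zeros_like(layer.params[k])
                self.v[(li, k)] = np.zeros_like(layer.params[k])

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for li, layer in enumerate(self.network.layers):
            if li in self.frozen:
                continue
            for k in layer.trainable_keys:
                g = layer.grads[k]
                m = self.m[(li, k)] = b1 * self.m[(li, k)] + (1 - b1) * g
                v = self.v[(li, k)] = b2 * self.v[(li, k)] + (1 - b2) * g * g
                mhat = m / corr1
                vhat = v / corr2
                layer.params[k] -= (self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    layer.params[k].dtype
                )
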