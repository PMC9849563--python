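"""Compact NumPy engine for the conv-LSTM phase regressor.

The network is small enough (a few thousand weights) that a vectorised
NumPy implementation trains it in minutes on one CPU, so forward pass,
backpropagation and the Adam optimiser are written out explicitly here.

Architecture (batch N, window T, channels C):

    input (N, T, C)
      -> Conv1D(filters, kernel, stride 1, same padding), sigmoid
      -> LSTM(units), sigmoid candidate/cell-output activation,
         sigmoid recurrent gating; last hidden state only
      -> Dense(...), sigmoid, for each hidden size
      -> Dense(n_out), sigmoid

The gate layout follows the common [input, forget, candidate, output]
ordering with a +1 forget-gate bias at initialisation.  Kernels are
Glorot-uniform, the recurrent kernel orthogonal, biases zero.

The heavy per-timestep work is kept out of the Python loop: the input
projection of the LSTM is one large matmul over all timesteps, and the
recurrent loop only touches (N, units) blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvLSTMNet", "Adam", "mse_loss"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, shape, fan_in, fan_out, dtype, gain: float = 1.0):
    # gain 4 compensates the 1/4 slope of the sigmoid at its midpoint,
    # keeping activation variance roughly constant through the stack
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng, n, dtype):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(dtype)


class ConvLSTMNet:
    """Conv1D -> LSTM -> dense stack with sigmoid activations throughout."""

    def __init__(
        self,
        window: int,
        channels: int,
        conv_filters: int = 32,
        conv_kernel: int = 8,
        lstm_units: int = 20,
        dense_sizes: tuple[int, ...] = (30, 10),
        outputs: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        if min(window, channels, conv_filters, conv_kernel, lstm_units, outputs) < 1:
            raise ValueError("all architecture dimensions must be >= 1")
        if conv_kernel > window:
            raise ValueError("conv kernel cannot exceed the window length")
        self.window = window
        self.channels = channels
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.lstm_units = lstm_units
        self.dense_sizes = tuple(int(s) for s in dense_sizes)
        self.outputs = outputs
        self.dtype = np.dtype(dtype)
        # 'same' padding for stride 1: total k-1, split floor/ceil
        self.pad_left = (conv_kernel - 1) // 2
        self.pad_right = conv_kernel - 1 - self.pad_left
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng) -> None:
        k, c, f, u = self.conv_kernel, self.channels, self.conv_filters, self.lstm_units
        dt = self.dtype
        # biases start at -0.5 * column sum: inputs and sigmoid activations
        # hover near 0.5, and cancelling that offset keeps units out of
        # saturation at the start of training
        p = {
            "conv_W": _glorot(rng, (k * c, f), k * c, f, dt, gain=4.0),
            "lstm_Wx": _glorot(rng, (f, 4 * u), f, u, dt, gain=4.0),
            "lstm_Wh": np.concatenate([_orthogonal(rng, u, dt) for _ in range(4)], axis=1),
        }
        p["conv_b"] = (-0.5 * p["conv_W"].sum(axis=0)).astype(dt)
        p["lstm_b"] = (-0.5 * p["lstm_Wx"].sum(axis=0)).astype(dt)
        p["lstm_b"][u : 2 * u] += 1.0  # forget-gate bias
        sizes = (u,) + self.dense_sizes + (self.outputs,)
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            p[f"dense{i}_W"] = _glorot(rng, (n_in, n_out), n_in, n_out, dt, gain=4.0)
            p[f"dense{i}_b"] = (-0.5 * p[f"dense{i}_W"].sum(axis=0)).astype(dt)
        self.params = p

    @property
    def n_dense_layers(self) -> int:
        return len(self.dense_sizes) + 1

    def count_params(self, per_layer: bool = False):
        """Total trainable parameters, optionally itemised per layer."""
        groups: dict[str, int] = {}
        for name, arr in self.params.items():
            layer = name.split("_")[0]
            groups[layer] = groups.get(layer, 0) + arr.size
        total = sum(groups.values())
        return (total, groups) if per_layer else total

    # ----- forward ---------------------------------------------------------

    def _conv_patches(self, X):
        Xp = np.pad(X, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        pat = sliding_window_view(Xp, self.conv_kernel, axis=1)  # (N, T, C, k)
        pat = np.ascontiguousarray(pat.transpose(0, 1, 3, 2))    # (N, T, k, C)
        return pat.reshape(X.shape[0], X.shape[1], -1)           # (N, T, k*C)

    def forward(self, X, want_cache: bool = False):
        """Run the network on an (N, T, C) batch; returns (N, outputs)."""
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1] != self.window or X.shape[2] != self.channels:
            raise ValueError(
                f"expected input of shape (N, {self.window}, {self.channels}), got {X.shape}"
            )
        p = self.params
        N, T = X.shape[0], X.shape[1]
        u = self.lstm_units

        pat = self._conv_patches(X)                               # (N, T, kC)
        H1 = _sigmoid(pat.reshape(N * T, -1) @ p["conv_W"] + p["conv_b"])
        H1 = H1.reshape(N, T, self.conv_filters)

        # LSTM: input projection in one matmul, recurrent part per step
        Gx = (H1.reshape(N * T, -1) @ p["lstm_Wx"]).reshape(N, T, 4 * u) + p["lstm_b"]
        h = np.zeros((N, u), dtype=self.dtype)
        c = np.zeros((N, u), dtype=self.dtype)
        gates_hist = np.empty((T, N, 4 * u), dtype=self.dtype) if want_cache else None
        state_hist = np.empty((T, 3, N, u), dtype=self.dtype) if want_cache else None
        for t in range(T):
            z = Gx[:, t] + h @ p["lstm_Wh"]
            g_all = _sigmoid(z)
            i_g, f_g = g_all[:, :u], g_all[:, u : 2 * u]
            c_g, o_g = g_all[:, 2 * u : 3 * u], g_all[:, 3 * u :]
            if want_cache:
                gates_hist[t] = g_all
                state_hist[t, 0] = h
                state_hist[t, 1] = c
            c = f_g * c + i_g * c_g
            h = o_g * _sigmoid(c)
            if want_cache:
                state_hist[t, 2] = c

        acts = [h]
        a = h
        for i in range(self.n_dense_layers):
            a = _sigmoid(a @ p[f"dense{i}_W"] + p[f"dense{i}_b"])
            acts.append(a)

        if want_cache:
            cache = {"pat": pat, "H1": H1, "gates": gates_hist, "states": state_hist, "acts": acts}
            return a, cache
        return a

    def predict(self, X, batch_size: int = 4096):
        """Forward pass in chunks; returns (N, outputs) float64."""
        X = np.asarray(X)
        out = [self.forward(X[i : i + batch_size]) for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0).astype(np.float64)

    # ----- backward --------------------------------------------------------

    def loss_and_grads(self, X, Y):
        """MSE loss and gradients for one batch."""
        Y = np.asarray(Y, dtype=self.dtype)
        y_pred, cache = self.forward(X, want_cache=True)
        N, T, u = Y.shape[0], self.window, self.lstm_units
        p = self.params
        grads = {}

        diff = y_pred - Y
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dA = (2.0 / diff.size) * diff                            # d loss / d output

        # dense stack (reverse)
        acts = cache["acts"]
        for i in range(self.n_dense_layers - 1, -1, -1):
            a_out, a_in = acts[i + 1], acts[i]
            dZ = dA * a_out * (1.0 - a_out)
            grads[f"dense{i}_W"] = a_in.T @ dZ
            grads[f"dense{i}_b"] = dZ.sum(axis=0)
            dA = dZ @ p[f"dense{i}_W"].T
        dh = dA                                                   # (N, u)

        # LSTM backward through time
        gates, states = cache["gates"], cache["states"]
        dZ_all = np.empty((T, N, 4 * u), dtype=self.dtype)
        dc = np.zeros((N, u), dtype=self.dtype)
        WhT = p["lstm_Wh"].T
        for t in range(T - 1, -1, -1):
            g_all = gates[t]
            i_g, f_g = g_all[:, :u], g_all[:, u : 2 * u]
            c_g, o_g = g_all[:, 2 * u : 3 * u], g_all[:, 3 * u :]
            c_prev, c_new = states[t, 1], states[t, 2]
            sc = _sigmoid(c_new)
            do = dh * sc
            dc = dc + dh * o_g * sc * (1.0 - sc)
            di = dc * c_g
            df = dc * c_prev
            dcg = dc * i_g
            dz = np.concatenate(
                [
                    di * i_g * (1.0 - i_g),
                    df * f_g * (1.0 - f_g),
                    dcg * c_g * (1.0 - c_g),
                    do * o_g * (1.0 - o_g),
                ],
                axis=1,
            )
            dZ_all[t] = dz
            dh = dz @ WhT
            dc = dc * f_g

        dZ_flat = dZ_all.transpose(1, 0, 2).reshape(N * T, 4 * u)
        H1_flat = cache["H1"].reshape(N * T, -1)
        Hprev_flat = states[:, 0].transpose(1, 0, 2).reshape(N * T, u)
        grads["lstm_Wx"] = H1_flat.T @ dZ_flat
        grads["lstm_Wh"] = Hprev_flat.T @ dZ_flat
        grads["lstm_b"] = dZ_flat.sum(axis=0)

        dH1 = (dZ_flat @ p["lstm_Wx"].T).reshape(N, T, -1)
        dA1 = dH1 * cache["H1"] * (1.0 - cache["H1"])
        dA1_flat = dA1.reshape(N * T, -1)
        grads["conv_W"] = cache["pat"].reshape(N * T, -1).T @ dA1_flat
        grads["conv_b"] = dA1_flat.sum(axis=0)
        return loss, grads

    # ----- serialisation ---------------------------------------------------

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        for k, v in self.params.items():
            w = np.asarray(weights[k], dtype=self.dtype)
            if w.shape != v.shape:
                raise ValueError(f"weight {k!r} has shape {w.shape}, expected {v.shape}")
            self.params[k] = w


def mse_loss(y_pred, y_true) -> float:
    d = np.asarray(y_pred, dtype=np.float64) - np.asarray(y_true, dtype=np.float64)
    return float(np.mean(d**2))


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k].astype(np.float64)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            update = self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            params[k] = (params[k].astype(np.float64) - update).astype(params[k].dtype)
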