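"""Minimal seeded NumPy neural-network backend for sequence regression.

Implements exactly the blocks the force estimator needs — LSTM layers with
full backpropagation through time, batch normalization, inverted dropout, a
dense head, Adam, and per-layer freeze flags — with deterministic behavior
under a single ``numpy.random.Generator``.

Conventions:

* sequences are ``(batch, time, features)`` arrays; computation runs in
  float32 by default (pass ``dtype=np.float64`` for gradient checking);
* a "block" is LSTM -> batch-norm -> dropout; the network is a stack of
  blocks followed by a dense single-output head applied to the last
  timestep;
* freezing the first ``k`` blocks excludes their parameters from gradient
  updates and pins their batch-norm layers to running statistics (so no
  state of a frozen block changes during calibration).
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError, ValidationError


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class LSTMLayer:
    """Single LSTM layer returning the full hidden sequence.

    Gate layout along the last axis of the packed weight matrices is
    (input, forget, cell, output); the forget-gate bias is initialized to 1.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.input_dim = input_dim
        self.units = units
        self.dtype = dtype
        k_in = 1.0 / np.sqrt(input_dim + units)
        self.Wx = rng.uniform(-k_in, k_in, (input_dim, 4 * units)).astype(dtype)
        self.Wh = rng.uniform(-k_in, k_in, (units, 4 * units)).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units:2 * units] = 1.0
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, T, D = x.shape
        U = self.units
        xw = x.reshape(B * T, D) @ self.Wx
        xw = xw.reshape(B, T, 4 * U)
        xw += self.b
        h = np.empty((B, T, U), dtype=self.dtype)
        c = np.empty((B, T, U), dtype=self.dtype)
        gates = np.empty((B, T, 4 * U), dtype=self.dtype) if store else None
        h_prev = np.zeros((B, U), dtype=self.dtype)
        c_prev = np.zeros((B, U), dtype=self.dtype)
        for t in range(T):
            z = xw[:, t] + h_prev @ self.Wh
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_prev = f * c_prev
            c_prev += i * g
            h_prev = o * np.tanh(c_prev)
            h[:, t] = h_prev
            c[:, t] = c_prev
            if store:
                gates[:, t, :U] = i
                gates[:, t, U:2 * U] = f
                gates[:, t, 2 * U:3 * U] = g
                gates[:, t, 3 * U:] = o
        if store:
            self._cache = (x, gates, c, h)
        return h

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        x, gates, c, h = self._cache
        B, T, D = x.shape
        U = self.units
        dWh = np.zeros_like(self.Wh)
        dz_all = np.empty((B, T, 4 * U), dtype=self.dtype)
        dh_next = np.zeros((B, U), dtype=self.dtype)
        dc_next = np.zeros((B, U), dtype=self.dtype)
        zeros = np.zeros((B, U), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            gt = gates[:, t]
            i = gt[:, :U]
            f = gt[:, U:2 * U]
            g = gt[:, 2 * U:3 * U]
            o = gt[:, 3 * U:]
            c_prev = c[:, t - 1] if t > 0 else zeros
            h_prev = h[:, t - 1] if t > 0 else zeros
            tc = np.tanh(c[:, t])
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o
            dc *= 1.0 - tc * tc
            dc += dc_next
            dz = dz_all[:, t]
            dz[:, :U] = dc * g * i * (1.0 - i)
            dz[:, U:2 * U] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * U:3 * U] = dc * i * (1.0 - g * g)
            dz[:, 3 * U:] = do * o * (1.0 - o)
            dWh += h_prev.T @ dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        flat = dz_all.reshape(B * T, 4 * U)
        self.grads = {
            "Wx": x.reshape(B * T, D).T @ flat,
            "Wh": dWh,
            "b": flat.sum(axis=0),
        }
        self._cache = None
        return (flat @ self.Wx.T).reshape(B, T, D)


class BatchNorm:
    """Batch normalization over batch (and time, for sequences) per feature."""

    def __init__(self, units: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.dtype = dtype
        self.gamma = np.ones(units, dtype=dtype)
        self.beta = np.zeros(units, dtype=dtype)
        self.running_mean = np.zeros(units, dtype=dtype)
        self.running_var = np.ones(units, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, update_stats: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if update_stats:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.dtype(self.momentum)
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.dtype(self.eps))
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes, update_stats)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, batch_mode = self._cache
        self.grads = {
            "gamma": (dout * xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        if not batch_mode:
            return dout * self.gamma * inv
        dxhat = dout * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        self._cache = None
        return dx


class Dropout:
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float, dtype=np.float32):
        if not 0.0 <= rate < 1.0:
            raise ValidationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.dtype = dtype
        self._mask = None

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(self.dtype) / self.dtype(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense:
    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = 1.0 / np.sqrt(input_dim)
        self.W = rng.uniform(-k, k, (input_dim, output_dim)).astype(dtype)
        self.b = np.zeros(output_dim, dtype=dtype)
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        self._cache = x
        return x @ self.W + self.b

    def backward(self, dout):
        x = self._cache
        self.grads = {"W": x.T @ dout, "b": dout.sum(axis=0)}
        self._cache = None
        return dout @ self.W.T


class StackedLSTMRegressor:
    """LSTM blocks (LSTM -> BN -> dropout) + dense(1) on the last timestep."""

    def __init__(self, layer_units, dropout: float, seed: int = 0,
                 dtype=np.float32):
        layer_units = tuple(int(u) for u in layer_units)
        if len(layer_units) == 0:
            raise ValidationError("layer_units must be non-empty")
        rng = np.random.default_rng(seed)
        self.layer_units = layer_units
        self.dropout_rate = float(dropout)
        self.dtype = dtype
        self.blocks: list[tuple[LSTMLayer, BatchNorm, Dropout]] = []
        d = 1
        for u in layer_units:
            self.blocks.append((
                LSTMLayer(d, u, rng, dtype),
                BatchNorm(u, dtype=dtype),
                Dropout(dropout, dtype=dtype),
            ))
            d = u
        self.dense = Dense(d, 1, rng, dtype)
        # start the output head at the centre of the normalized force range
        self.dense.b[:] = 0.5
        self.frozen_depth = 0

    # -- parameter bookkeeping ------------------------------------------------

    def named_params(self, trainable_only: bool = False):
        """Yield (name, layer_object, key) triples for every parameter."""
        for k, (lstm, bn, _) in enumerate(self.blocks):
            if trainable_only and k < self.frozen_depth:
                continue
            for key in lstm.params():
                yield f"block{k}.lstm.{key}", lstm, key
            for key in bn.params():
                yield f"block{k}.bn.{key}", bn, key
        for key in self.dense.params():
            yield f"dense.{key}", self.dense, key

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer, key in self.named_params():
            out[name] = layer.params()[key].copy()
        for k, (_, bn, _) in enumerate(self.blocks):
            for key, buf in bn.buffers().items():
                out[f"block{k}.bn.{key}"] = buf.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params()[key][...] = weights[name]
        for k, (_, bn, _) in enumerate(self.blocks):
            bn.running_mean[...] = weights[f"block{k}.bn.running_mean"]
            bn.running_var[...] = weights[f"block{k}.bn.running_var"]

    # -- forward / backward ---------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """X is (batch, time); returns (batch,) float64 predictions."""
        a = np.asarray(X, dtype=self.dtype)[:, :, None]
        for k, (lstm, bn, drop) in enumerate(self.blocks):
            a = lstm.forward(a, store=train)
            batch_mode = train and k >= self.frozen_depth
            a = bn.forward(a, update_stats=batch_mode)
            a = drop.forward(a, train, rng)
        self._last_T = a.shape[1]
        return self.dense.forward(a[:, -1, :])[:, 0].astype(np.float64)

    def backward(self, dy: np.ndarray) -> None:
        dlast = self.dense.backward(dy[:, None].astype(self.dtype))
        B = dlast.shape[0]
        da = None
        for k in range(len(self.blocks) - 1, -1, -1):
            lstm, bn, drop = self.blocks[k]
            if da is None:
                da = np.zeros((B, self._last_T, lstm.units), dtype=self.dtype)
                da[:, -1] = dlast
            da = drop.backward(da)
            da = bn.backward(da)
            da = lstm.backward(da)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float = 5.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, net: StackedLSTMRegressor) -> None:
        entries = list(net.named_params(trainable_only=True))
        grads = {name: layer.grads[key] for name, layer, key in entries}
        gnorm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                            for g in grads.values()))
        scale = min(1.0, self.clip_norm / gnorm) if gnorm > 0 else 1.0
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, layer, key in entries:
            g = grads[name] * scale
            if not np.all(np.isfinite(g)):
                raise TrainingError(f"non-finite gradient in {name}")
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            layer.params()[key][...] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def rmse_loss_and_grad(y_pred: np.ndarray, y_true: np.ndarray):
    """Root-mean-square-error loss (normalized-force units) and its gradient."""
    err = y_pred - y_true
    mse = float(np.mean(err * err))
    loss = np.sqrt(mse)
    if loss < 1e-12:
        return loss, np.zeros_like(err)
    return loss, err / (len(err) * loss)
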