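"""Minimal neural-network core for 1D-CNN/GRU sequence classifiers.

Implements exactly the layers the scoring models need — 1-D convolution
(same padding, stride 1, ReLU), max-pooling, a sequence-returning GRU,
dense, dropout, flatten, and a parallel-branch concatenation — with
hand-derived backpropagation (including GRU backprop-through-time), a
softmax cross-entropy loss, and an Adam optimizer. Everything is plain
numpy and deterministic given its RNG seeds.

Conventions
-----------
* Sequence tensors are ``(batch, time, channels)``.
* Weight init: Glorot uniform for all weight matrices, zeros for biases.
* GRU (single-bias form, ``3*(in*units + units^2 + units)`` parameters)::

      z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)          (update gate)
      r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)          (reset gate)
      c_t = tanh(x_t Wc + (r_t * h_{t-1}) Uc + bc)     (candidate)
      h_t = z_t * h_{t-1} + (1 - z_t) * c_t
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

#: compute dtype; single precision is ample for these shallow models and
#: roughly halves memory traffic
DTYPE = np.float32

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "GRU",
    "Flatten",
    "Dropout",
    "Sequential",
    "ParallelConcat",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "Network",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(DTYPE)


def _zeros(n: int) -> np.ndarray:
    return np.zeros(n, dtype=DTYPE)


class Layer:
    """Base layer: ``params`` and ``grads`` are parallel dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.params = {"W": _glorot(rng, (n_in, n_out)), "b": _zeros(n_out)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = dout * self._mask
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Conv1D(Layer):
    """Temporal convolution, stride 1, 'same' zero padding, ReLU activation."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k = kernel_size
        self.in_channels = in_channels
        self.filters = filters
        self.params = {
            "W": _glorot(rng, (kernel_size * in_channels, filters)),
            "b": _zeros(filters),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, c = x.shape
        if t < 1:
            raise ValueError("empty time axis")
        pl, pr = (self.k - 1) // 2, self.k // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (b, t, c, k) -> (b, t, k, c) -> (b, t, k*c)
        cols = sliding_window_view(xp, self.k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(b, t, self.k * c)
        self._pads = (pl, pr, t)
        z = self._cols @ self.params["W"] + self.params["b"]
        self._mask = z > 0
        return z * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._mask
        b, t, f = dz.shape
        kc = self.k * self.in_channels
        self.grads = {
            "W": self._cols.reshape(-1, kc).T @ dz.reshape(-1, f),
            "b": dz.sum(axis=(0, 1)),
        }
        dcols = (dz @ self.params["W"].T).reshape(b, t, self.k, self.in_channels)
        pl, pr, t_in = self._pads
        dxp = np.zeros((b, t_in + pl + pr, self.in_channels), dtype=dout.dtype)
        for i in range(self.k):
            dxp[:, i : i + t_in, :] += dcols[:, :, i, :]
        return dxp[:, pl : pl + t_in, :]


class MaxPool1D(Layer):
    """Non-overlapping max pool along time; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        self.p = pool_size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, c = x.shape
        t_out = t // self.p
        if t_out < 1:
            raise ValueError(f"time axis {t} shorter than pool size {self.p}")
        xr = x[:, : t_out * self.p].reshape(b, t_out, self.p, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, t_out, c = dout.shape
        dxr = np.zeros((b, t_out, self.p, c), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, : t_out * self.p] = dxr.reshape(b, t_out * self.p, c)
        return dx


class GRU(Layer):
    """Gated recurrent layer returning its hidden state at every timestep."""

    def __init__(self, in_channels: int, units: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.in_channels = in_channels
        p = {}
        for g in "zrc":
            p[f"W{g}"] = _glorot(rng, (in_channels, units))
            p[f"U{g}"] = _glorot(rng, (units, units))
            p[f"b{g}"] = _zeros(units)
        self.params = p

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        P = self.params
        # input projections for all timesteps at once; the two plain-h gate
        # matrices are fused so each step costs two matmuls, not four
        xz = x @ P["Wz"] + P["bz"]
        xr = x @ P["Wr"] + P["br"]
        xc = x @ P["Wc"] + P["bc"]
        Uzr = np.concatenate([P["Uz"], P["Ur"]], axis=1)
        h = np.zeros((b, u), dtype=x.dtype)
        hs = np.empty((b, t, u), dtype=x.dtype)
        cache = []
        for i in range(t):
            zr = h @ Uzr
            z = _sigmoid(xz[:, i] + zr[:, :u])
            r = _sigmoid(xr[:, i] + zr[:, u:])
            rh = r * h
            c = np.tanh(xc[:, i] + rh @ P["Uc"])
            h_new = z * h + (1.0 - z) * c
            cache.append((h, z, r, c, rh))
            h = h_new
            hs[:, i] = h
        self._x, self._cache, self._Uzr = x, cache, Uzr
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, cache = self._x, self._cache
        b, t, _ = x.shape
        u = self.units
        P = self.params
        dXz = np.empty((b, t, u), dtype=x.dtype)
        dXr = np.empty_like(dXz)
        dXc = np.empty_like(dXz)
        Hprev = np.empty((b, t, u), dtype=x.dtype)
        RH = np.empty((b, t, u), dtype=x.dtype)
        UcT = np.ascontiguousarray(P["Uc"].T)
        UzrT = np.ascontiguousarray(self._Uzr.T)
        dh_next = np.zeros((b, u), dtype=x.dtype)
        for i in range(t - 1, -1, -1):
            h_prev, z, r, c, rh = cache[i]
            dh = dout[:, i] + dh_next
            dz = dh * (h_prev - c) * z * (1.0 - z)
            dc = dh * (1.0 - z) * (1.0 - c * c)
            drh = dc @ UcT
            dr = drh * h_prev * r * (1.0 - r)
            dzr = np.concatenate([dz, dr], axis=1)
            dh_next = dh * z + drh * r + dzr @ UzrT
            dXz[:, i], dXr[:, i], dXc[:, i] = dz, dr, dc
            Hprev[:, i], RH[:, i] = h_prev, rh
        flat = x.reshape(-1, self.in_channels)
        hflat = Hprev.reshape(-1, u)
        self.grads = {
            "Wz": flat.T @ dXz.reshape(-1, u),
            "Wr": flat.T @ dXr.reshape(-1, u),
            "Wc": flat.T @ dXc.reshape(-1, u),
            "Uz": hflat.T @ dXz.reshape(-1, u),
            "Ur": hflat.T @ dXr.reshape(-1, u),
            "Uc": RH.reshape(-1, u).T @ dXc.reshape(-1, u),
            "bz": dXz.sum(axis=(0, 1)),
            "br": dXr.sum(axis=(0, 1)),
            "bc": dXc.sum(axis=(0, 1)),
        }
        return (
            dXz @ P["Wz"].T + dXr @ P["Wr"].T + dXc @ P["Wc"].T
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / np.asarray(
            keep, dtype=x.dtype
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ParallelConcat)):
                yield from layer.iter_layers()
            else:
                yield layer

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.iter_layers())


class ParallelConcat(Layer):
    """Feed the same input to several branches; concatenate flat outputs."""

    def __init__(self, branches: list[Sequential]) -> None:
        super().__init__()
        self.branches = branches

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train=train) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self._widths)[:-1]
        dx = None
        for branch, d in zip(self.branches, np.split(dout, splits, axis=1)):
            g = branch.backward(d)
            dx = g if dx is None else dx + g
        return dx

    def iter_layers(self):
        for b in self.branches:
            yield from b.iter_layers()

    def n_params(self) -> int:
        return sum(b.n_params() for b in self.branches)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.sum(onehot * np.log(np.clip(p, 1e-12, None)))) / n
    return loss, (p - onehot) / n


class Network:
    """A trunk of layers ending in class logits, with loss plumbing."""

    def __init__(self, trunk: Sequential, n_classes: int) -> None:
        self.trunk = trunk
        self.n_classes = n_classes

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        out = [
            softmax(self.trunk.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.vstack(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def train_batch(self, x: np.ndarray, onehot: np.ndarray) -> float:
        x = np.asarray(x, dtype=DTYPE)
        onehot = np.asarray(onehot, dtype=DTYPE)
        logits = self.trunk.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, onehot)
        self.trunk.backward(dlogits)
        return loss

    def parameters(self):
        """Yield (layer, name) handles for every trainable array."""
        for layer in self.trunk.iter_layers():
            for name in layer.params:
                yield layer, name

    def n_params(self) -> int:
        return self.trunk.n_params()

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights, strict=True):
            layer.params[name] = w.copy()


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, network: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.network = network
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in network.parameters()]
        self.v = [np.zeros_like(mi) for mi in self.m]

    def step(self) -> None:
        self.t += 1
        # fold both bias corrections into one step size (standard identity)
        step = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for i, (layer, name) in enumerate(self.network.parameters()):
            g = layer.grads[name]
            m, v = self.m[i], self.v[i]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            layer.params[name] -= step * m / (np.sqrt(v) + self.eps)
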