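"""Minimal numpy neural-network backend.

Implements exactly the layer vocabulary the topology grammar can express:
1-D convolution along the time axis (sensor channels as depth), max-pooling,
feedforward and LSTM/GRU layers with optional dropout and L1/L2 weight
regularization, a softmax classifier head, and the six supported learning
rules.  All layers carry explicit ``params``/``grads`` lists and a
forward/backward pair so the whole stack is trainable with plain
backpropagation (BPTT for the recurrent layers).

Internal activations use the (batch, time, features) layout; feedforward and
recurrent layers collapse the time axis to length 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaxPool1D",
    "FeedForward",
    "LSTM",
    "GRU",
    "SoftmaxClassifier",
    "make_optimizer",
]

_EPS = 1e-7


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "ReLU":
        return np.maximum(z, 0.0)
    return z


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "ReLU":
        return (z > 0).astype(z.dtype)
    return np.ones_like(z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # conv kernel (size, in, out)
        fan_in = shape[0] * shape[1]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: forward/backward plus aligned params and grads lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    regularizer: str = "none"
    reg_lambda: float = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def reg_penalty(self) -> float:
        if self.regularizer == "none" or self.reg_lambda == 0.0:
            return 0.0
        total = 0.0
        for w in self._reg_weights():
            if self.regularizer == "L1":
                total += np.abs(w).sum()
            else:
                total += (w ** 2).sum()
        return self.reg_lambda * total

    def add_reg_grads(self) -> None:
        if self.regularizer == "none" or self.reg_lambda == 0.0:
            return
        for w, g in zip(self.params, self.grads):
            if w.ndim < 2:  # biases are not regularized
                continue
            if self.regularizer == "L1":
                g += self.reg_lambda * np.sign(w)
            else:
                g += 2.0 * self.reg_lambda * w

    def _reg_weights(self) -> list[np.ndarray]:
        return [p for p in self.params if p.ndim >= 2]


class Dropout:
    """Inverted dropout helper shared by the dense layers."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Conv1D(Layer):
    """Valid 1-D convolution along the time axis, stride 1.

    Input (N, T, C_in) -> output (N, T - size + 1, kernels), with the
    element-wise activation fused in.
    """

    def __init__(
        self,
        in_channels: int,
        kernels: int,
        size: int,
        activation: str,
        rng: np.random.Generator,
    ):
        self.size = size
        self.activation = activation
        self.W = _glorot(rng, (size, in_channels, kernels))
        self.b = np.zeros(kernels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        windows = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=1)
        # windows: (N, T', C_in, size)
        self._windows = windows
        z = np.einsum("ntcs,sck->ntk", windows, self.W, optimize=True) + self.b
        self._z = z
        return _act(self.activation, z)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _act_grad(self.activation, self._z)
        self.grads[0][...] = np.einsum(
            "ntcs,ntk->sck", self._windows, dz, optimize=True
        )
        self.grads[1][...] = dz.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        Tp = dz.shape[1]
        for s in range(self.size):
            dx[:, s : s + Tp, :] += np.einsum(
                "ntk,ck->ntc", dz, self.W[s], optimize=True
            )
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max-pooling along the time axis: T -> T // size."""

    def __init__(self, size: int):
        self.size = size
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, T, F = x.shape
        T_out = T // self.size
        self._in_shape = x.shape
        trimmed = x[:, : T_out * self.size, :].reshape(N, T_out, self.size, F)
        self._argmax = trimmed.argmax(axis=2)
        return trimmed.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, T_out, F = dout.shape
        dx = np.zeros(self._in_shape)
        n_idx, t_idx, f_idx = np.meshgrid(
            np.arange(N), np.arange(T_out), np.arange(F), indexing="ij"
        )
        time_idx = t_idx * self.size + self._argmax
        np.add.at(dx, (n_idx, time_idx, f_idx), dout)
        return dx


class FeedForward(Layer):
    """Dense layer on the flattened sequence; output sequence length 1."""

    def __init__(
        self,
        in_time: int,
        in_features: int,
        units: int,
        activation: str,
        dropout: float,
        regularizer: str,
        reg_lambda: float,
        rng: np.random.Generator,
    ):
        self.in_dim = in_time * in_features
        self.activation = activation
        self.regularizer = regularizer
        self.reg_lambda = reg_lambda
        self.W = _glorot(rng, (self.in_dim, units))
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.dropout = Dropout(dropout, rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N = x.shape[0]
        self._x_shape = x.shape
        flat = x.reshape(N, -1)
        self._flat = flat
        z = flat @ self.W + self.b
        self._z = z
        out = _act(self.activation, z)
        out = self.dropout.forward(out, train)
        return out[:, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.dropout.backward(dout[:, 0, :])
        dz = d * _act_grad(self.activation, self._z)
        self.grads[0][...] = self._flat.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        dflat = dz @ self.W.T
        return dflat.reshape(self._x_shape)


class LSTM(Layer):
    """LSTM over the input sequence, emitting the last hidden state.

    Gate order in the packed weight matrices is (i, f, o, g); ``activation``
    replaces the usual tanh on the candidate and the cell output.
    """

    def __init__(
        self,
        in_features: int,
        units: int,
        activation: str,
        dropout: float,
        regularizer: str,
        reg_lambda: float,
        rng: np.random.Generator,
    ):
        self.units = units
        self.activation = activation
        self.regularizer = regularizer
        self.reg_lambda = reg_lambda
        self.Wx = _glorot(rng, (in_features, 4 * units))
        self.Wh = _glorot(rng, (units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.dropout = Dropout(dropout, rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, T, F = x.shape
        U = self.units
        h = np.zeros((N, U))
        c = np.zeros((N, U))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            zi, zf, zo, zg = (z[:, k * U : (k + 1) * U] for k in range(4))
            i, f, o = _sigmoid(zi), _sigmoid(zf), _sigmoid(zo)
            g = _act(self.activation, zg)
            c_prev = c
            c = f * c_prev + i * g
            ac = _act(self.activation, c)
            h_prev = h
            h = o * ac
            self._cache.append((i, f, o, g, zg, c_prev, c, ac, h_prev))
        self._h_last = h
        out = self.dropout.forward(h, train)
        return out[:, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        N, T, F = x.shape
        U = self.units
        dWx, dWh, db = (np.zeros_like(p) for p in self.params)
        dx = np.zeros_like(x)
        dh = self.dropout.backward(dout[:, 0, :])
        dc = np.zeros((N, U))
        for t in range(T - 1, -1, -1):
            i, f, o, g, zg, c_prev, c, ac, h_prev = self._cache[t]
            do = dh * ac
            dc = dc + dh * o * _act_grad(self.activation, c)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dzi = di * i * (1 - i)
            dzf = df * f * (1 - f)
            dzo = do * o * (1 - o)
            dzg = dg * _act_grad(self.activation, zg)
            dz = np.concatenate([dzi, dzf, dzo, dzg], axis=1)
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        self.grads[0][...] = dWx
        self.grads[1][...] = dWh
        self.grads[2][...] = db
        return dx


class GRU(Layer):
    """GRU over the input sequence, emitting the last hidden state.

    ``h_t = z * h_{t-1} + (1 - z) * act(x W_h + (r * h_{t-1}) U_h + b_h)``
    with packed gate order (z, r, h).
    """

    def __init__(
        self,
        in_features: int,
        units: int,
        activation: str,
        dropout: float,
        regularizer: str,
        reg_lambda: float,
        rng: np.random.Generator,
    ):
        self.units = units
        self.activation = activation
        self.regularizer = regularizer
        self.reg_lambda = reg_lambda
        self.Wx = _glorot(rng, (in_features, 3 * units))
        self.Wh = _glorot(rng, (units, 3 * units))
        self.b = np.zeros(3 * units)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.dropout = Dropout(dropout, rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, T, F = x.shape
        U = self.units
        h = np.zeros((N, U))
        self._x = x
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            zx = xt @ self.Wx + self.b
            hh_lin = h @ self.Wh
            z = _sigmoid(zx[:, :U] + hh_lin[:, :U])
            r = _sigmoid(zx[:, U : 2 * U] + hh_lin[:, U : 2 * U])
            rh = r * h
            zg = zx[:, 2 * U :] + rh @ self.Wh[:, 2 * U :]
            g = _act(self.activation, zg)
            h_prev = h
            h = z * h_prev + (1 - z) * g
            self._cache.append((z, r, g, zg, rh, h_prev))
        self._h_last = h
        out = self.dropout.forward(h, train)
        return out[:, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        N, T, F = x.shape
        U = self.units
        dWx, dWh, db = (np.zeros_like(p) for p in self.params)
        dx = np.zeros_like(x)
        dh = self.dropout.backward(dout[:, 0, :])
        for t in range(T - 1, -1, -1):
            z, r, g, zg, rh, h_prev = self._cache[t]
            dz_gate = dh * (h_prev - g)
            dg = dh * (1 - z)
            dzg = dg * _act_grad(self.activation, zg)
            drh = dzg @ self.Wh[:, 2 * U :].T
            dr = drh * h_prev
            dzz = dz_gate * z * (1 - z)
            dzr = dr * r * (1 - r)
            dpre = np.concatenate([dzz, dzr, dzg], axis=1)
            dWx += x[:, t, :].T @ dpre
            db += dpre.sum(axis=0)
            dWh[:, :U] += h_prev.T @ dzz
            dWh[:, U : 2 * U] += h_prev.T @ dzr
            dWh[:, 2 * U :] += rh.T @ dzg
            dx[:, t, :] = dpre @ self.Wx.T
            dh = (
                dh * z
                + dzz @ self.Wh[:, :U].T
                + dzr @ self.Wh[:, U : 2 * U].T
                + drh * r
            )
        self.grads[0][...] = dWx
        self.grads[1][...] = dWh
        self.grads[2][...] = db
        return dx


class SoftmaxClassifier(Layer):
    """Affine map from the flattened final activation to class probabilities."""

    def __init__(
        self,
        in_time: int,
        in_features: int,
        n_classes: int,
        rng: np.random.Generator,
    ):
        self.in_dim = in_time * in_features
        self.W = _glorot(rng, (self.in_dim, n_classes))
        self.b = np.zeros(n_classes)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N = x.shape[0]
        self._x_shape = x.shape
        flat = x.reshape(N, -1)
        self._flat = flat
        z = flat @ self.W + self.b
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self._probs = ez / ez.sum(axis=1, keepdims=True)
        return self._probs

    def backward_from_labels(self, y: np.ndarray) -> np.ndarray:
        """Combined softmax + cross-entropy gradient (mean over the batch)."""
        N = len(y)
        dz = self._probs.copy()
        dz[np.arange(N), y] -= 1.0
        dz /= N
        self.grads[0][...] = self._flat.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        dflat = dz @ self.W.T
        return dflat.reshape(self._x_shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError("use backward_from_labels")


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.state: dict[int, list] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(params, grads)):
            self._update(k, p, g)

    def _update(self, k: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGDOpt(_Optimizer):
    def _update(self, k, p, g):
        p -= self.lr * g


class AdaGradOpt(_Optimizer):
    def _update(self, k, p, g):
        acc = self.state.setdefault(k, [np.zeros_like(p)])[0]
        acc += g ** 2
        p -= self.lr * g / (np.sqrt(acc) + _EPS)


class AdaDeltaOpt(_Optimizer):
    rho = 0.95

    def _update(self, k, p, g):
        st = self.state.setdefault(k, [np.zeros_like(p), np.zeros_like(p)])
        acc, delta_acc = st
        acc *= self.rho
        acc += (1 - self.rho) * g ** 2
        update = np.sqrt(delta_acc + _EPS) / np.sqrt(acc + _EPS) * g
        delta_acc *= self.rho
        delta_acc += (1 - self.rho) * update ** 2
        p -= self.lr * update


class RMSPropOpt(_Optimizer):
    rho = 0.9

    def _update(self, k, p, g):
        acc = self.state.setdefault(k, [np.zeros_like(p)])[0]
        acc *= self.rho
        acc += (1 - self.rho) * g ** 2
        p -= self.lr * g / (np.sqrt(acc) + _EPS)


class AdamOpt(_Optimizer):
    b1, b2 = 0.9, 0.999

    def _update(self, k, p, g):
        st = self.state.setdefault(k, [np.zeros_like(p), np.zeros_like(p)])
        m, v = st
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g ** 2
        mhat = m / (1 - self.b1 ** self.t)
        vhat = v / (1 - self.b2 ** self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + _EPS)


class AdamaxOpt(_Optimizer):
    b1, b2 = 0.9, 0.999

    def _update(self, k, p, g):
        st = self.state.setdefault(k, [np.zeros_like(p), np.zeros_like(p)])
        m, u = st
        m *= self.b1
        m += (1 - self.b1) * g
        np.maximum(self.b2 * u, np.abs(g), out=u)
        p -= self.lr * m / ((1 - self.b1 ** self.t) * (u + _EPS))


_OPTIMIZERS = {
    "SGD": SGDOpt,
    "AdaGrad": AdaGradOpt,
    "AdaDelta": AdaDeltaOpt,
    "RMSProp": RMSPropOpt,
    "Adam": AdamOpt,
    "Adamax": AdamaxOpt,
}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        return _OPTIMIZERS[name](lr)
    except KeyError as exc:
        raise ValueError(f"unknown optimizer {name!r}") from exc
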