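"""Minimal numpy neural-network engine for the benchmark classifiers.

Implements exactly the layer types the benchmark architectures need — LSTM,
1-D valid convolution, batch normalization, dropout, flatten, dense — with
reverse-mode gradients and an Adam optimizer.  Everything is float64 and
driven by explicit ``numpy.random.Generator`` objects, so training is fully
deterministic given the seeds.

Conventions follow the common deep-learning defaults: Glorot-uniform kernel
init, orthogonal recurrent init with unit forget-gate bias for the LSTM,
batch-norm momentum 0.99 / epsilon 1e-3, Adam epsilon 1e-7.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTM", "Conv1D", "ReLU", "BatchNorm", "Dropout", "Flatten", "Dense",
           "Network", "Adam", "one_hot"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x, train: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


try:  # optional JIT kernels for the hot loops; numpy paths are the reference
    from . import _kernels as _lk
except ImportError:  # pragma: no cover - numba missing
    _lk = None


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state.

    Input (B, T, F) → output (B, units).  Gate order (i, f, g, o); forget
    bias initialized to 1.  When numba is available the sequence loop runs
    through a compiled kernel implementing the identical arithmetic; the
    numpy path below is the reference implementation and the fallback.
    """

    def __init__(self, units: int, features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units, self.features = units, features
        u = units
        self.Wx = _glorot(rng, features, 4 * u, (features, 4 * u))
        self.Wh = np.hstack([_orthogonal(rng, u, u) for _ in range(4)])
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        B, T, F = x.shape
        u = self.units
        x = np.ascontiguousarray(x, dtype=np.float64)
        self._x = x
        # input projection for all timesteps at once; the recurrence loop then
        # only carries the h @ Wh term
        zx = (x.reshape(B * T, F) @ self.Wx).reshape(B, T, 4 * u) + self.b
        if _lk is not None:
            h, self._kcache = _lk.forward(zx, self.Wh, u)
            self._cache = None
            return h
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        for t in range(T):
            z = zx[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._cache.append((h_prev, c_prev, i, f, g, o, tc))
        return h

    def backward(self, grad):
        x = self._x
        B, T, F = x.shape
        u = self.units
        if self._cache is None:
            dz_flat = _lk.backward(np.ascontiguousarray(grad), self.Wh, u,
                                   *self._kcache).reshape(B * T, 4 * u)
            h_all = self._kcache[4]
            self.grads[0][...] = x.reshape(B * T, F).T @ dz_flat
            self.grads[1][...] = h_all.reshape(B * T, u).T @ dz_flat
            self.grads[2][...] = dz_flat.sum(axis=0)
            return None
        dz_all = np.empty((B, T, 4 * u))
        h_all = np.empty((B, T, u))
        dh = grad
        dc = np.zeros_like(grad)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = dz_all[:, t]
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u:2 * u] = df * f * (1.0 - f)
            dz[:, 2 * u:3 * u] = dg * (1.0 - g * g)
            dz[:, 3 * u:] = do * o * (1.0 - o)
            h_all[:, t] = h_prev
            dh = dz @ self.Wh.T
            dc = dc * f
        dz_flat = dz_all.reshape(B * T, 4 * u)
        self.grads[0][...] = x.reshape(B * T, F).T @ dz_flat
        self.grads[1][...] = h_all.reshape(B * T, u).T @ dz_flat
        self.grads[2][...] = dz_flat.sum(axis=0)
        return None  # first layer; input gradient not propagated


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1: (B, L, Cin) → (B, L−k+1, filters)."""

    def __init__(self, filters: int, kernel: int, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.filters, self.kernel, self.channels = filters, kernel, channels
        fan_in = kernel * channels
        self.W = _glorot(rng, fan_in, filters, (kernel, channels, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        B, L, C = x.shape
        k = self.kernel
        Lo = L - k + 1
        if Lo < 1:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        # im2col: one (B·Lo, k·C) @ (k·C, F) matmul instead of k strided ones
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, Lo, C, k)
        cols = windows.transpose(0, 1, 3, 2).reshape(B * Lo, k * C)
        y = cols @ self.W.reshape(k * C, self.filters) + self.b
        self._x = x
        self._cols = cols
        return y.reshape(B, Lo, self.filters)

    def backward(self, grad):
        x = self._x
        B, Lo, F = grad.shape
        k, C = self.kernel, self.channels
        g2 = grad.reshape(B * Lo, F)
        self.grads[0][...] = (self._cols.T @ g2).reshape(k, C, F)
        self.grads[1][...] = g2.sum(axis=0)
        dx = np.zeros_like(x)
        for j in range(k):
            dx[:, j:j + Lo, :] += grad @ self.W[j].T
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization over batch (and length, if 3-D) axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        self._train = train
        if not train:
            # fold the affine transform into one multiply-add per element
            scale = self.gamma / np.sqrt(self.running_var + self.eps)
            self._scale = scale
            return x * scale + (self.beta - self.running_mean * scale)
        axes = tuple(range(x.ndim - 1))
        if _lk is not None and x.ndim == 3:
            y, mean, var, std, xhat = _lk.bn_forward_train(
                np.ascontiguousarray(x), self.gamma, self.beta, self.eps)
        else:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            std = np.sqrt(var + self.eps)
            xhat = (x - mean) / std
            y = self.gamma * xhat + self.beta
        m = self.momentum
        self.running_mean[...] = m * self.running_mean + (1 - m) * mean
        self.running_var[...] = m * self.running_var + (1 - m) * var
        self._axes = axes
        self._n = int(np.prod([x.shape[a] for a in axes]))
        self._std = std
        self._xhat = xhat
        return y

    def backward(self, grad):
        if not self._train:
            raise RuntimeError("batch-norm backward requires a training-mode forward")
        if _lk is not None and grad.ndim == 3:
            dx, dgamma, dbeta = _lk.bn_backward_train(
                np.ascontiguousarray(grad), self._xhat, self._std, self.gamma)
            self.grads[0][...] = dgamma
            self.grads[1][...] = dbeta
            return dx
        axes = self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        # float32 draws: half the memory traffic of the default float64 stream
        self._mask = rng.random(x.shape, dtype=np.float32) < keep
        self._scale = 1.0 / keep
        out = x * self._mask
        out *= self._scale
        return out

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        out *= self._scale
        return out


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


_EPS = 1e-7  # probability clip in the cross-entropy


class Network:
    """Feed-forward stack ending in a 2-unit head with sigmoid or softmax.

    With the sigmoid head (the benchmark's printed choice) the categorical
    cross-entropy normalizes the two sigmoid activations to a distribution
    before taking the log, matching the usual framework semantics of pairing
    a sigmoid output layer with categorical cross-entropy.
    """

    def __init__(self, layers: list[Layer], head: str = "sigmoid") -> None:
        if head not in ("sigmoid", "softmax"):
            raise ValueError("head must be 'sigmoid' or 'softmax'")
        self.layers = layers
        self.head = head

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def _forward(self, x, train: bool, rng) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def _activate(self, z: np.ndarray) -> np.ndarray:
        if self.head == "sigmoid":
            return _sigmoid(z)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_scores(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Per-class scores in [0, 1], in inference mode."""
        outs = [self._activate(self._forward(x[i:i + batch_size], False, None))
                for i in range(0, x.shape[0], batch_size)]
        return np.vstack(outs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class labels (0/1)."""
        return self.predict_scores(x).argmax(axis=1).astype(np.int8)

    def loss(self, x: np.ndarray, t: np.ndarray) -> float:
        """Mean categorical cross-entropy in inference mode; t is one-hot."""
        return self.loss_and_accuracy(x, t)[0]

    def loss_and_accuracy(self, x: np.ndarray, t: np.ndarray) -> tuple[float, float]:
        """Inference-mode cross-entropy and argmax accuracy in one pass."""
        s = self.predict_scores(x)
        p = s / np.clip(s.sum(axis=1, keepdims=True), _EPS, None) if self.head == "sigmoid" else s
        loss = float(-np.mean(np.sum(t * np.log(np.clip(p, _EPS, 1.0)), axis=1)))
        acc = float(np.mean(s.argmax(axis=1) == t.argmax(axis=1)))
        return loss, acc

    def train_step(self, x: np.ndarray, t: np.ndarray, optimizer: "Adam",
                   rng: np.random.Generator) -> tuple[float, int]:
        """One forward/backward/update pass; returns (batch loss, n correct)."""
        B = x.shape[0]
        z = self._forward(x, True, rng)
        s = self._activate(z)
        if self.head == "softmax":
            p = s
            dz = (p - t) / B
        else:
            S = np.clip(s.sum(axis=1, keepdims=True), _EPS, None)
            p = s / S
            ds = (-t / np.clip(s, _EPS, None) + 1.0 / S) / B
            dz = ds * s * (1.0 - s)
        loss = float(-np.mean(np.sum(t * np.log(np.clip(p, _EPS, 1.0)), axis=1)))
        correct = int(np.sum(p.argmax(axis=1) == t.argmax(axis=1)))
        grad = dz
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self.layers)
        return loss, correct

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)


class Adam:
    """Adam optimizer (β1 = 0.9, β2 = 0.999, ε = 1e-7)."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self, layers: list[Layer]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self._t) / (1 - b1 ** self._t)
        for layer in layers:
            for p, g in zip(layer.params, layer.grads):
                key = id(p)
                if key not in self._state:
                    self._state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._state[key]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                p -= lr_t * m / (np.sqrt(v) + self.eps)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return out
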