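"""A compact NumPy implementation of the 1-D temporal CNN used throughout.

The network is small enough that an explicit forward/backward
implementation on top of BLAS matmuls is both fast and fully
deterministic given a seed, which the subject-wise cross-validation
protocol relies on. Architecture: a stack of 1-D convolutions over the
frame axis (feature columns as input channels, same padding, stride 1),
each followed by batch normalization, ReLU and dropout; a flatten; one
fully connected layer (BN, ReLU, dropout); and a single linear output
unit producing a logit. The loss is binary cross-entropy on the logit.

Gradients are exact (verified against finite differences in the test
suite). The Adam optimizer follows the standard update with bias
correction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "BatchNorm", "ReLU", "Dropout", "Dense", "Flatten",
           "SequentialNet", "Adam", "bce_with_logits", "sigmoid"]

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99

# All parameters and activations are float32: the networks are small and
# memory-bandwidth-bound, and single precision is standard for CNN training.
DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    logits = np.asarray(logits)
    y = np.asarray(y, dtype=logits.dtype)
    # log(1 + e^z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    grad = ((sigmoid(logits) - y) / logits.size).astype(logits.dtype)
    return loss, grad


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D:
    """Same-padding 1-D convolution over the frame axis, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        self.k = kernel_size
        self.pad = kernel_size // 2
        self.c_in = c_in
        self.c_out = c_out
        self.W = _glorot_uniform(rng, kernel_size * c_in, c_out,
                                 (c_in * kernel_size, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        B, T, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        # (B, T, c_in, k) windows -> rows of the im2col matrix
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        self._cols = cols.reshape(B * T, self.c_in * self.k)
        self._in_shape = (B, T)
        out = self._cols @ self.W + self.b
        return out.reshape(B, T, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T = self._in_shape
        d2 = dout.reshape(B * T, self.c_out)
        self.dW[...] = self._cols.T @ d2
        self.db[...] = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(B, T, self.c_in, self.k)
        dxp = np.zeros((B, T + 2 * self.pad, self.c_in), dtype=dout.dtype)
        for w in range(self.k):                       # k is small (<= 9)
            dxp[:, w:w + T, :] += dcols[:, :, :, w]
        return dxp[:, self.pad:self.pad + T, :]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot_uniform(rng, n_in, n_out, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class BatchNorm:
    """Batch normalization over all axes except the last (channel) axis."""

    def __init__(self, n_channels: int, momentum: float = _BN_MOMENTUM,
                 eps: float = _BN_EPS):
        self.gamma = np.ones(n_channels, dtype=DTYPE)
        self.beta = np.zeros(n_channels, dtype=DTYPE)
        self.dgamma = np.zeros(n_channels, dtype=DTYPE)
        self.dbeta = np.zeros(n_channels, dtype=DTYPE)
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training, rng=None):
        self._shape = x.shape
        x2 = x.reshape(-1, x.shape[-1])
        if training:
            mu = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._mu, self._var = mu, var
            self._xc = x2 - mu
            self._inv_sd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = self._xc * self._inv_sd
            out = self.gamma * self._xhat + self.beta
        else:
            xhat = (x2 - self.running_mean) / np.sqrt(self.running_var + self.eps)
            out = self.gamma * xhat + self.beta
        return out.reshape(self._shape)

    def backward(self, dout):
        d2 = dout.reshape(-1, dout.shape[-1])
        n = d2.shape[0]
        self.dgamma[...] = (d2 * self._xhat).sum(axis=0)
        self.dbeta[...] = d2.sum(axis=0)
        dxhat = d2 * self.gamma
        dx = (self._inv_sd / n) * (
            n * dxhat
            - dxhat.sum(axis=0)
            - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(self._shape)


class ReLU:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class SequentialNet:
    """A plain layer stack ending in a single linear logit unit."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out[:, 0]                                  # (B,) logits

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p[...] = w

    def get_state(self):
        """Weights plus batch-norm running statistics."""
        state = {"weights": self.get_weights(), "running": []}
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state["running"].append(
                    (layer.running_mean.copy(), layer.running_var.copy()))
        return state

    def set_state(self, state):
        self.set_weights(state["weights"])
        it = iter(state["running"])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                mean, var = next(it)
                layer.running_mean[...] = mean
                layer.running_var[...] = var


class Adam:
    """Adam with bias correction (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, params, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 epsilon=1e-7):
        self.params = params
        self.lr = learning_rate
        self.b1 = beta1
        self.b2 = beta2
        self.eps = epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
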