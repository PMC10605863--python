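"""A compact 1D-CNN engine in numpy.

Implements exactly the layer set the beat classifier needs — stride-1
length-preserving 1D convolution, batch normalisation, ReLU/sigmoid,
inverted dropout, flatten, dense, softmax + categorical cross-entropy —
with hand-written backprop and an Adam optimiser.  Keeping the engine
in-repo (rather than behind an autodiff framework) makes the gradients
of a class score with respect to any intermediate feature map directly
available, which is what the Grad-CAM++ stage consumes, and lets the
test-suite check those gradients against central finite differences.

Shapes: activations are ``(N, C, L)`` float32; dense layers operate on
``(N, F)``.  Convolutions use "same" zero padding so L is preserved.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ----------------------------------------------------------------------
# Layers
# ----------------------------------------------------------------------

class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv1dSame(Layer):
    """Stride-1 cross-correlation with zero 'same' padding.

    Weights ``W``: (C_out, C_in, K); Xavier/Glorot-uniform init with
    fan_in = C_in*K, fan_out = C_out*K; biases start at zero.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("same-padding conv needs an odd kernel")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.params["W"] = _glorot_uniform(
            rng, (c_out, c_in, kernel_size),
            c_in * kernel_size, c_out * kernel_size)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (N, C, L, K) -> (N, L, C*K)
        return np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n, length, c * self.k)

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._cols = self._im2col(x)           # (N, L, C_in*K)
        self._in_shape = x.shape
        w2 = self.params["W"].reshape(self.c_out, -1).T  # (C_in*K, C_out)
        y = self._cols @ w2 + self.params["b"]           # (N, L, C_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        n, _, length = self._in_shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1), dtype=DTYPE)
        flat_cols = self._cols.reshape(-1, self.c_in * self.k)
        flat_dy = dyt.reshape(-1, self.c_out)
        self.grads["W"] = (flat_dy.T @ flat_cols).reshape(
            self.c_out, self.c_in, self.k)
        self.grads["b"] = flat_dy.sum(axis=0)
        dcols = (flat_dy @ self.params["W"].reshape(self.c_out, -1)).reshape(
            n, length, self.c_in, self.k)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, length + 2 * p), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, :, j:j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p:p + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (batch, position) axes."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean = self.running_mean.astype(DTYPE)
            var = self.running_var.astype(DTYPE)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE))
        return (self.params["gamma"][None, :, None] * xhat
                + self.params["beta"][None, :, None]).astype(DTYPE)

    def backward(self, dy):
        xhat, inv_std = self._cache
        n, c, length = dy.shape
        m = n * length
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        z = np.clip(x, -60.0, 60.0).astype(DTYPE)
        self._y = 1.0 / (1.0 + np.exp(-z))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


# ----------------------------------------------------------------------
# Network
# ----------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  eps: float = 1e-12) -> float:
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())


class Network:
    """A feed-forward stack with an optional *tap*: the index of the
    layer whose output is the feature map of interest for class
    activation mapping (the last convolutional block's activation)."""

    def __init__(self, layers: list[Layer], tap_index: int | None = None):
        self.layers = layers
        self.tap_index = tap_index
        self.tap_value: np.ndarray | None = None

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=DTYPE)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if i == self.tap_index:
                self.tap_value = h
        return h  # logits (N, n_classes)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def backward_from_logits(self, dlogits: np.ndarray,
                             stop_after: int | None = None) -> np.ndarray:
        """Backpropagate ``d(objective)/d(logits)``; returns the gradient
        with respect to the output of layer ``stop_after`` (or the input
        when None)."""
        g = dlogits.astype(DTYPE)
        stop = -1 if stop_after is None else stop_after
        for i in range(len(self.layers) - 1, stop, -1):
            g = self.layers[i].backward(g)
        return g

    # -- Grad-CAM support ---------------------------------------------
    def forward_from_tap(self, tap_activation: np.ndarray) -> np.ndarray:
        """Run only the layers after the tap (inference mode)."""
        if self.tap_index is None:
            raise ValueError("network has no tap layer")
        h = np.ascontiguousarray(tap_activation, dtype=DTYPE)
        for layer in self.layers[self.tap_index + 1:]:
            h = layer.forward(h, False)
        return h

    def class_score_grad_at_tap(self, x: np.ndarray, class_index: int
                                ) -> tuple[np.ndarray, np.ndarray]:
        """(feature maps A, dS_c/dA) at the tap for pre-softmax score
        S_c; batched over the first axis."""
        if self.tap_index is None:
            raise ValueError("network has no tap layer")
        logits = self.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        grad = self.backward_from_logits(dlogits, stop_after=self.tap_index)
        return self.tap_value, grad

    # -- parameter plumbing -------------------------------------------
    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value

    def get_state(self) -> list[np.ndarray]:
        state = [v.copy() for _, _, v in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer, name, _ in list(self.parameters()):
            layer.params[name] = next(it).copy()
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, _, v in net.parameters()]
        self.v = [np.zeros_like(v) for _, _, v in net.parameters()]

    def step(self):
        self.t += 1
        for i, (layer, name, value) in enumerate(self.net.parameters()):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] = value - self.lr * mhat / (
                np.sqrt(vhat) + self.eps)
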