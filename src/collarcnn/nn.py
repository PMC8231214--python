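"""Minimal 1D CNN engine (numpy).

Implements exactly the layer set the collar classifier needs — 1D valid
convolution, inverted dropout, batch normalisation, ReLU, adaptive average
pooling to length one, a linear head — together with softmax cross-entropy,
reverse-mode gradients, the AdamW optimiser with decoupled weight decay,
and a one-cycle learning-rate schedule. Convolutions are evaluated as
im2col matrix products so the heavy lifting is BLAS sgemm.

Weight layouts follow the usual convention: conv weights are
``(out_channels, in_channels, kernel)``, linear weights ``(out, in)``.
Batch-norm keeps two trainable parameters per channel (scale, shift) plus
non-trainable running statistics. All gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "Dropout",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "ConvNet",
    "softmax",
    "softmax_cross_entropy",
    "AdamW",
    "OneCycleSchedule",
    "ConstantSchedule",
]


class Layer:
    """Base: ``params`` maps name -> array (updated in place by the
    optimiser), ``grads`` holds the matching gradients after backward."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv1d(Layer):
    """Valid-padding strided 1D convolution (cross-correlation) with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if min(in_channels, out_channels, kernel_size, stride) < 1:
            raise ValueError("conv dimensions and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.params["weight"] = _uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in, dtype)
        self.params["bias"] = _uniform_init(rng, (out_channels,), fan_in, dtype)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def out_length(self, in_length: int) -> int:
        if in_length < self.kernel_size:
            raise ValueError(
                f"input length {in_length} shorter than kernel {self.kernel_size}"
            )
        return (in_length - self.kernel_size) // self.stride + 1

    def _weight2d(self) -> np.ndarray:
        w = self.params["weight"]
        if w.dtype == np.float16:  # FP16 storage, FP32 arithmetic
            w = w.astype(np.float32)
        return w.reshape(self.out_channels, -1)

    def forward(self, x, training, rng=None):
        n, c, length = x.shape
        l_out = self.out_length(length)
        k, s = self.kernel_size, self.stride
        v = sliding_window_view(x, k, axis=2)[:, :, :: s][:, :, :l_out]  # (N,C,L_out,K)
        cols = np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(n, l_out, c * k)
        bias = self.params["bias"]
        if bias.dtype == np.float16:
            bias = bias.astype(np.float32)
        y = cols @ self._weight2d().T + bias
        self._cols, self._in_len = cols, length
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        cols = self._cols
        n, l_out, _ = cols.shape
        g = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (N,L_out,out)
        dw2d = np.tensordot(g, cols, axes=([0, 1], [0, 1]))  # (out, C*K)
        self.grads["weight"] = dw2d.reshape(self.params["weight"].shape)
        self.grads["bias"] = dy.sum(axis=(0, 2))
        dcols = (g @ self._weight2d()).reshape(n, l_out, self.in_channels, self.kernel_size)
        dcols = dcols.transpose(0, 2, 1, 3)  # (N,C,L_out,K)
        dx = np.zeros((n, self.in_channels, self._in_len), dtype=dy.dtype)
        s = self.stride
        for j in range(self.kernel_size):
            dx[:, :, j : j + s * l_out : s] += dcols[:, :, :, j]
        self._cols = None
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (batch, length) axes."""

    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["weight"] = np.ones(channels, dtype=dtype)   # scale (gamma)
        self.params["bias"] = np.zeros(channels, dtype=dtype)    # shift (beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, training, rng=None):
        gamma = self.params["weight"][None, :, None]
        beta = self.params["bias"][None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = x.shape[0] * x.shape[2]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std) if training else None
        return gamma * xhat + beta

    def backward(self, dy):
        xhat, std = self._cache
        gamma = self.params["weight"]
        m = dy.shape[0] * dy.shape[2]
        self.grads["weight"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["bias"] = dy.sum(axis=(0, 2))
        sum_dy = dy.sum(axis=(0, 2))[None, :, None]
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2))[None, :, None]
        g = gamma[None, :, None] / (std[None, :, None] * m)
        dx = g * (m * dy - sum_dy - xhat * sum_dy_xhat)
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    trainable = False

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs a random generator")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class ReLU(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool(Layer):
    """Adaptive average pooling to a single value per channel: (N,C,L)->(N,C).

    Makes the classifier length-agnostic, so one model evaluates 60/90/120 s
    windows interchangeably."""

    trainable = False

    def __init__(self):
        super().__init__()
        self._length = 0

    def forward(self, x, training, rng=None):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params["weight"] = _uniform_init(rng, (out_features, in_features), in_features, dtype)
        self.params["bias"] = _uniform_init(rng, (out_features,), in_features, dtype)
        self._x = None

    def forward(self, x, training, rng=None):
        w, b = self.params["weight"], self.params["bias"]
        if w.dtype == np.float16:
            w, b = w.astype(np.float32), b.astype(np.float32)
        self._x = x
        return x @ w.T + b

    def backward(self, dy):
        w = self.params["weight"]
        if w.dtype == np.float16:
            w = w.astype(np.float32)
        self.grads["weight"] = dy.T @ self._x
        self.grads["bias"] = dy.sum(axis=0)
        self._x = None
        return dy @ w


class ConvNet:
    """Sequential container: conv blocks (Conv -> Dropout -> BatchNorm ->
    ReLU), global average pooling, linear head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def conv_layers(self) -> list[Conv1d]:
        return [l for l in self.layers if isinstance(l, Conv1d)]

    @property
    def batchnorm_layers(self) -> list[BatchNorm1d]:
        return [l for l in self.layers if isinstance(l, BatchNorm1d)]

    @property
    def head(self) -> Linear:
        return next(l for l in self.layers if isinstance(l, Linear))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size], training=False)
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0) if out else np.empty((0, self.head.out_features))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return np.argmax(self.predict_logits(x, batch_size), axis=1)

    # -- parameter bookkeeping ---------------------------------------------
    def named_parameters(self):
        """Yield (name, layer, key) triples for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                yield f"layer{i}.{type(layer).__name__}.{key}", layer, key

    def n_trainable_parameters(self) -> int:
        """Brute-force enumeration of trainable tensor sizes."""
        return int(sum(layer.params[key].size for _, layer, key in self.named_parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: layer.params[key].copy() for name, layer, key in self.named_parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_parameters():
            np.copyto(layer.params[key], state[name])
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                np.copyto(layer.running_mean, state[f"layer{i}.running_mean"])
                np.copyto(layer.running_var, state[f"layer{i}.running_var"])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(p[np.arange(n), targets] + 1e-300).mean())
    dlogits = p
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class AdamW:
    """Adam with decoupled weight decay (the weight-decay step scales with
    the scheduled learning rate, not the adaptive one)."""

    def __init__(self, net: ConvNet, lr: float = 1e-4, weight_decay: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = {name: np.zeros_like(layer.params[key])
                   for name, layer, key in net.named_parameters()}
        self._v = {name: np.zeros_like(layer.params[key])
                   for name, layer, key in net.named_parameters()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, layer, key in self.net.named_parameters():
            g = layer.grads[key].astype(np.float32)
            m = self._m[name]
            v = self._v[name]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p = layer.params[key]
            p -= (lr * update + lr * self.weight_decay * p).astype(p.dtype)


class OneCycleSchedule:
    """Linear warm-up to ``peak_factor * base_lr`` over ``warmup_frac`` of the
    run, then cosine annealing down to ``base_lr / final_div``."""

    def __init__(self, base_lr: float, total_steps: int, peak_factor: float = 10.0,
                 warmup_frac: float = 0.3, final_div: float = 100.0):
        if total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        self.base_lr = base_lr
        self.total_steps = total_steps
        self.peak_lr = peak_factor * base_lr
        self.final_lr = base_lr / final_div
        self.warmup_steps = max(1, int(round(warmup_frac * total_steps)))

    def lr_at(self, step: int) -> float:
        if step <= self.warmup_steps:
            frac = step / self.warmup_steps
            return self.base_lr + frac * (self.peak_lr - self.base_lr)
        span = max(self.total_steps - self.warmup_steps, 1)
        frac = min((step - self.warmup_steps) / span, 1.0)
        return self.final_lr + 0.5 * (self.peak_lr - self.final_lr) * (1 + np.cos(np.pi * frac))


class ConstantSchedule:
    """Fixed learning rate — used during the pruning iterations, where no
    annealing is applied so learning stays active between filter removals."""

    def __init__(self, lr: float):
        self.lr = lr

    def lr_at(self, step: int) -> float:
        return self.lr
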