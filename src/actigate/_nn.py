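"""A compact NumPy engine for the small convolutional classifiers used here.

The activity-recognition models are tiny (tens of thousands to under a
million parameters on 30×24 single-channel inputs), so a plain NumPy
implementation with im2col convolutions and BLAS matmuls trains them in
minutes on one CPU core. The engine implements exactly the layer vocabulary
the model family needs: 'same'-padded biased 3×3 convolutions with ReLU,
2×2 max pooling with floor on odd dimensions, global average pooling,
dense layers, inverted dropout, and softmax cross-entropy with Adam.

Data layout is NHWC throughout; all activations are float32.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 'same' convolution with bias and optional ReLU."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        relu: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.relu = relu
        fan_in = kernel * kernel * in_ch
        self.W = _he_init(rng, fan_in, (fan_in, out_ch))
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        k = self.kernel
        cols = [
            xp[:, di : di + H, dj : dj + W, :] for di in range(k) for dj in range(k)
        ]
        return np.concatenate(cols, axis=-1)  # (B, H, W, k*k*C)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, C = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = self._im2col(xp, H, W)
        z = cols.reshape(-1, cols.shape[-1]) @ self.W + self.b
        z = z.reshape(B, H, W, self.out_ch)
        if self.relu:
            self._mask = z > 0
            z = np.maximum(z, 0)
        if train:
            self._cols = cols
            self._in_shape = (B, H, W, C)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._in_shape
        k, p = self.kernel, self.kernel // 2
        dz = dout * self._mask if self.relu else dout
        dz_flat = dz.reshape(-1, self.out_ch)
        cols_flat = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads[0][...] = cols_flat.T @ dz_flat
        self.grads[1][...] = dz_flat.sum(axis=0)
        dcols = (dz_flat @ self.W.T).reshape(B, H, W, k * k * C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            dxp[:, di : di + H, dj : dj + W, :] += dcols[..., idx * C : (idx + 1) * C]
        del self._cols
        return dxp[:, p : p + H, p : p + W, :]


class MaxPool2D(Layer):
    """2×2 max pooling; odd trailing rows/columns are dropped (floor)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.size
        B, H, W, C = x.shape
        H2, W2 = H // s, W // s
        xr = x[:, : H2 * s, : W2 * s, :].reshape(B, H2, s, W2, s, C)
        out = xr.max(axis=(2, 4))
        if train:
            self._in_shape = x.shape
            self._xr = xr
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.size
        B, H, W, C = self._in_shape
        H2, W2 = H // s, W // s
        mask = self._xr == self._out[:, :, None, :, None, :]
        # distribute gradient equally among tied maxima (deterministic)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        dx[:, : H2 * s, : W2 * s, :] = dxr.reshape(B, H2 * s, W2 * s, C)
        return dx


class GlobalAvgPool(Layer):
    """Mean over the spatial dimensions: (B, H, W, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._in_shape
        return np.broadcast_to(dout[:, None, None, :] / (H * W), (B, H, W, C)).astype(
            np.float32
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(
        self,
        in_units: int,
        out_units: int,
        relu: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.relu = relu
        self.W = _he_init(rng, in_units, (in_units, out_units))
        self.b = np.zeros(out_units, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            z = np.maximum(z, 0)
        if train:
            self._x = x
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._mask if self.relu else dout
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward stack trained with softmax cross-entropy and Adam."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; leaves gradients in the layers."""
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        n = len(y)
        loss = float(-np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean())
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        probs = self.predict_proba(x, batch_size)
        return float(-np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).mean())

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights, strict=True):
            p[...] = w


class Adam:
    """Adam with a constant learning rate."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
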