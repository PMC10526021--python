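"""Minimal NumPy neural-network layer stack with manual backpropagation.

Supplies exactly what the pre-training and fine-tuning loops need: strided
convolutions, ReLU, global average pooling, affine layers, inverted dropout,
a decoupled-weight-decay Adam optimizer (AdamW), and npz checkpointing.
Layouts are NCHW float32.  The desk-scale encoders (``tiny_cnn``,
``micro_cnn``) are small strided convnets suitable for CPU training on
64-pixel images; the ResNet34 encoder used at clinical scale requires a GPU
deep-learning framework and is not part of this build.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def set_buffers(self, bufs: Sequence[np.ndarray]) -> None:
        if bufs:
            raise ValueError("layer holds no buffers")


class Conv2d(Layer):
    """3x3-style strided convolution via im2col; zero padding."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * kernel * kernel))  # He init
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)))
        self.b = Param(np.zeros(cout))
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, train=False, rng=None):
        k, s, p = self.kernel, self.stride, self.padding
        n, cin, h, w = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # N,Cin,Ho,Wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, cin * k * k)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)  # Cout, Cin*k*k
        out = col @ wmat.T + self.b.value
        self._cache = (col, x.shape, (n, ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, gout):
        col, xpad_shape, (n, ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        cout = gout.shape[1]
        g = gout.transpose(0, 2, 3, 1).reshape(n, ho * wo, cout)
        wmat = self.w.value.reshape(cout, -1)
        self.w.grad += (g.reshape(-1, cout).T @ col.reshape(-1, col.shape[-1])
                        ).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=(0, 1))
        gcol = (g @ wmat).reshape(n, ho, wo, -1, k, k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros(xpad_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcol[:, :, :, :, i, j]
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class BatchNorm(Layer):
    """Batch normalization over the channel axis (2-D or 4-D inputs).

    Training mode normalizes by batch statistics and updates running
    estimates; inference mode uses the running estimates, so embeddings are
    deterministic per image.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _flat(x: np.ndarray) -> np.ndarray:
        # collapse all axes except channels: (N,C) or (N,C,H,W) -> (M,C)
        if x.ndim == 2:
            return x
        return x.transpose(0, 2, 3, 1).reshape(-1, x.shape[1])

    def _unflat(self, y: np.ndarray, shape) -> np.ndarray:
        if len(shape) == 2:
            return y
        n, c, h, w = shape
        return y.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def forward(self, x, train=False, rng=None):
        flat = self._flat(x)
        if train:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        self._cache = (xhat, inv, x.shape, train)
        return self._unflat(xhat * self.gamma.value + self.beta.value, x.shape)

    def backward(self, gout):
        xhat, inv, shape, train = self._cache
        g = self._flat(gout)
        self.gamma.grad += np.sum(g * xhat, axis=0)
        self.beta.grad += np.sum(g, axis=0)
        if not train:
            return self._unflat(g * self.gamma.value * inv, shape)
        m = g.shape[0]
        gx = (self.gamma.value * inv / m) * (
            m * g - g.sum(axis=0) - xhat * np.sum(g * xhat, axis=0)
        )
        return self._unflat(gx.astype(np.float32), shape)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def set_buffers(self, bufs: Sequence[np.ndarray]) -> None:
        self.running_mean, self.running_var = [b.astype(np.float32) for b in bufs]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / din)
        self.w = Param(rng.normal(0.0, scale, size=(din, dout)))
        self.b = Param(np.zeros(dout))

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout):
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def set_buffers(self, bufs):
        i = 0
        for layer in self.layers:
            k = len(layer.buffers())
            if k:
                layer.set_buffers(bufs[i:i + k])
                i += k
        if i != len(bufs):
            raise ValueError("buffer count mismatch")


ENCODER_FEATURE_DIMS = {"tiny_cnn": 64, "micro_cnn": 32}


def build_encoder(architecture: str, rng: np.random.Generator) -> tuple[Sequential, int]:
    """Encoder f(·): image -> feature vector.  Returns (net, feature_dim)."""
    if architecture == "tiny_cnn":
        chans = [3, 16, 32, 64, 64]
    elif architecture == "micro_cnn":
        chans = [3, 8, 16, 32]
    elif architecture == "resnet34":
        raise NotImplementedError(
            "resnet34 is the clinical-scale encoder and requires a GPU "
            "deep-learning framework; use 'tiny_cnn' for CPU-scale runs"
        )
    else:
        raise ValueError(f"unknown encoder architecture {architecture!r}")
    layers: list[Layer] = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        layers += [Conv2d(cin, cout, 3, 2, 1, rng), BatchNorm(cout), ReLU()]
    layers.append(GlobalAvgPool())
    return Sequential(layers), chans[-1]


def build_projection_head(feature_dim: int, hidden_dim: int, out_dim: int,
                          rng: np.random.Generator) -> Sequential:
    """Projection head g(·): Linear -> ReLU -> Linear."""
    return Sequential([Linear(feature_dim, hidden_dim, rng), ReLU(),
                       Linear(hidden_dim, out_dim, rng)])


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Param], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            p.value *= 1.0 - self.lr * self.weight_decay
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def save_checkpoint(path: str | Path, modules: dict[str, Layer],
                    meta: dict) -> Path:
    """Serialize named modules' parameters plus a JSON metadata blob."""
    path = Path(path)
    arrays = {}
    for name, module in modules.items():
        for i, p in enumerate(module.params()):
            arrays[f"{name}.{i}"] = p.value
        for i, b in enumerate(module.buffers()):
            arrays[f"{name}@buf.{i}"] = b
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(
    path: str | Path,
) -> tuple[dict[str, list[np.ndarray]], dict[str, list[np.ndarray]], dict]:
    """Inverse of :func:`save_checkpoint`: (weights, buffers, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        grouped: dict[str, list[tuple[int, np.ndarray]]] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            name, idx = key.rsplit(".", 1)
            grouped.setdefault(name, []).append((int(idx), data[key]))
    ordered = {name: [a for _, a in sorted(vals)] for name, vals in grouped.items()}
    weights = {n: v for n, v in ordered.items() if "@buf" not in n}
    buffers = {n.split("@buf")[0]: v for n, v in ordered.items() if "@buf" in n}
    return weights, buffers, meta


def restore_module(module: Layer, weights: Sequence[np.ndarray],
                   buffers: Optional[Sequence[np.ndarray]] = None) -> None:
    set_params(module, weights)
    if buffers:
        module.set_buffers(list(buffers))


def set_params(module: Layer, weights: Sequence[np.ndarray]) -> None:
    params = module.params()
    if len(params) != len(weights):
        raise ValueError(
            f"checkpoint holds {len(weights)} arrays but module has {len(params)} parameters"
        )
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError(f"shape mismatch: checkpoint {w.shape} vs model {p.value.shape}")
        p.value = w.astype(np.float32)
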