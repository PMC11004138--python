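"""Minimal NumPy neural-network core.

Implements exactly the pieces the tile scorer and the slide-level fusion
head need — 3x3 convolutions (im2col), 2x2 max pooling, global average
pooling, linear layers, multi-head self-attention with a class token, layer
normalization — together with manual backpropagation and momentum SGD.
Everything is deterministic given a seeded ``numpy.random.Generator`` and a
single CPU thread; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "sigmoid",
    "softmax",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "SmallConvNet",
    "MultiHeadSelfAttention",
    "LayerNorm",
    "SlideFusionNet",
    "SGD",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class: stateless unless it declares ``params``/``grads``."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) for stride-1 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """3x3 stride-1 'same' convolution via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3,
                 dtype=np.float32) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.params = {"W": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x_shape = x.shape
        cols = _im2col(x, self.k, self.pad)
        if train:
            self._cols = cols
        n, _, h, w = x.shape
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.grads["W"][...] = self._cols.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        dcols = g @ self.params["W"].T
        return _col2im(dcols, self._x_shape, self.k, self.pad)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h // 2, w // 2, 4))
        self._idx = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(d, self._idx[..., None], grad[..., None], axis=-1)
        return (d.reshape(n, c, h // 2, w // 2, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, h, w))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._x_shape).copy()


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        w = rng.normal(0.0, math.sqrt(2.0 / din), size=(din, dout))
        self.params = {"W": w.astype(dtype), "b": np.zeros(dout, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Sequential:
    def __init__(self, layers: Iterable[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class _StatefulNet:
    """Flat parameter-dict view shared by all trainable nets."""

    def _layers_with_params(self) -> list[tuple[str, Layer]]:
        raise NotImplementedError

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v.copy()
                for name, layer in self._layers_with_params()
                for k, v in layer.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._layers_with_params():
            for k in layer.params:
                layer.params[k][...] = state[f"{name}.{k}"]

    def param_items(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return [(f"{name}.{k}", layer.params[k], layer.grads[k])
                for name, layer in self._layers_with_params()
                for k in layer.params]

    def param_refs(self) -> dict[str, np.ndarray]:
        """Live (non-copy) views of the parameters, keyed by flat name."""
        return {name: p for name, p, _ in self.param_items()}


class SmallConvNet(_StatefulNet):
    """3-block convolutional tile scorer.

    Input is a (N, 3, side, side) float image batch in [0, 1]; each block is
    conv3x3 -> ReLU -> maxpool2.  A global average pool yields the feature
    vector of dimension ``widths[-1]`` and a linear head maps it to one
    logit whose sigmoid is the tile's typicality.
    """

    def __init__(self, rng: np.random.Generator, in_side: int = 32,
                 widths: tuple[int, ...] = (16, 32, 32), dtype=np.float32) -> None:
        if in_side % (2 ** len(widths)) != 0:
            raise ValueError("in_side must be divisible by 2**n_blocks")
        self.in_side = in_side
        self.widths = tuple(widths)
        self.feature_dim = widths[-1]
        layers: list[Layer] = []
        cin = 3
        for w in widths:
            layers += [Conv2d(cin, w, rng, dtype=dtype), ReLU(), MaxPool2()]
            cin = w
        layers.append(GlobalAvgPool())
        self.trunk = Sequential(layers)
        self.head = Linear(self.feature_dim, 1, rng, dtype=dtype)

    def _layers_with_params(self) -> list[tuple[str, Layer]]:
        out = [(f"trunk{i}", l) for i, l in enumerate(self.trunk.layers) if l.params]
        out.append(("head", self.head))
        return out

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.trunk.forward(x, train=train)

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.features(x, train=train), train=train)[:, 0]

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        grad = self.head.backward(dlogits[:, None])
        self.trunk.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, train=False))

    def clone(self) -> "SmallConvNet":
        other = SmallConvNet(np.random.default_rng(0), self.in_side, self.widths,
                             dtype=self.head.params["W"].dtype)
        other.set_state(self.get_state())
        return other


class LayerNorm(Layer):
    def __init__(self, d: int, dtype=np.float32, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(d, dtype=dtype), "beta": np.zeros(d, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = grad.shape[-1]
        self.grads["gamma"][...] = (grad * self._xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.grads["beta"][...] = grad.sum(axis=tuple(range(grad.ndim - 1)))
        gh = grad * self.params["gamma"]
        return (self._inv / d) * (
            d * gh - gh.sum(axis=-1, keepdims=True)
            - self._xhat * (gh * self._xhat).sum(axis=-1, keepdims=True)
        )


class MultiHeadSelfAttention(Layer):
    """Single multi-head self-attention block over one (L, d) sequence.

    No positional encoding is used, so the output of any query row is
    invariant to permutations of the other rows.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if d % n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        self.d, self.h = d, n_heads
        self.dh = d // n_heads
        s = math.sqrt(1.0 / d)
        self.params = {
            name: rng.normal(0.0, s, size=(d, d)).astype(dtype)
            for name in ("Wq", "Wk", "Wv", "Wo")
        }
        for name in ("bq", "bk", "bv", "bo"):
            self.params[name] = np.zeros(d, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _split(self, x: np.ndarray) -> np.ndarray:
        L = x.shape[0]
        return x.reshape(L, self.h, self.dh).transpose(1, 0, 2)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        h, L, dh = x.shape
        return x.transpose(1, 0, 2).reshape(L, h * dh)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.params
        self._x = x
        self._Q = self._split(x @ p["Wq"] + p["bq"])
        self._K = self._split(x @ p["Wk"] + p["bk"])
        self._V = self._split(x @ p["Wv"] + p["bv"])
        scale = 1.0 / math.sqrt(self.dh)
        self._A = softmax(self._Q @ self._K.transpose(0, 2, 1) * scale, axis=-1)
        self._O = self._merge(self._A @ self._V)
        return self._O @ p["Wo"] + p["bo"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p, g = self.params, self.grads
        g["Wo"][...] = self._O.T @ grad
        g["bo"][...] = grad.sum(axis=0)
        dO = self._split(grad @ p["Wo"].T)
        dA = dO @ self._V.transpose(0, 2, 1)
        dV = self._A.transpose(0, 2, 1) @ dO
        dS = self._A * (dA - (dA * self._A).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(self.dh)
        dQ = dS @ self._K * scale
        dK = dS.transpose(0, 2, 1) @ self._Q * scale
        dQf, dKf, dVf = (self._merge(t) for t in (dQ, dK, dV))
        x = self._x
        g["Wq"][...] = x.T @ dQf
        g["bq"][...] = dQf.sum(axis=0)
        g["Wk"][...] = x.T @ dKf
        g["bk"][...] = dKf.sum(axis=0)
        g["Wv"][...] = x.T @ dVf
        g["bv"][...] = dVf.sum(axis=0)
        return dQf @ p["Wq"].T + dKf @ p["Wk"].T + dVf @ p["Wv"].T


class _ClassToken(Layer):
    def __init__(self, d: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.params = {"token": rng.normal(0.0, 0.02, size=(d,)).astype(dtype)}
        self.grads = {"token": np.zeros(d, dtype=dtype)}


class SlideFusionNet(_StatefulNet):
    """Attention fusion of tile features plus an MLP slide classifier.

    A learnable class token is prepended to the (n_tiles, d) feature
    sequence; one multi-head self-attention block followed by layer
    normalization produces the fused slide token (its first output row).
    The token is concatenated with an 11-value statistical summary of the
    tile probabilities and classified by a two-hidden-layer MLP.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 n_stats: int = 11, hidden: tuple[int, int] = (256, 64),
                 dtype=np.float32) -> None:
        self.d, self.n_stats = d, n_stats
        self.cls = _ClassToken(d, rng, dtype=dtype)
        self.msa = MultiHeadSelfAttention(d, n_heads, rng, dtype=dtype)
        self.ln = LayerNorm(d, dtype=dtype)
        self.fc1 = Linear(d + n_stats, hidden[0], rng, dtype=dtype)
        self.act1 = ReLU()
        self.fc2 = Linear(hidden[0], hidden[1], rng, dtype=dtype)
        self.act2 = ReLU()
        self.fc3 = Linear(hidden[1], 2, rng, dtype=dtype)

    def _layers_with_params(self) -> list[tuple[str, Layer]]:
        return [("cls", self.cls), ("msa", self.msa), ("ln", self.ln),
                ("fc1", self.fc1), ("fc2", self.fc2), ("fc3", self.fc3)]

    def fuse(self, features: np.ndarray, train: bool = True) -> np.ndarray:
        """(n_tiles, d) -> fused slide token of length d."""
        x = np.vstack([self.cls.params["token"][None, :], features])
        y = self.ln.forward(self.msa.forward(x, train=train), train=train)
        self._seq_len = x.shape[0]
        return y[0]

    def backward_fuse(self, dtoken: np.ndarray) -> np.ndarray:
        dy = np.zeros((self._seq_len, self.d), dtype=dtoken.dtype)
        dy[0] = dtoken
        dx = self.msa.backward(self.ln.backward(dy))
        self.cls.grads["token"][...] = dx[0]
        return dx[1:]

    def head_logits(self, emb: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.act1.forward(self.fc1.forward(emb, train=train), train=train)
        h = self.act2.forward(self.fc2.forward(h, train=train), train=train)
        return self.fc3.forward(h, train=train)

    def backward_head(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.fc3.backward(dlogits)
        g = self.fc2.backward(self.act2.backward(g))
        return self.fc1.backward(self.act1.backward(g))

    def forward_slide(self, features: np.ndarray, stats: np.ndarray,
                      train: bool = True) -> np.ndarray:
        token = self.fuse(features, train=train)
        emb = np.concatenate([token, stats]).astype(token.dtype)
        return self.head_logits(emb[None, :], train=train)[0]

    def backward_slide(self, dlogits: np.ndarray) -> None:
        demb = self.backward_head(dlogits[None, :])[0]
        self.backward_fuse(demb[: self.d])


class SGD:
    """Momentum SGD over a stateful net's flat parameter view."""

    def __init__(self, net: _StatefulNet, momentum: float = 0.9) -> None:
        self.net = net
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(p) for name, p, _ in net.param_items()}

    def step(self, lr: float) -> None:
        for name, p, g in self.net.param_items():
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * g
            p += v

    def zero_grad(self) -> None:
        for _, _, g in self.net.param_items():
            g[...] = 0.0
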