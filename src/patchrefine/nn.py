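"""Compact numpy CNN engine.

Compiles a :class:`~patchrefine.models.ModelGraph` into a trainable network:
stride-1 'same' convolutions via im2col + BLAS matmul, 2x2 max pooling,
non-overlapping average pooling, batch norm, PReLU, fully connected layers and
channel concatenation, trained with SGD + momentum on the softmax
cross-entropy loss.  Batch normalization followed by PReLU is inserted after
every weighted layer except the output head.

Bitwise reproducibility across BLAS builds is not promised; for a fixed seed
the initialization and batch order are fixed, which is what the package's
determinism contract requires.
"""

from __future__ import annotations

import numpy as np

from .models import ModelGraph, WEIGHTED_KINDS

_EPS = 1e-5


class Param:
    __slots__ = ("value", "grad", "vel")

    def __init__(self, value):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


class _Node:
    inputs: list

    def params(self):
        return []

    def forward(self, xs, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class _Input(_Node):
    def __init__(self):
        self.inputs = []

    def forward(self, xs, train):
        return xs[0]

    def backward(self, dout):
        return []


class _Conv(_Node):
    """3x3 (or 1x1) stride-1 convolution, 'same' zero padding, any dilation."""

    def __init__(self, rng, cin, cout, kernel, dilation):
        self.k, self.d = kernel, dilation
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, (cout, cin * kernel * kernel)))
        self.b = Param(np.zeros(cout))
        self.inputs = []

    def params(self):
        return [self.W, self.b]

    def forward(self, xs, train):
        X = xs[0]
        N, C, H, W = X.shape
        k, d = self.k, self.d
        if k == 1:
            cols = X.reshape(N, C, H * W)
        else:
            p = d * (k - 1) // 2
            Xp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
            Xp[:, :, p : p + H, p : p + W] = X
            cols = np.empty((N, C, k * k, H, W), dtype=np.float32)
            for a in range(k):
                for b in range(k):
                    cols[:, :, a * k + b] = Xp[:, :, a * d : a * d + H, b * d : b * d + W]
            cols = cols.reshape(N, C * k * k, H * W)
        # batched GEMM keeps the (N, channels, pixels) layout end to end
        out = np.matmul(self.W.value, cols)
        out += self.b.value[None, :, None]
        self._cache = (cols, (N, C, H, W)) if train else None
        return out.reshape(N, self.W.value.shape[0], H, W)

    def backward(self, dout):
        cols, (N, C, H, W) = self._cache
        k, d = self.k, self.d
        cout = self.W.value.shape[0]
        df = dout.reshape(N, cout, H * W)
        self.W.grad += np.tensordot(df, cols, axes=([0, 2], [0, 2]))
        self.b.grad += df.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, df)  # (N, C*k*k, H*W)
        if k == 1:
            return [dcols.reshape(N, C, H, W)]
        p = d * (k - 1) // 2
        dcols = dcols.reshape(N, C, k * k, H, W)
        dXp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                dXp[:, :, a * d : a * d + H, b * d : b * d + W] += dcols[:, :, a * k + b]
        return [dXp[:, :, p : p + H, p : p + W]]


class _MaxPool2(_Node):
    def __init__(self):
        self.inputs = []

    def forward(self, xs, train):
        X = xs[0]
        N, C, H, W = X.shape
        if not train:  # max of the four strided views, no copies
            out = np.maximum(X[:, :, ::2, ::2], X[:, :, ::2, 1::2])
            np.maximum(out, X[:, :, 1::2, ::2], out=out)
            np.maximum(out, X[:, :, 1::2, 1::2], out=out)
            return out
        Xr = (
            X.reshape(N, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H // 2, W // 2, 4)
        )
        idx = Xr.argmax(axis=-1)
        out = np.take_along_axis(Xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (N, C, H, W))
        return out

    def backward(self, dout):
        idx, (N, C, H, W) = self._cache
        dXr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dXr, idx[..., None], dout[..., None], axis=-1)
        dX = (
            dXr.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        return [dX]


class _AvgPool(_Node):
    def __init__(self, kernel):
        self.k = kernel
        self.inputs = []

    def forward(self, xs, train):
        X = xs[0]
        N, C, H, W = X.shape
        k = self.k
        self._shape = (N, C, H, W)
        return X.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(self, dout):
        N, C, H, W = self._shape
        k = self.k
        dX = np.repeat(np.repeat(dout, k, axis=2), k, axis=3) / (k * k)
        return [dX.astype(np.float32)]


class _GlobalAvgPool(_Node):
    def __init__(self):
        self.inputs = []

    def forward(self, xs, train):
        X = xs[0]
        self._shape = X.shape
        return X.mean(axis=(2, 3), keepdims=True)

    def backward(self, dout):
        N, C, H, W = self._shape
        return [np.broadcast_to(dout / (H * W), self._shape).astype(np.float32)]


class _FC(_Node):
    def __init__(self, rng, cin, cout):
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, (cin, cout)))
        self.b = Param(np.zeros(cout))
        self.inputs = []

    def params(self):
        return [self.W, self.b]

    def forward(self, xs, train):
        X = xs[0]
        self._in_shape = X.shape
        Xf = X.reshape(X.shape[0], -1)
        self._cache = Xf if train else None
        return Xf @ self.W.value + self.b.value

    def backward(self, dout):
        Xf = self._cache
        self.W.grad += Xf.T @ dout
        self.b.grad += dout.sum(axis=0)
        return [(dout @ self.W.value.T).reshape(self._in_shape)]


class _Concat(_Node):
    def __init__(self):
        self.inputs = []

    def forward(self, xs, train):
        self._splits = np.cumsum([x.shape[1] for x in xs])[:-1]
        return np.concatenate(xs, axis=1)

    def backward(self, dout):
        return [np.ascontiguousarray(d) for d in np.split(dout, self._splits, axis=1)]


class _BatchNorm(_Node):
    """Per-channel batch norm; works on (N, C) and (N, C, H, W)."""

    def __init__(self, c, momentum=0.9):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.inputs = []

    def params(self):
        return [self.gamma, self.beta]

    def _chan(self, X):
        return (1, -1) if X.ndim == 2 else (1, -1, 1, 1)

    def forward(self, xs, train):
        X = xs[0]
        sh = self._chan(X)
        axes = (0,) if X.ndim == 2 else (0, 2, 3)
        if train:
            mu = X.mean(axis=axes)
            var = X.var(axis=axes)
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu
            self.run_var = m * self.run_var + (1 - m) * var
        else:  # eval: single fused affine pass from running stats
            scale = self.gamma.value / np.sqrt(self.run_var + _EPS)
            shift = self.beta.value - scale * self.run_mean
            return X * scale.reshape(sh) + shift.reshape(sh)
        std = np.sqrt(var + _EPS)
        xhat = (X - mu.reshape(sh)) / std.reshape(sh)
        self._cache = (xhat, std, axes, sh)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dout):
        xhat, std, axes, sh = self._cache
        m = float(np.prod([dout.shape[a] for a in axes]))
        dbeta = dout.sum(axis=axes)
        dgamma = (dout * xhat).sum(axis=axes)
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        g_over_std = (self.gamma.value / std).reshape(sh)
        dX = g_over_std * (
            dout - dbeta.reshape(sh) / m - xhat * dgamma.reshape(sh) / m
        )
        return [dX.astype(np.float32)]


class _PReLU(_Node):
    def __init__(self, c):
        self.a = Param(np.full(c, 0.25))
        self.inputs = []

    def params(self):
        return [self.a]

    def _chan(self, X):
        return (1, -1) if X.ndim == 2 else (1, -1, 1, 1)

    def forward(self, xs, train):
        X = xs[0]
        sh = self._chan(X)
        if not train:
            return np.maximum(X, 0.0) + self.a.value.reshape(sh) * np.minimum(X, 0.0)
        pos = X > 0
        self._cache = (X, pos, sh)
        return np.where(pos, X, self.a.value.reshape(sh) * X)

    def backward(self, dout):
        X, pos, sh = self._cache
        axes = (0,) if X.ndim == 2 else (0, 2, 3)
        self.a.grad += np.where(pos, 0.0, dout * X).sum(axis=axes)
        return [np.where(pos, dout, self.a.value.reshape(sh) * dout).astype(np.float32)]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NumpyNet:
    """A ModelGraph compiled to trainable numpy ops."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        self.graph = graph
        rng = np.random.default_rng(seed)
        shapes = graph.shapes()
        weighted = [i for i, s in enumerate(graph.layers) if s.kind in WEIGHTED_KINDS]
        head = weighted[-1] if weighted else -1

        self.nodes: list[_Node] = []
        gmap = {}  # graph idx -> runtime output idx

        def push(node, inputs):
            node.inputs = inputs
            self.nodes.append(node)
            return len(self.nodes) - 1

        for gi, spec in enumerate(graph.layers):
            kind = spec.kind
            ins = [gmap[j] for j in spec.inputs]
            if kind == "input":
                gmap[gi] = push(_Input(), [])
                continue
            if kind in ("conv", "atrous_conv", "nin_conv1x1"):
                cin = graph.in_channels(gi, shapes)
                ri = push(_Conv(rng, cin, spec.out_channels, spec.kernel, spec.dilation), ins)
            elif kind == "max_pool":
                ri = push(_MaxPool2(), ins)
            elif kind == "avg_pool":
                ri = push(_AvgPool(spec.kernel), ins)
            elif kind == "global_avg_pool":
                ri = push(_GlobalAvgPool(), ins)
            elif kind == "fully_connected":
                cin = graph.in_channels(gi, shapes)
                ri = push(_FC(rng, cin, spec.out_channels), ins)
            elif kind == "concat":
                ri = push(_Concat(), ins)
            elif kind == "batch_norm":
                ri = push(_BatchNorm(shapes[gi][2]), ins)
            elif kind == "activation":
                ri = push(_PReLU(shapes[gi][2]), ins)
            else:  # pragma: no cover
                raise ValueError(f"cannot compile layer kind {kind}")
            if kind in WEIGHTED_KINDS and gi != head:
                ri = push(_BatchNorm(spec.out_channels), [ri])
                ri = push(_PReLU(spec.out_channels), [ri])
            gmap[gi] = ri

        self.n_classes = graph.layers[head].out_channels if head >= 0 else None

    # -- execution -------------------------------------------------------

    def params(self):
        out = []
        for n in self.nodes:
            out.extend(n.params())
        return out

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        acts = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            xs = [acts[j] for j in node.inputs] if node.inputs else [X]
            acts[i] = node.forward(xs, train)
        if train:
            self._acts_len = len(acts)
        return acts[-1]

    def backward(self, dscores: np.ndarray) -> None:
        grads = [None] * len(self.nodes)
        grads[-1] = dscores.astype(np.float32)
        for i in range(len(self.nodes) - 1, -1, -1):
            node = self.nodes[i]
            if grads[i] is None or not node.inputs:
                continue
            dins = node.backward(grads[i])
            for j, d in zip(node.inputs, dins):
                grads[j] = d if grads[j] is None else grads[j] + d

    def train_step(self, X, y, lr, momentum=0.9, weight_decay=0.0) -> float:
        """One SGD step on a mini-batch; returns the batch softmax loss."""
        for p in self.params():
            p.grad[...] = 0.0
        scores = self.forward(X, train=True)
        probs = softmax(scores)
        n = X.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        d = probs
        d[np.arange(n), y] -= 1.0
        self.backward(d / n)
        for p in self.params():
            g = p.grad
            if weight_decay:
                g = g + weight_decay * p.value
            p.vel[...] = momentum * p.vel - lr * g
            p.value += p.vel
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = np.empty((X.shape[0], self.n_classes), dtype=np.float32)
        for i in range(0, X.shape[0], batch_size):
            out[i : i + batch_size] = softmax(self.forward(X[i : i + batch_size]))
        return out
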