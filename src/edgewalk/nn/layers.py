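"""Minimal NumPy neural-network layers with manual backpropagation.

Layout is NCHW throughout. Every layer caches what its backward pass
needs during ``forward`` and releases it on ``backward``; calling
``backward`` twice without an intervening ``forward`` is an error.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def _buffers(self) -> list[np.ndarray]:
        out = []
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for i, b in enumerate(self._buffers()):
            state[f"b{i}"] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffers()
        n_expected = len(params) + len(buffers)
        n_given = len([k for k in state if k.startswith(("p", "b"))])
        if n_given != n_expected:
            raise ValueError(
                f"state has {n_given} arrays, module expects {n_expected}"
            )
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {i}: checkpoint shape {arr.shape} != model shape {p.data.shape}"
                )
            p.data[...] = arr
        for i, b in enumerate(buffers):
            b[...] = state[f"b{i}"]

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Param(_he_init(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.k = k
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        # windows: (n, c, ho, wo, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (cols, xp.shape, (n, c, h, w, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, c, h, w, ho, wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.padding
        cout = dy.shape[1]
        dy_cols = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        self.weight.grad += (dy_cols.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy_cols.sum(axis=0)
        wmat = self.weight.data.reshape(cout, -1)
        dcols = (dy_cols @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dy * g * inv_std[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        # standard batchnorm backward over the (N, H, W) reduction axes
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv_std[None, :, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        else:
            xp = x
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, ho, wo, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, xp.shape, (n, c, h, w, ho, wo))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xp_shape, (n, c, h, w, ho, wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.padding
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        ki, kj = np.divmod(idx, k)
        rows = (np.arange(ho) * s)[None, None, :, None] + ki
        cols = (np.arange(wo) * s)[None, None, None, :] + kj
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dxp, (nn_[:, :, None, None], cc[:, :, None, None], rows, cols), dy)
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Param(np.zeros(out_features))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        x = self._x
        self._x = None
        return dy @ self.weight.data


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearResize(Module):
    """Resize (N, C, H, W) to a fixed (out_h, out_w) via separable linear maps."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h = out_h
        self.out_w = out_w
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._in_hw = None

    def _get(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(h, self.out_h), _interp_matrix(w, self.out_w))
        return self._mats[key]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        self._in_hw = (h, w)
        a, b = self._get(h, w)
        return a @ x @ b.T

    def backward(self, dy: np.ndarray) -> np.ndarray:
        a, b = self._get(*self._in_hw)
        return a.T @ dy @ b


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.items = list(modules)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for m in self.items:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.items):
            dy = m.backward(dy)
        return dy


def conv_bn_relu(
    cin: int,
    cout: int,
    k: int,
    stride: int = 1,
    rng: np.random.Generator | None = None,
) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=k // 2, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class BasicBlock(Module):
    """Two 3x3 convolutions with an identity or projection shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.down: Sequential | None = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(cout)
            )
        else:
            self.down = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        sc = self.down.forward(x, train) if self.down is not None else x
        return self.relu2.forward(out + sc, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dy)
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(dy)))))
        d_sc = self.down.backward(dy) if self.down is not None else dy
        return d_main + d_sc


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with expansion 4."""

    expansion = 4

    def __init__(self, cin: int, planes: int, stride: int = 1, rng: np.random.Generator | None = None):
        cout = planes * self.expansion
        self.conv1 = Conv2d(cin, planes, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(planes, planes, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(planes, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        self.relu3 = ReLU()
        if stride != 1 or cin != cout:
            self.down: Sequential | None = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(cout)
            )
        else:
            self.down = None
        self.out_channels = cout

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, train), train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        sc = self.down.forward(x, train) if self.down is not None else x
        return self.relu3.forward(out + sc, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu3.backward(dy)
        d = self.conv3.backward(self.bn3.backward(dy))
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(d)))
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))
        d_sc = self.down.backward(dy) if self.down is not None else dy
        return d_main + d_sc
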