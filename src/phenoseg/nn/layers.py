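"""Minimal CPU neural-network layers with explicit forward/backward passes.

All tensors are ``numpy.float32`` arrays in NCHW layout. Each layer caches
what its backward pass needs during ``forward`` and releases it after
``backward``. Composite networks (U-Net and friends) wire layers together
manually and are responsible for summing gradients at skip connections.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest2x",
    "GlobalAvgPool",
    "Linear",
    "SEBlock",
    "ConvBNReLU",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        mods.extend(v.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """Flat list of all learnable + running-statistic arrays, in a
        deterministic traversal order, for checkpointing."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(own)}"
            )
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError(
                    f"shape mismatch loading state: {dst.shape} vs {np.shape(src)}"
                )
            dst[...] = src

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _im2col(xp: np.ndarray, k: int, stride: int, dilation: int,
            h_out: int, w_out: int) -> np.ndarray:
    """xp is the already-padded input (N, C, Hp, Wp)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c * k * k, h_out * w_out), dtype=np.float32)
    idx = 0
    for ki in range(k):
        for kj in range(k):
            i0 = ki * dilation
            j0 = kj * dilation
            patch = xp[:, :, i0:i0 + stride * h_out:stride,
                       j0:j0 + stride * w_out:stride]
            cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, -1)
            idx += 1
    return cols


class Conv2d(Module):
    """2-D convolution via im2col + GEMM; supports stride, padding, dilation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *,
                 stride: int = 1, padding: int | None = None,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding, self.dilation = padding, dilation
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.weight = Parameter(
            rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)), "conv.weight")
        self.bias = Parameter(np.zeros(out_ch), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k_eff = self.dilation * (self.kernel - 1) + 1
        h_out = (h + 2 * self.padding - k_eff) // self.stride + 1
        w_out = (w + 2 * self.padding - k_eff) // self.stride + 1
        return h_out, w_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h_out, w_out = self._out_hw(h, w)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.kernel, self.stride, self.dilation, h_out, w_out)
        w2d = self._weight_2d()
        out = np.matmul(w2d, cols)
        if self.bias is not None:
            out += self.bias.data[None, :, None]
        if self.training:
            self._cache = (x.shape, xp if p else x, cols.shape, cols)
        else:
            self._cache = None
        return out.reshape(n, self.out_ch, h_out, w_out)

    def _weight_2d(self) -> np.ndarray:
        # im2col stacks patches as (ki, kj, channel); match that ordering
        return (self.weight.data.transpose(2, 3, 1, 0)
                .reshape(-1, self.out_ch).T.copy())

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xp, cols_shape, cols = self._cache
        self._cache = None
        n, _, h, w = x_shape
        h_out, w_out = dy.shape[2:]
        dy2 = dy.reshape(n, self.out_ch, -1)
        # dW: sum over batch of dy @ cols^T, back to (kij*c, out) ordering
        dw2d = np.einsum("nol,ncl->oc", dy2, cols, optimize=True)
        dw = (dw2d.T.reshape(self.kernel, self.kernel, self.in_ch, self.out_ch)
              .transpose(3, 2, 0, 1))
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=(0, 2))
        # col2im: one GEMM per kernel offset keeps outputs contiguous
        w2dt = self._weight_2d().T
        dxp = np.zeros_like(xp)
        c = self.in_ch
        idx = 0
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                i0 = ki * self.dilation
                j0 = kj * self.dilation
                block = np.matmul(w2dt[idx * c:(idx + 1) * c], dy2)
                dxp[:, :, i0:i0 + self.stride * h_out:self.stride,
                    j0:j0 + self.stride * w_out:self.stride] += (
                    block.reshape(n, c, h_out, w_out))
                idx += 1
        p = self.padding
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, ch: int, *, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch), "bn.gamma")
        self.beta = Parameter(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (dxhat - s1[None, :, None, None] / m
              - xhat * s2[None, :, None, None] / m)
        return dx * inv_std[None, :, None, None]


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if self.training:
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dy * mask


class Sigmoid(Module):
    def __init__(self) -> None:
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if self.training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return dy * y * (1.0 - y)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2. Spatial dims must be even."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        s00 = x[:, :, 0::2, 0::2]
        s01 = x[:, :, 0::2, 1::2]
        s10 = x[:, :, 1::2, 0::2]
        s11 = x[:, :, 1::2, 1::2]
        y = np.maximum(np.maximum(s00, s01), np.maximum(s10, s11))
        if self.training:
            self._cache = (x.shape, (s00, s01, s10, s11), y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, slices, y = self._cache
        self._cache = None
        dx = np.zeros(shape, dtype=np.float32)
        remaining = dy
        # route each gradient to the first window position attaining the max
        for (oi, oj), s in zip(((0, 0), (0, 1), (1, 0), (1, 1)), slices):
            hit = s == y
            dx[:, :, oi::2, oj::2] = np.where(hit, remaining, 0.0)
            remaining = np.where(hit, 0.0, remaining)
        return dx


class UpsampleNearest2x(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return (dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) channel descriptors."""

    def __init__(self) -> None:
        super().__init__()
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(
            dy[:, :, None, None] / (h * w), dy.shape + (h, w)).astype(np.float32).copy()


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / in_f)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_f, in_f)),
                                "linear.weight")
        self.bias = Parameter(np.zeros(out_f), "linear.bias")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    squeeze: global average pool -> per-channel descriptor;
    excitation: FC(C -> ceil(C/r)) + ReLU + FC(-> C) + sigmoid;
    scale: channel-wise multiply. ``identity_gate=True`` bypasses the gate
    (all weights treated as exactly 1), which reduces the block to identity.
    """

    def __init__(self, ch: int, reduction: int = 16,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if reduction < 1:
            raise ValueError(f"SE reduction ratio must be >= 1, got {reduction}")
        hidden = max(1, math.ceil(ch / reduction))
        self.ch, self.reduction, self.hidden = ch, reduction, hidden
        self.pool = GlobalAvgPool()
        self.fc1 = Linear(ch, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, ch, rng=rng)
        self.sigmoid = Sigmoid()
        self.identity_gate = False
        self._cache: tuple | None = None

    def squeeze(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(2, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.identity_gate:
            return x
        z = self.pool.forward(x)
        s = self.sigmoid.forward(self.fc2.forward(
            self.relu.forward(self.fc1.forward(z))))
        if self.training:
            self._cache = (x, s)
        return x * s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.identity_gate:
            return dy
        x, s = self._cache
        self._cache = None
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        dz = self.fc1.backward(self.relu.backward(
            self.fc2.backward(self.sigmoid.backward(ds))))
        dx += self.pool.backward(dz)
        return dx


class ConvBNReLU(Sequential):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *,
                 stride: int = 1, dilation: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__(
            Conv2d(in_ch, out_ch, kernel, stride=stride, dilation=dilation,
                   padding=padding, bias=False, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
        )
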