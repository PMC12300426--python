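"""Minimal reverse-mode automatic differentiation engine on numpy.

This module provides the tensor/layer/optimizer substrate for the
segmentation network: a :class:`Tensor` with a dynamically built backward
graph, 2-D convolution (im2col), adaptive average pooling, bilinear
upsampling, batch normalization, linear layers, and the AdamW optimizer
with a step-decay learning-rate scheduler.

Only the operations the segmentation model needs are implemented; all
arrays are numpy, float32 by default (float64 is preserved when passed
in, which the finite-difference gradient tests rely on).
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "AdamW",
    "StepLR",
    "no_grad",
    "count_flops",
    "concat",
    "stack",
    "sigmoid",
    "relu",
    "softmax",
    "conv2d",
    "pad2d",
    "adaptive_avg_pool2d",
    "upsample_bilinear2d",
    "upsample_nearest2d",
]

_grad_enabled = True
_flop_counter: list = []  # stack of mutable counters


@contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextmanager
def count_flops():
    """Count multiply–add FLOPs of matmul/conv ops executed in the context.

    Yields a single-element list; element 0 holds the running count.
    """
    counter = [0]
    _flop_counter.append(counter)
    try:
        yield counter
    finally:
        _flop_counter.remove(counter)


def _bump_flops(n: int) -> None:
    for counter in _flop_counter:
        counter[0] += n


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution: keep a reference (never mutated until owned);
        # second: materialize a private sum we may then update in place
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + g
            self._grad_owned = True
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the graph and intermediate gradients as we go; leaves
            # (parameters, inputs) keep their gradients
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None
                node._grad_owned = False

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars at this tensor's dtype (avoids float64 promotion)."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        m = int(np.prod(out_data.shape[:-1])) if out_data.ndim else 1
        _bump_flops(2 * m * self.data.shape[-1] * other.data.shape[-1])

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(self.data.dtype))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        old_shape = self.shape

        def backward(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def expand(self, shape: tuple):
        """Broadcast to `shape` (gradient sums over expanded axes)."""
        out_data = np.broadcast_to(self.data, shape)
        src_shape = self.shape

        def backward(g):
            self._accumulate(_unbroadcast(g, src_shape))

        return Tensor._make(np.ascontiguousarray(out_data), (self,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


# -----------------------------------------------------------------------------
# functional ops
# -----------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    s = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the two trailing axes of a B×C×H×W tensor."""
    if pad == 0:
        return x
    if mode not in ("reflect", "zero"):
        raise ValueError(f"unknown padding mode {mode!r}")
    np_mode = "reflect" if mode == "reflect" else "constant"
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode=np_mode)
    H, W = x.shape[-2], x.shape[-1]

    def backward(g):
        if mode == "zero":
            x._accumulate(g[..., pad:pad + H, pad:pad + W])
            return
        g = g.copy()
        # fold reflected columns back into the body, then rows
        for i in range(1, pad + 1):
            g[..., :, pad + i] += g[..., :, pad - i]
            g[..., :, pad + W - 1 - i] += g[..., :, pad + W - 1 + i]
        for i in range(1, pad + 1):
            g[..., pad + i, :] += g[..., pad - i, :]
            g[..., pad + H - 1 - i, :] += g[..., pad + H - 1 + i, :]
        x._accumulate(g[..., pad:pad + H, pad:pad + W])

    return Tensor._make(out_data, (x,), backward)


def _conv_windows(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Strided B×C×OH×OW×kh×kw window view of a padded B×C×H×W array."""
    eff_h = dilation * (kh - 1) + 1
    eff_w = dilation * (kw - 1) + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (eff_h, eff_w), axis=(2, 3))
    return windows[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | None = None,
    pad_mode: str = "reflect",
) -> Tensor:
    """2-D convolution (cross-correlation) of B×C×H×W with O×C×kh×kw.

    `padding=None` means "same" padding for the given dilation; the border
    is reflect-padded by default so edge responses are not inflated by an
    artificial zero frame.
    """
    O, C, kh, kw = weight.shape
    if x.shape[1] != C:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, kernel {C}")
    if x.shape[-2] < kh or x.shape[-1] < kw:
        raise ValueError(f"input {x.shape[-2:]} smaller than kernel ({kh},{kw})")
    if padding is None:
        padding = dilation * (kh - 1) // 2
    xp = pad2d(x, padding, pad_mode)

    windows = _conv_windows(xp.data, kh, kw, stride, dilation)  # B×C×OH×OW×kh×kw view
    B, OH, OW = x.shape[0], windows.shape[2], windows.shape[3]
    out_data = np.einsum("bchwij,ocij->bohw", windows, weight.data, optimize=True)
    _bump_flops(2 * B * OH * OW * C * kh * kw * O)
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)
    parents = (xp, weight) if bias is None else (xp, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("bohw,bchwij->ocij", g, windows, optimize=True))
        if xp.requires_grad:
            gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
            gx = np.zeros_like(xp.data)
            for a in range(kh):
                for b in range(kw):
                    contrib = (gflat @ weight.data[:, :, a, b]).reshape(
                        B, OH, OW, C).transpose(0, 3, 1, 2)
                    gx[:, :,
                       a * dilation:a * dilation + OH * stride:stride,
                       b * dilation:b * dilation + OW * stride:stride,
                       ] += contrib
            xp._accumulate(gx)

    return Tensor._make(out_data, parents, backward)


def _pool_bins(in_size: int, out_size: int):
    starts = (np.arange(out_size) * in_size) // out_size
    ends = -((-(np.arange(out_size) + 1) * in_size) // out_size)  # ceil
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, output_size) -> Tensor:
    """Average-pool a B×C×H×W tensor to an arbitrary output grid."""
    oh, ow = (output_size, output_size) if isinstance(output_size, int) else output_size
    B, C, H, W = x.shape
    rs, re = _pool_bins(H, oh)
    cs, ce = _pool_bins(W, ow)
    out_data = np.empty((B, C, oh, ow), dtype=x.dtype)
    for i in range(oh):
        for j in range(ow):
            out_data[:, :, i, j] = x.data[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                gx[:, :, rs[i]:re[i], cs[j]:ce[j]] += g[:, :, i:i + 1, j:j + 1] / area
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int) -> Tensor:
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        B, C, H, W = x.shape
        gx = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def _linear_coords(in_size: int, out_size: int):
    # half-pixel-center mapping (align_corners=False convention)
    coords = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    coords = np.clip(coords, 0, in_size - 1)
    lo = np.floor(coords).astype(np.int64)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = (coords - lo).astype(np.float32)
    return lo, hi, frac


def upsample_bilinear2d(x: Tensor, size) -> Tensor:
    """Bilinearly resample a B×C×H×W tensor to `size` (oh, ow)."""
    oh, ow = (size, size) if isinstance(size, int) else size
    B, C, H, W = x.shape
    r0, r1, fr = _linear_coords(H, oh)
    c0, c1, fc = _linear_coords(W, ow)
    fr_ = fr.reshape(1, 1, oh, 1)
    fc_ = fc.reshape(1, 1, 1, ow)
    rows = x.data[:, :, r0, :] * (1 - fr_) + x.data[:, :, r1, :] * fr_
    out_data = rows[:, :, :, c0] * (1 - fc_) + rows[:, :, :, c1] * fc_

    def backward(g):
        grows = np.zeros((B, C, oh, W), dtype=g.dtype)
        np.add.at(grows, (slice(None), slice(None), slice(None), c0), g * (1 - fc_))
        np.add.at(grows, (slice(None), slice(None), slice(None), c1), g * fc_)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)), grows * (1 - fr_))
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), grows * fr_)
        x._accumulate(gx)

    return Tensor._make(out_data.astype(x.dtype), (x,), backward)


# -----------------------------------------------------------------------------
# modules
# -----------------------------------------------------------------------------

def batch_norm(x: Tensor, weight: Tensor, bias: Tensor, *, mean: np.ndarray,
               inv_std: np.ndarray, training: bool) -> Tensor:
    """Fused per-channel normalization x̂·w + b with closed-form gradient.

    ``mean``/``inv_std`` are 1×C×1×1 arrays: batch statistics when
    ``training`` (their dependence on x enters the gradient), running
    statistics otherwise (treated as constants).
    """
    C = x.shape[1]
    xhat = (x.data - mean) * inv_std
    w = weight.data.reshape(1, C, 1, 1)
    out_data = xhat * w + bias.data.reshape(1, C, 1, 1)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * w
            if training:
                mu_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                mu_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(inv_std * (gxhat - mu_g - xhat * mu_gx))
            else:
                x._accumulate(inv_std * gxhat)

    return Tensor._make(out_data, (x, weight, bias), backward)


class Module:
    """Base class tracking parameters, buffers and submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer." + name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        expected = set(params) | {"buffer." + n for n, _ in self.named_buffers()}
        missing = expected - set(state)
        extra = set(state) - expected
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        # buffers are stored flat; walk modules to reassign
        def assign(mod: Module, prefix: str):
            for bname in list(mod._buffers):
                mod.register_buffer(bname, np.asarray(state["buffer." + prefix + bname]).copy())
            for mname, sub in mod._modules.items():
                assign(sub, prefix + mname + ".")

        assign(self, "")


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *, stride: int = 1,
                 dilation: int = 1, bias: bool = True, pad_mode: str = "reflect",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.dilation = dilation
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, pad_mode=self.pad_mode)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            m = x.data.mean(axis=(0, 2, 3), keepdims=True)
            v = x.data.var(axis=(0, 2, 3), keepdims=True)
            rm = (1 - self.momentum) * self.running_mean + self.momentum * m.reshape(C)
            rv = (1 - self.momentum) * self.running_var + self.momentum * v.reshape(C)
            self.register_buffer("running_mean", rm.astype(np.float32))
            self.register_buffer("running_var", rv.astype(np.float32))
        else:
            m = self.running_mean.reshape(1, C, 1, 1)
            v = self.running_var.reshape(1, C, 1, 1)
        inv_std = 1.0 / np.sqrt(v + self.eps)
        return batch_norm(x, self.weight, self.bias,
                          mean=np.asarray(m, dtype=x.dtype),
                          inv_std=np.asarray(inv_std, dtype=x.dtype),
                          training=self.training)


# -----------------------------------------------------------------------------
# optimization
# -----------------------------------------------------------------------------

class AdamW:
    """AdamW: Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class StepLR:
    """Step-decay schedule: lr(e) = base_lr * gamma ** floor(e / step_size)."""

    def __init__(self, optimizer: AdamW, step_size: int = 30, gamma: float = 0.1):
        if not 0 < gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.step_size = step_size
        self.gamma = gamma
        self.epoch = 0
        self._apply()

    def _apply(self) -> None:
        self.optimizer.lr = self.base_lr * self.gamma ** (self.epoch // self.step_size)

    def step(self) -> None:
        """Advance one epoch and update the optimizer's learning rate."""
        self.epoch += 1
        self._apply()

    def get_lr(self) -> float:
        return self.optimizer.lr
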