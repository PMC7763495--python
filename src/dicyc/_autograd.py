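"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the synthesis networks need: broadcasted
arithmetic, reductions, matmul, slicing/concatenation, pointwise
nonlinearities, 2-D (transposed) convolution, reflection/zero padding and
differentiable bilinear grid sampling, plus thin ``Module``/``Adam`` layers on
top.  Arrays are kept in float64 throughout; the networks here are small
enough that precision is worth more than speed.

Conventions follow the common deep-learning layout: images are
``(N, C, H, W)``; sampling grids are ``(N, H, W, 2)`` with the last axis
ordered ``(x, y)`` in normalized ``[-1, 1]`` coordinates and pixel centers at
the interval endpoints (align-corners).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "InstanceNorm2d",
    "Adam",
    "as_tensor",
    "concat",
    "grid_sample",
    "pad2d",
]

_DTYPE = np.float64

# multiply-add tally: when a list is installed here, conv/matmul forwards
# append their MAC counts (one MAC per kernel-element multiply; padding,
# normalization and activations excluded by convention)
_MAC_TALLY = None


class mac_tally:
    """Context manager collecting multiply-add counts of forward passes."""

    def __init__(self):
        self.total = 0

    def __enter__(self):
        global _MAC_TALLY
        self._prev = _MAC_TALLY
        _MAC_TALLY = self
        return self

    def __exit__(self, *exc):
        global _MAC_TALLY
        _MAC_TALLY = self._prev
        return False

    def add(self, n: int):
        self.total += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=_DTYPE))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, self)
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, self)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        if _MAC_TALLY is not None:
            k = self.shape[-1]
            out_elems = int(np.prod(self.shape[:-1] + other.shape[-1:]))
            _MAC_TALLY.add(out_elems * k)
        out = _node(self.data @ other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), self)
        out._backward = (
            lambda g: self._accum(g * out.data) if self.requires_grad else None
        )
        return out

    def log(self):
        out = _node(np.log(self.data), self)
        out._backward = (
            lambda g: self._accum(g / self.data) if self.requires_grad else None
        )
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), self)
        out._backward = (
            lambda g: self._accum(g * 0.5 / out.data) if self.requires_grad else None
        )
        return out

    def tanh(self):
        out = _node(np.tanh(self.data), self)
        out._backward = (
            lambda g: self._accum(g * (1.0 - out.data**2))
            if self.requires_grad
            else None
        )
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), self)
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), self)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        out._backward = bw
        return out

    def abs(self):
        s = np.sign(self.data)
        out = _node(np.abs(self.data), self)
        out._backward = lambda g: self._accum(g * s) if self.requires_grad else None
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = _node(np.clip(self.data, lo, hi), self)
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), self)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), self)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = _node(self.data.transpose(axes), self)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], self)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = live
    out.requires_grad = any(p.requires_grad for p in parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# padding (gather formulation: backward is a scatter-add over the same index)
# ---------------------------------------------------------------------------

def _pad_indices(n: int, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return np.arange(n)
    if mode == "reflect":
        return np.pad(np.arange(n), p, mode="reflect")
    if mode == "replicate":
        return np.pad(np.arange(n), p, mode="edge")
    raise ValueError(f"unsupported pad mode {mode!r}")


def pad2d(x: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the two trailing spatial axes of an (N, C, H, W) tensor."""
    x = as_tensor(x)
    if pad == 0:
        return x
    n, c, h, w = x.shape
    if mode == "zeros":
        data = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_DTYPE)
        data[:, :, pad:-pad, pad:-pad] = x.data
        out = _node(data, x)

        def bw(g):
            if x.requires_grad:
                x._accum(g[:, :, pad:-pad, pad:-pad])

        out._backward = bw
        return out
    iy = _pad_indices(h, pad, mode)
    ix = _pad_indices(w, pad, mode)
    out = _node(x.data[:, :, iy[:, None], ix[None, :]], x)

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (slice(None), slice(None), iy[:, None], ix[None, :]), g)
            x._accum(full)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 2-D convolution (im2col / einsum core shared by forward and both gradients)
# ---------------------------------------------------------------------------

def _patches(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Sliding-window view (N, C, Ho, Wo, kh, kw) of a padded input."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    p = _patches(x, w.shape[2], w.shape[3], stride)
    return np.einsum("nchwij,ocij->nohw", p, w, optimize=True)


def _conv_grad_weight(x, gy, kshape, stride, pad):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    p = _patches(x, kshape[2], kshape[3], stride)
    # crop gy in case the padded input admitted more windows than gy has
    p = p[:, :, : gy.shape[2], : gy.shape[3]]
    return np.einsum("nohw,nchwij->ocij", gy, p, optimize=True)


def _conv_grad_input(gy, w, xshape, stride, pad):
    n, c, h, wdt = xshape
    kh, kw = w.shape[2], w.shape[3]
    # scatter-dilate gy by the stride, then full-correlate with flipped kernel
    hd = (gy.shape[2] - 1) * stride + 1
    wd = (gy.shape[3] - 1) * stride + 1
    dil = np.zeros((n, w.shape[0], hd, wd), dtype=_DTYPE)
    dil[:, :, ::stride, ::stride] = gy
    dil = np.pad(dil, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    wflip = w[:, :, ::-1, ::-1]
    p = _patches(dil, kh, kw, 1)
    gx_full = np.einsum("nohwij,ocij->nchw", p, wflip, optimize=True)
    # remove the original zero padding and pad out to the input size
    gx = np.zeros(xshape, dtype=_DTYPE)
    hs = gx_full.shape[2]
    ws = gx_full.shape[3]
    src = gx_full[:, :, pad : pad + h, pad : pad + wdt]
    gx[:, :, : src.shape[2], : src.shape[3]] = src
    return gx


def conv2d(x: Tensor, w: Tensor, b, stride: int = 1, pad: int = 0) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    y = _conv_forward(x.data, w.data, stride, pad)
    if _MAC_TALLY is not None:
        _MAC_TALLY.add(y.size * w.data[0].size)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[None, :, None, None]
        out = _node(y, x, w, b)
    else:
        out = _node(y, x, w)

    def bw(g):
        if x.requires_grad:
            x._accum(_conv_grad_input(g, w.data, x.shape, stride, pad))
        if w.requires_grad:
            w._accum(_conv_grad_weight(x.data, g, w.shape, stride, pad))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def _convT_forward(x, w, stride, pad, output_pad):
    """Transposed-conv forward: scatter-dilate x, full-correlate flipped w.

    ``w`` has shape (C_in, C_out, kh, kw); output spatial size is
    ``(H-1)*stride - 2*pad + k + output_pad``.
    """
    n, cin, h, wd = x.shape
    kh, kw = w.shape[2], w.shape[3]
    ho = (h - 1) * stride - 2 * pad + kh + output_pad
    wo = (wd - 1) * stride - 2 * pad + kw + output_pad
    hd = (h - 1) * stride + 1
    wdil = (wd - 1) * stride + 1
    dil = np.zeros((n, cin, hd, wdil), dtype=_DTYPE)
    dil[:, :, ::stride, ::stride] = x
    dil = np.pad(dil, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    wflip = w[:, :, ::-1, ::-1]
    p = _patches(dil, kh, kw, 1)
    y_full = np.einsum("nchwij,coij->nohw", p, wflip, optimize=True)
    y = np.zeros((n, w.shape[1], ho, wo), dtype=_DTYPE)
    src = y_full[:, :, pad : pad + ho, pad : pad + wo]
    y[:, :, : src.shape[2], : src.shape[3]] = src
    return y


def _pad_to(a, h, w):
    return np.pad(
        a,
        ((0, 0), (0, 0), (0, max(0, h - a.shape[2])), (0, max(0, w - a.shape[3]))),
    )[:, :, :h, :w]


def conv_transpose2d(
    x: Tensor, w: Tensor, b, stride: int = 2, pad: int = 1, output_pad: int = 1
) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    kh, kw = w.shape[2], w.shape[3]
    y = _convT_forward(x.data, w.data, stride, pad, output_pad)
    if _MAC_TALLY is not None:
        # counted as the equivalent dense conv: Hout*Wout*Cin*Cout*k*k
        _MAC_TALLY.add(y.size * x.shape[1] * kh * kw)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[None, :, None, None]
        out = _node(y, x, w, b)
    else:
        out = _node(y, x, w)

    def bw(g):
        # the adjoint of a transposed conv is the matching strided conv
        need_h = (h - 1) * stride + kh
        need_w = (wd - 1) * stride + kw
        gp = _pad_to(np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad))), need_h, need_w)
        if x.requires_grad:
            pch = _patches(gp, kh, kw, stride)  # (N, Cout, h, wd, kh, kw)
            x._accum(np.einsum("nohwij,coij->nchw", pch, w.data, optimize=True))
        if w.requires_grad:
            pch = _patches(gp, kh, kw, stride)
            w._accum(np.einsum("nchw,nohwij->coij", x.data, pch, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# bilinear grid sampling
# ---------------------------------------------------------------------------

def _grid_to_pixels(grid: np.ndarray, h: int, w: int):
    gx = (grid[..., 0] + 1.0) * 0.5 * (w - 1)
    gy = (grid[..., 1] + 1.0) * 0.5 * (h - 1)
    # snap coordinates within rounding noise of a pixel center onto it, so an
    # identity grid samples bit-exactly despite the normalized round-trip
    for g in (gx, gy):
        r = np.round(g)
        near = np.abs(g - r) < 1e-9
        g[near] = r[near]
    return gx, gy


def _bilinear_core(x: np.ndarray, grid: np.ndarray, padding: str):
    """Shared forward of bilinear sampling; returns output plus caches."""
    n, c, h, w = x.shape
    gx, gy = _grid_to_pixels(grid, h, w)
    if padding == "border":
        gx = np.clip(gx, 0.0, w - 1.0)
        gy = np.clip(gy, 0.0, h - 1.0)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    x1, y1 = x0 + 1, y0 + 1
    fx, fy = gx - x0, gy - y0
    corners = []
    for yy, xx in ((y0, x0), (y0, x1), (y1, x0), (y1, x1)):
        if padding == "zeros":
            valid = (xx >= 0) & (xx <= w - 1) & (yy >= 0) & (yy <= h - 1)
        else:
            valid = np.ones_like(xx, dtype=bool)
        xc = np.clip(xx, 0, w - 1)
        yc = np.clip(yy, 0, h - 1)
        corners.append((yc, xc, valid))
    w00 = (1 - fx) * (1 - fy)
    w01 = fx * (1 - fy)
    w10 = (1 - fx) * fy
    w11 = fx * fy
    weights = (w00, w01, w10, w11)
    ni = np.arange(n)[:, None, None]
    vals = [x[ni, :, yc, xc].transpose(0, 3, 1, 2) * valid[:, None] for yc, xc, valid in corners]
    out = sum(wt[:, None] * v for wt, v in zip(weights, vals))
    cache = (corners, weights, vals, fx, fy, gx, gy)
    return out, cache


def grid_sample_np(x: np.ndarray, grid: np.ndarray, padding: str = "border") -> np.ndarray:
    """Non-differentiable bilinear sampling (NumPy in / NumPy out)."""
    out, _ = _bilinear_core(
        np.asarray(x, dtype=_DTYPE), np.asarray(grid, dtype=_DTYPE), padding
    )
    return out


def grid_sample(x: Tensor, grid: Tensor, padding: str = "border") -> Tensor:
    """Differentiable bilinear sampling of ``x`` (N,C,H,W) at ``grid`` (N,H,W,2)."""
    x, grid = as_tensor(x), as_tensor(grid)
    n, c, h, w = x.shape
    out_data, cache = _bilinear_core(x.data, grid.data, padding)
    out = _node(out_data, x, grid)
    corners, weights, vals, fx, fy, gx, gy = cache

    def bw(g):
        ni = np.arange(n)[:, None, None]
        if x.requires_grad:
            gx_acc = np.zeros_like(x.data)
            for (yc, xc, valid), wt in zip(corners, weights):
                contrib = (g * wt[:, None] * valid[:, None]).transpose(0, 2, 3, 1)
                np.add.at(gx_acc, (ni, slice(None), yc, xc), contrib)
            x._accum(gx_acc)
        if grid.requires_grad:
            v00, v01, v10, v11 = vals
            # d out / d gx and / d gy per pixel, summed over channels
            dfx = ((v01 - v00) * (1 - fy)[:, None] + (v11 - v10) * fy[:, None])
            dfy = ((v10 - v00) * (1 - fx)[:, None] + (v11 - v01) * fx[:, None])
            ggx = (g * dfx).sum(axis=1) * 0.5 * (w - 1)
            ggy = (g * dfy).sum(axis=1) * 0.5 * (h - 1)
            if padding == "border":
                ggx *= (gx > 0) & (gx < w - 1)
                ggy *= (gy > 0) & (gy < h - 1)
            grid._accum(np.stack([ggx, ggy], axis=-1))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=_DTYPE)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init_conv(rng: np.random.Generator, shape, gain: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, gain, size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, rng=None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        w = np.zeros((cout, cin, k, k)) if zero_init else _init_conv(rng, (cout, cin, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, stride=2, pad=1, output_pad=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_init_conv(rng, (cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.pad, self.output_pad = stride, pad, output_pad

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad, self.output_pad)


class Linear(Module):
    def __init__(self, cin, cout, rng=None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        w = np.zeros((cin, cout)) if zero_init else rng.normal(0.0, 0.02, size=(cin, cout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x):
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization without learned affine."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        return centred / (var + self.eps).sqrt()


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "lr": self.lr,
        }

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
        self.lr = state["lr"]
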