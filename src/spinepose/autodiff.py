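"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine covering exactly the operations the localization
network needs: broadcast arithmetic, matmul, stride-1 "same" convolutions in
2D/3D (odd kernels), average pooling, nearest and linear-interpolation
upsampling, bilinear/trilinear sampling at fixed coordinates, spatial
softmax, pointwise nonlinearities and reductions.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which runs a topological sort of the recorded graph. Arrays keep whatever
float dtype they are built with (float32 for training, float64 in gradient
checks).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "grid_sample2d", "sample_at_points"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises g is a freshly allocated array no other node
        # aliases, so it can be adopted without copying
        if self.grad is None:
            self.grad = g if own and g.dtype == self.data.dtype else g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def _wrap(self, other) -> "Tensor":
        # scalars/arrays adopt this tensor's dtype so float32 graphs stay float32
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out = self._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(-out.grad, own=True)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape), own=True)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape), own=True
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        assert np.isscalar(exponent)
        out = self._make(self.data**exponent, (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1), own=True)

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.shape), own=True)
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape), own=True)

        out._backward = backward
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = self._make(self.data[key], (self,), None)

        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key)
        )

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                if basic:
                    g[key] += out.grad
                else:
                    np.add.at(g, key, out.grad)
                self._accum(g, own=True)

        out._backward = backward
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out = self._make(np.exp(self.data), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data, own=True)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data, own=True)

        out._backward = backward
        return out

    def abs(self) -> "Tensor":
        out = self._make(np.abs(self.data), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data), own=True)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        from scipy.special import expit  # overflow-safe logistic

        out = self._make(expit(self.data), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data), own=True)

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + e^x)
        d = np.logaddexp(0.0, self.data)
        out = self._make(d, (self,), None)

        def backward():
            from scipy.special import expit

            if self.requires_grad:
                self._accum(out.grad * expit(self.data), own=True)

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.1) -> "Tensor":
        from . import _kernels

        out = self._make(_kernels.leaky_forward(np.ascontiguousarray(self.data), slope),
                         (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(_kernels.leaky_backward(self.data, slope, out.grad), own=True)

        out._backward = backward
        return out

    def clip_min(self, lo: float) -> "Tensor":
        mask = (self.data >= lo).astype(self.dtype)
        out = self._make(np.maximum(self.data, lo), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask, own=True)

        out._backward = backward
        return out

    def softmax_lastaxis(self) -> "Tensor":
        """Softmax over the last axis, stabilized by max subtraction."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        out = self._make(p, (self,), None)

        def backward():
            if self.requires_grad:
                g = out.grad
                dot = (g * p).sum(axis=-1, keepdims=True)
                self._accum(p * (g - dot), own=True)

        out._backward = backward
        return out

    # -- convolutions ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Stride-1 'same' 2D convolution (cross-correlation), odd kernels.

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); returns (N, O, H, W).
        """
        return _conv(self, weight, bias, ndim=2)

    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Stride-1 'same' 3D convolution; ``self``: (N, C, D, H, W)."""
        return _conv(self, weight, bias, ndim=3)

    # -- pooling / resampling -------------------------------------------
    def avg_pool(self, factor: int) -> "Tensor":
        """Non-overlapping average pooling of all trailing spatial axes.

        Works for (N, C, H, W) and (N, C, D, H, W); every spatial dim must be
        divisible by ``factor``.
        """
        sp = self.shape[2:]
        if any(s % factor for s in sp):
            raise ValueError(f"spatial dims {sp} not divisible by pool factor {factor}")
        newshape = self.shape[:2]
        for s in sp:
            newshape += (s // factor, factor)
        axes = tuple(range(3, 3 + 2 * len(sp), 2))
        pooled = self.data.reshape(newshape).mean(axis=axes)
        out = self._make(pooled, (self,), None)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad / (factor ** len(sp))
            for ax in range(2, 2 + len(sp)):
                g = np.repeat(g, factor, axis=ax)
            self._accum(g, own=True)

        out._backward = backward
        return out

    def upsample_nearest(self, factor: int) -> "Tensor":
        """Nearest-neighbour upsampling of all trailing spatial axes."""
        sp = self.shape[2:]
        up = self.data
        for ax in range(2, 2 + len(sp)):
            up = np.repeat(up, factor, axis=ax)
        out = self._make(up, (self,), None)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            shape = self.shape[:2]
            for s in sp:
                shape += (s, factor)
            axes = tuple(range(3, 3 + 2 * len(sp), 2))
            self._accum(g.reshape(shape).sum(axis=axes), own=True)

        out._backward = backward
        return out

    def upsample_linear(self, factor: int) -> "Tensor":
        """Separable linear-interpolation upsampling of trailing spatial axes.

        Output sample j maps to input coordinate (j + 0.5)/factor - 0.5
        (pixel-centre alignment), clamped at the borders.
        """
        sp = self.shape[2:]
        mats = [_linear_upsample_matrix(s, factor, self.dtype) for s in sp]
        data = self.data
        for i, S in enumerate(mats):
            data = np.moveaxis(np.tensordot(S, data, axes=(1, 2 + i)), 0, 2 + i)
        out = self._make(data, (self,), None)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            for i, S in enumerate(mats):
                g = np.moveaxis(np.tensordot(S.T, g, axes=(1, 2 + i)), 0, 2 + i)
            self._accum(np.ascontiguousarray(g), own=True)

        out._backward = backward
        return out

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # dismantle the graph: break closure cycles and free intermediate
        # gradients promptly (leaf tensors keep theirs); a second backward
        # through the same graph is not supported
        for node in topo:
            if node._parents:
                node.grad = None
                node._backward = None
                node._parents = ()

    def zero_grad_graph(self) -> None:
        for t in self._parents:
            t.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def _conv_correlate(inp: np.ndarray, w: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    """Stride-1 'same' cross-correlation as one batched GEMM per kernel offset.

    ``inp`` (N, C, *S), ``w`` (O, C, *k) -> (N, O, *S). Each offset slices a
    shifted view of the zero-padded input, copies it contiguously, and runs a
    (O, C) @ (N, C, prod(S)) batched matmul — far cheaper than materializing
    the full im2col window tensor.
    """
    from itertools import product

    spatial = inp.shape[2:]
    N, C = inp.shape[:2]
    O = w.shape[0]
    pad = [(0, 0), (0, 0)] + [(kk // 2, kk // 2) for kk in k]
    xp = np.pad(inp, pad)
    hw = int(np.prod(spatial))
    out = np.zeros((N, O, hw), dtype=inp.dtype)
    tmp = np.empty((N, O, hw), dtype=inp.dtype)
    for off in product(*(range(kk) for kk in k)):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + s) for o, s in zip(off, spatial)
        )
        xs = np.ascontiguousarray(xp[sl]).reshape(N, C, hw)
        wk = np.ascontiguousarray(w[(slice(None), slice(None)) + off])  # (O, C)
        np.matmul(wk, xs, out=tmp)
        out += tmp
    return out.reshape((N, O) + spatial)


def _conv_weight_grad(inp: np.ndarray, g: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    """Gradient of :func:`_conv_correlate` w.r.t. the weights.

    ``inp`` (N, C, *S), ``g`` (N, O, *S) -> (O, C, *k).
    """
    from itertools import product

    spatial = inp.shape[2:]
    N, C = inp.shape[:2]
    O = g.shape[1]
    pad = [(0, 0), (0, 0)] + [(kk // 2, kk // 2) for kk in k]
    xp = np.pad(inp, pad)
    hw = int(np.prod(spatial))
    gf = np.ascontiguousarray(g).reshape(N, O, hw)
    dw = np.zeros((O, C) + k, dtype=g.dtype)
    for off in product(*(range(kk) for kk in k)):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + s) for o, s in zip(off, spatial)
        )
        xs = np.ascontiguousarray(xp[sl]).reshape(N, C, hw)
        # sum_n (O, hw) @ (hw, C)
        dw[(slice(None), slice(None)) + off] = np.einsum(
            "noh,nch->oc", gf, xs, optimize=True
        )
    return dw


def _conv(x: Tensor, weight: Tensor, bias: Tensor | None, ndim: int) -> Tensor:
    from . import _kernels

    k = weight.shape[2:]
    if any(kk % 2 == 0 for kk in k):
        raise ValueError("only odd kernel sizes are supported")
    correlate = _kernels.correlate2d if ndim == 2 else _kernels.correlate3d
    weight_grad = _kernels.weight_grad2d if ndim == 2 else _kernels.weight_grad3d
    # pad once; the padded input is shared with the weight-gradient pass
    xp = _kernels.pad_same(x.data, k)
    out_data = correlate(xp, weight.data, padded=True)
    if bias is not None:
        out_data += bias.data.reshape((1, -1) + (1,) * ndim)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if not out.requires_grad:
        return out
    out._parents = parents

    def backward():
        g = out.grad  # (N, O, *spatial)
        if weight.requires_grad:
            weight._accum(weight_grad(xp, g, k, n_ch=x.shape[1], padded=True)
                          .astype(weight.dtype, copy=False), own=True)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0,) + tuple(range(2, 2 + ndim))), own=True)
        if x.requires_grad:
            # adjoint of stride-1 same-pad correlation: correlate g with the
            # spatially flipped, channel-transposed weights
            flip = (slice(None), slice(None)) + (slice(None, None, -1),) * ndim
            wT = np.ascontiguousarray(np.swapaxes(weight.data[flip], 0, 1))
            x._accum(correlate(g, wT).astype(x.dtype, copy=False), own=True)

    out._backward = backward
    return out


def _linear_upsample_matrix(n_in: int, factor: int, dtype) -> np.ndarray:
    """(n_in*factor, n_in) linear interpolation matrix, border-clamped."""
    n_out = n_in * factor
    j = np.arange(n_out)
    src = (j + 0.5) / factor - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    frac[src > n_in - 1] = 0.0
    S = np.zeros((n_out, n_in), dtype=dtype)
    S[j, lo] += 1.0 - frac
    S[j, hi] += frac
    return S


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if not out.requires_grad:
        return out
    out._parents = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * data.ndim
                idx[axis] = slice(a, b)
                t._accum(out.grad[tuple(idx)])

    out._backward = backward
    return out


def grid_sample2d(image: Tensor, uv: np.ndarray) -> Tensor:
    """Bilinearly sample a (C, H, W) image at fixed pixel locations.
    (gather/scatter loops are numba-compiled)

    ``uv`` is (P, 2) in (column, row) pixel-centre coordinates; samples
    outside the image contribute zero (zero padding). Returns (P, C) and is
    differentiable with respect to the image values only — the sample
    locations are treated as constants.
    """
    from . import _kernels

    C, H, W = image.shape
    u = np.asarray(uv[:, 0], dtype=image.dtype)
    v = np.asarray(uv[:, 1], dtype=image.dtype)
    x0 = np.floor(u).astype(int)
    y0 = np.floor(v).astype(int)
    fx = u - x0
    fy = v - y0
    P = len(u)
    out_data = np.zeros((P, C), dtype=image.dtype)
    img = np.ascontiguousarray(image.data)
    corners = []
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            w = (fx if dx else 1.0 - fx) * (fy if dy else 1.0 - fy)
            valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
            idx = np.nonzero(valid)[0]
            xi_v, yi_v, w_v = xi[idx], yi[idx], w[idx]
            sub = np.zeros((len(idx), C), dtype=image.dtype)
            _kernels.gather2d(img, yi_v, xi_v, w_v, sub)
            out_data[idx] += sub
            corners.append((idx, xi_v, yi_v, w_v))

    out = Tensor(out_data)
    out.requires_grad = image.requires_grad
    if not out.requires_grad:
        return out
    out._parents = (image,)

    def backward():
        from . import _kernels

        g = out.grad  # (P, C)
        dimg = np.zeros((H, W, C), dtype=image.dtype)
        for idx, xi_v, yi_v, w_v in corners:
            _kernels.scatter_add2d(dimg, yi_v, xi_v, w_v,
                                   np.ascontiguousarray(g[idx]))
        image._accum(np.ascontiguousarray(np.moveaxis(dimg, -1, 0)), own=True)

    out._backward = backward
    return out


def sample_at_points(volume: Tensor, pts_idx: np.ndarray) -> Tensor:
    """Trilinearly sample channel ``l`` of a (L, D, H, W) volume at point ``l``.

    ``pts_idx`` is (L, 3) in fractional voxel-index coordinates ordered like
    the volume axes (d, h, w). Points must lie inside the index bounds.
    Returns (L,), differentiable w.r.t. the volume.
    """
    L, D, H, W = volume.shape
    p = np.asarray(pts_idx, dtype=volume.dtype)
    if np.any(p < 0) or np.any(p > np.array([D, H, W]) - 1):
        raise ValueError("sample point outside volume index bounds")
    base = np.floor(p).astype(int)
    base = np.minimum(base, np.array([D, H, W]) - 2)  # keep the +1 corner in bounds
    f = p - base
    lidx = np.arange(L)
    out_data = np.zeros(L, dtype=volume.dtype)
    corners = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (f[:, 0] if dz else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dx else 1 - f[:, 2])
                )
                zi, yi, xi = base[:, 0] + dz, base[:, 1] + dy, base[:, 2] + dx
                out_data += w * volume.data[lidx, zi, yi, xi]
                corners.append((zi, yi, xi, w))

    out = Tensor(out_data)
    out.requires_grad = volume.requires_grad
    if not out.requires_grad:
        return out
    out._parents = (volume,)

    def backward():
        g = out.grad
        dv = np.zeros_like(volume.data)
        for zi, yi, xi, w in corners:
            np.add.at(dv, (lidx, zi, yi, xi), w * g)
        volume._accum(dv, own=True)

    out._backward = backward
    return out

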