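"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations a DeepLabV3+-style encoder-decoder needs:
2-D convolution (strided / dilated / grouped), batch normalisation, ReLU
family, channel concatenation, elementwise add, global average pooling,
bilinear resizing and a softmax cross-entropy head.  Everything is float32
NCHW.  The graph is built dynamically; ``Tensor.backward()`` runs a
topological sweep and accumulates gradients on leaves that require them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "relu",
    "relu6",
    "concat",
    "conv2d",
    "batch_norm",
    "global_avg_pool",
    "broadcast_hw",
    "bilinear_resize",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward_fn = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data, dtype=np.float32)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward_fn is not None:
                for parent, pg in zip(node._parents, node._backward_fn(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward_fn = backward_fn
    return out


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(data, (a, b), bwd)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


def relu6(x: Tensor) -> Tensor:
    mask = (x.data > 0) & (x.data < 6.0)
    return _make(np.clip(x.data, 0.0, 6.0), (x,), lambda g: (g * mask,))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over H and W, keeping singleton spatial dims."""
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        return (np.broadcast_to(g / (h * w), x.data.shape).copy(),)

    return _make(data, (x,), bwd)


def broadcast_hw(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Broadcast a (N, C, 1, 1) tensor over a spatial grid."""
    assert x.data.shape[2] == x.data.shape[3] == 1
    data = np.broadcast_to(x.data, x.data.shape[:2] + (out_h, out_w)).copy()

    def bwd(g):
        return (g.sum(axis=(2, 3), keepdims=True),)

    return _make(data, (x,), bwd)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_indices(h_p, w_p, kh, kw, sh, sw, dh, dw):
    out_h = (h_p - dh * (kh - 1) - 1) // sh + 1
    out_w = (w_p - dw * (kw - 1) - 1) // sw + 1
    i = (np.arange(out_h) * sh)[:, None] + (np.arange(kh) * dh)[None, :]
    j = (np.arange(out_w) * sw)[:, None] + (np.arange(kw) * dw)[None, :]
    # flat spatial index for every (out_y, ky, out_x, kx)
    flat = (i[:, :, None, None] * w_p + j[None, None, :, :]).reshape(
        out_h, kh, out_w, kw
    )
    return out_h, out_w, flat


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    groups: int = 1,
    padding: int | None = None,
) -> Tensor:
    """2-D convolution, NCHW.  ``padding=None`` means 'same' for stride 1."""
    n, c_in, h, w = x.data.shape
    c_out, c_in_g, kh, kw = weight.data.shape
    if padding is None:
        padding = dilation * (kh - 1) // 2
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    h_p, w_p = xp.shape[2], xp.shape[3]
    out_h, out_w, flat = _conv_indices(h_p, w_p, kh, kw, stride, stride, dilation, dilation)
    l = out_h * out_w

    # cols: (N, C, kh*kw, L)
    xf = xp.reshape(n, c_in, h_p * w_p)
    cols = xf[:, :, flat.transpose(1, 3, 0, 2).reshape(kh * kw, l)]
    cols = cols.reshape(n, groups, c_in_g * kh * kw, l)

    wmat = weight.data.reshape(groups, c_out // groups, c_in_g * kh * kw)
    out = np.einsum("gof,ngfl->ngol", wmat, cols, optimize=True)
    out = out.reshape(n, c_out, out_h, out_w)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    flat_cols = flat.transpose(1, 3, 0, 2).reshape(kh * kw, l)

    def bwd(g):
        gmat = g.reshape(n, groups, c_out // groups, l)
        gw = np.einsum("ngol,ngfl->gof", gmat, cols, optimize=True)
        gw = gw.reshape(weight.data.shape)
        gb = g.sum(axis=(0, 2, 3)) if bias is not None else None

        gx = None
        if x.requires_grad:
            gcols = np.einsum("gof,ngol->ngfl", wmat, gmat, optimize=True)
            gcols = gcols.reshape(n * c_in, kh * kw, l)
            # scatter-add back into the padded image via one bincount
            base = (np.arange(n * c_in) * (h_p * w_p))[:, None, None]
            idx = (flat_cols[None, :, :] + base).ravel()
            gxp = np.bincount(idx, weights=gcols.ravel(), minlength=n * c_in * h_p * w_p)
            gxp = gxp.reshape(n, c_in, h_p, w_p).astype(np.float32)
            gx = (
                gxp[:, :, padding : padding + h, padding : padding + w]
                if padding
                else gxp
            )
        if bias is not None:
            return gx, gw, gb
        return gx, gw

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bwd)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    m = n * h * w

    def bwd(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gs = gamma.data * inv_std
        if training:
            gx = gs.reshape(1, c, 1, 1) * (
                g
                - gbeta.reshape(1, c, 1, 1) / m
                - xhat * ggamma.reshape(1, c, 1, 1) / m
            )
        else:
            gx = gs.reshape(1, c, 1, 1) * g
        return gx.astype(np.float32), ggamma, gbeta

    return _make(out, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# bilinear resize
# ---------------------------------------------------------------------------

def _resize_axis_weights(n_out: int, n_in: int):
    """half-pixel-centre source coordinates (align_corners=False)."""
    if n_in == 1:
        z = np.zeros(n_out, dtype=np.int64)
        return z, z, np.zeros(n_out, dtype=np.float32)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    return i0, i1, frac


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.data.shape
    if (out_h, out_w) == (h, w):
        return _make(x.data, (x,), lambda g: (g,))
    y0, y1, fy = _resize_axis_weights(out_h, h)
    x0, x1, fx = _resize_axis_weights(out_w, w)
    fy_c = fy.reshape(1, 1, out_h, 1)
    fx_c = fx.reshape(1, 1, 1, out_w)

    rows = x.data[:, :, y0, :] * (1 - fy_c) + x.data[:, :, y1, :] * fy_c
    out = rows[:, :, :, x0] * (1 - fx_c) + rows[:, :, :, x1] * fx_c

    def bwd(g):
        grows = np.zeros((n, c, out_h, w), dtype=np.float32)
        np.add.at(grows, (slice(None), slice(None), slice(None), x0), g * (1 - fx_c))
        np.add.at(grows, (slice(None), slice(None), slice(None), x1), g * fx_c)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), y0, slice(None)), grows * (1 - fy_c))
        np.add.at(gx, (slice(None), slice(None), y1, slice(None)), grows * fy_c)
        return (gx,)

    return _make(out.astype(np.float32), (x,), bwd)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy. ``labels``: int array (N, H, W)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = z - zmax - np.log(sez)
    n, k, h, w = z.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    picked = logp[idx_n, labels, idx_h, idx_w]
    count = n * h * w
    loss = -picked.sum() / count

    def bwd(g):
        p = ez / sez
        p[idx_n, labels, idx_h, idx_w] -= 1.0
        return ((g * p / count).astype(np.float32),)

    return _make(np.float32(loss), (logits,), bwd)
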