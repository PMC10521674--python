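"""Minimal reverse-mode autodiff on numpy arrays.

Exactly the operator set the segmentation network needs: 3-D convolution
(kernel 1 or 3, stride 1 or 2, "same" padding), group normalisation,
ReLU, 2x2x2 max-pooling, 2x nearest-neighbour upsampling, channel
concatenation, addition, dropout, and a fused softmax cross-entropy with
optional hard-voxel selection.  Tensors carry a (C, D, H, W) float32
array; gradients are accumulated by a topological backward sweep.

Convolutions are evaluated as tensordot contractions over a strided
sliding-window view (an im2col in disguise), which keeps a full
forward/backward pass on a 32**3 volume well under a second on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=()):
        data = np.asarray(data, dtype=np.float32)
        self.data = data if data.flags.c_contiguous else np.ascontiguousarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float32)
        self.grad += g

    def backward(self):
        """Reverse sweep from a scalar loss."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def parameter(array) -> Tensor:
    return Tensor(np.asarray(array, dtype=np.float32))


# ------------------------------------------------------------------ ops

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """'Same'-padded 3-D convolution; kernel size read from the weight."""
    k = w.data.shape[2]
    pad = k // 2
    xd = x.data
    if pad:
        xp = np.pad(xd, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    else:
        xp = xd
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    if stride > 1:
        win = win[:, ::stride, ::stride, ::stride]
    out = np.tensordot(w.data, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    out += b.data[:, None, None, None]
    t = Tensor(out, parents=(x, w, b))

    def backward(g):
        w._accumulate(np.tensordot(g, win, axes=([1, 2, 3], [1, 2, 3])))
        b._accumulate(g.sum(axis=(1, 2, 3)))
        dxp = np.zeros_like(xp)
        Do, Ho, Wo = g.shape[1:]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    contrib = np.tensordot(w.data[:, :, i, j, l], g, axes=([0], [0]))
                    dxp[:, i:i + stride * Do:stride,
                        j:j + stride * Ho:stride,
                        l:l + stride * Wo:stride] += contrib
        x._accumulate(dxp[:, pad:pad + xd.shape[1], pad:pad + xd.shape[2],
                          pad:pad + xd.shape[3]] if pad else dxp)

    t._backward = backward
    return t


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    t = Tensor(x.data * mask, parents=(x,))
    t._backward = lambda g: x._accumulate(g * mask)
    return t


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    C = x.data.shape[0]
    g = groups
    while C % g:
        g -= 1
    xg = x.data.reshape(g, -1)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv_std).reshape(x.data.shape)
    out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]
    t = Tensor(out, parents=(x, gamma, beta))

    def backward(gr):
        gamma._accumulate((gr * xhat).sum(axis=(1, 2, 3)))
        beta._accumulate(gr.sum(axis=(1, 2, 3)))
        dxhat = (gr * gamma.data[:, None, None, None]).reshape(g, -1)
        xh = xhat.reshape(g, -1)
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xh).mean(axis=1, keepdims=True)
        dx = inv_std * (dxhat - m1 - xh * m2)
        x._accumulate(dx.reshape(x.data.shape).astype(np.float32))

    t._backward = backward
    return t


def max_pool2(x: Tensor) -> Tensor:
    C, D, H, W = x.data.shape
    xr = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, D // 2, H // 2, W // 2, 8)
    am = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
    t = Tensor(out, parents=(x,))

    def backward(g):
        dxr = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=np.float32)
        np.put_along_axis(dxr, am[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
        dx = dx.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, D, H, W)
        x._accumulate(dx)

    t._backward = backward
    return t


def upsample2(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    t = Tensor(out, parents=(x,))

    def backward(g):
        C, D, H, W = x.data.shape
        x._accumulate(g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6)))

    t._backward = backward
    return t


def concat(tensors) -> Tensor:
    sizes = [t.data.shape[0] for t in tensors]
    t = Tensor(np.concatenate([u.data for u in tensors], axis=0), parents=tuple(tensors))

    def backward(g):
        off = 0
        for u, s in zip(tensors, sizes):
            u._accumulate(g[off:off + s])
            off += s

    t._backward = backward
    return t


def add(a: Tensor, b: Tensor) -> Tensor:
    t = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    t._backward = backward
    return t


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    t = Tensor(x.data * mask, parents=(x,))
    t._backward = lambda g: x._accumulate(g * mask)
    return t


def softmax_cross_entropy(logits: Tensor, target: np.ndarray,
                          hard_fraction: float | None = None) -> Tensor:
    """Voxelwise CE over (K, spatial) logits against integer targets.

    With ``hard_fraction`` f in (0, 1), only the hardest f of voxels
    (largest per-voxel loss) contribute — hard-example mining within one
    image.  Returns a scalar tensor.
    """
    K = logits.data.shape[0]
    flat = logits.data.reshape(K, -1).astype(np.float64)
    tgt = np.asarray(target).reshape(-1).astype(np.intp)
    V = flat.shape[1]
    shifted = flat - flat.max(axis=0, keepdims=True)
    ex = np.exp(shifted)
    Z = ex.sum(axis=0, keepdims=True)
    p = ex / Z
    logp = shifted - np.log(Z)
    per_voxel = -logp[tgt, np.arange(V)]
    if hard_fraction is not None and 0 < hard_fraction < 1:
        nsel = max(1, int(round(hard_fraction * V)))
        sel = np.argpartition(per_voxel, V - nsel)[V - nsel:]
    else:
        nsel = V
        sel = np.arange(V)
    loss = per_voxel[sel].mean()
    t = Tensor(np.float32(loss), parents=(logits,))

    def backward(g):
        dl = np.zeros((K, V), dtype=np.float32)
        grad_sel = p[:, sel].copy()
        grad_sel[tgt[sel], np.arange(sel.size)] -= 1.0
        dl[:, sel] = grad_sel / nsel
        logits._accumulate(np.float32(g) * dl.reshape(logits.data.shape))

    t._backward = backward
    return t


def softmax(logits_data: np.ndarray) -> np.ndarray:
    """Channel softmax for inference (plain numpy, float64)."""
    a = np.asarray(logits_data, dtype=np.float64)
    a = a - a.max(axis=0, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=0, keepdims=True)


class Adam:
    """Adam with classic (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
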