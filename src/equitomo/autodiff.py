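"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the restoration
network and its training objective need: 3D convolution (3x3x3, stride 1,
same padding), leaky ReLU, 2x average pooling / nearest upsampling,
elementwise arithmetic, mean-squared-error reduction, and two linear
volume operators with trivial adjoints — the Fourier wedge projector
(self-adjoint) and signed-permutation rotation (adjoint = inverse
rotation).  Convolutions are evaluated as 27 shifted 1x1 channel-mixing
matmuls, which keeps the arithmetic in BLAS.

Activations and parameters are float32.  Gradients propagate through
every operation, including the wedge projector and rotations, so losses
that apply the network to its own (re-corrupted) output differentiate end
to end.
"""

from __future__ import annotations

import numpy as np

from .geometry import GroupElement, apply_transform, inverse as g_inverse

__all__ = ["Tensor", "conv3d", "leaky_relu", "avg_pool", "upsample", "add",
           "sub", "scale", "mse", "wedge_project", "rotate", "mean_of", "Adam"]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _channel_mix(w2: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(O,C) x (B,C,n) -> (B,O,n) via BLAS."""
    B, C, n = x.shape
    return np.matmul(w2, x.reshape(B, C, n))


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3x3 convolution, stride 1, same (zero) padding.

    ``x``: (B, C, D, H, W); ``w``: (O, C, 3, 3, 3); ``b``: (O,).
    """
    xd, wd = x.data, w.data
    B, C, D, H, W = xd.shape
    O = wd.shape[0]
    xp = np.pad(xd, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    n = D * H * W
    out = np.zeros((B, O, n), dtype=np.float32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = np.ascontiguousarray(xp[:, :, i:i + D, j:j + H, k:k + W])
                out += _channel_mix(wd[:, :, i, j, k], xs.reshape(B, C, n))
    out = out.reshape(B, O, D, H, W) + b.data[None, :, None, None, None]
    res = Tensor(out, _parents=(x, w, b))

    def _bw(g: np.ndarray) -> None:
        g3 = g.reshape(B, O, n)
        # bias
        b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        # weights: grad_w[o,c,ijk] = sum_{b,p} g[b,o,p] xp[b,c,p+ijk]
        gw = np.empty_like(wd)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = np.ascontiguousarray(
                        xp[:, :, i:i + D, j:j + H, k:k + W]).reshape(B, C, n)
                    gw[:, :, i, j, k] = np.einsum("bon,bcn->oc", g3, xs, optimize=True)
        w._accumulate(gw)
        # input: grad_xp[p+ijk] += w[:,:,ijk]^T g[p]
        gxp = np.zeros((B, C, D + 2, H + 2, W + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    contrib = np.matmul(wd[:, :, i, j, k].T, g3)  # (B,C,n)
                    gxp[:, :, i:i + D, j:j + H, k:k + W] += contrib.reshape(B, C, D, H, W)
        x._accumulate(gxp[:, :, 1:-1, 1:-1, 1:-1])

    res._backward = _bw
    return res


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * x.data)
    res = Tensor(out, _parents=(x,))
    res._backward = lambda g: x._accumulate(np.where(pos, g, alpha * g))
    return res


def avg_pool(x: Tensor) -> Tensor:
    """2x average pooling over the three spatial axes."""
    B, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"avg_pool needs even spatial dims, got {(D, H, W)}")
    r = x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = r.mean(axis=(3, 5, 7))
    res = Tensor(out, _parents=(x,))

    def _bw(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(np.repeat(g, 2, 2), 2, 3), 2, 4) / 8.0
        x._accumulate(gx)

    res._backward = _bw
    return res


def upsample(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling over the three spatial axes."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, 2), 2, 3), 2, 4)
    res = Tensor(out, _parents=(x,))

    def _bw(g: np.ndarray) -> None:
        B, C, D, H, W = x.data.shape
        r = g.reshape(B, C, D, 2, H, 2, W, 2)
        x._accumulate(r.sum(axis=(3, 5, 7)))

    res._backward = _bw
    return res


def add(a: Tensor, b: Tensor) -> Tensor:
    res = Tensor(a.data + b.data, _parents=(a, b))

    def _bw(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(g)

    res._backward = _bw
    return res


def sub(a: Tensor, b: Tensor) -> Tensor:
    res = Tensor(a.data - b.data, _parents=(a, b))

    def _bw(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(-g)

    res._backward = _bw
    return res


def scale(a: Tensor, c: float) -> Tensor:
    res = Tensor(a.data * c, _parents=(a,))
    res._backward = lambda g: a._accumulate(g * c)
    return res


def mean_of(parts: list[Tensor]) -> Tensor:
    """Arithmetic mean of scalar tensors."""
    out = sum(p.data for p in parts) / len(parts)
    res = Tensor(out, _parents=tuple(parts))

    def _bw(g: np.ndarray) -> None:
        for p in parts:
            p._accumulate(g / len(parts))

    res._backward = _bw
    return res


def mse(a: Tensor, b: Tensor, weight: np.ndarray | None = None) -> Tensor:
    """Mean squared difference, optionally with a fixed elementwise weight."""
    d = a.data - b.data
    if weight is not None:
        wd = weight.astype(np.float32)
        val = np.mean(wd * d * d)
    else:
        wd = None
        val = np.mean(d * d)
    res = Tensor(val, _parents=(a, b))

    def _bw(g: np.ndarray) -> None:
        gg = (2.0 / d.size) * d * g
        if wd is not None:
            gg = gg * wd
        a._accumulate(gg)
        b._accumulate(-gg)

    res._backward = _bw
    return res


def _fft_mask(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(
        np.fft.fftn(vol.astype(np.float32), axes=(-3, -2, -1)) * mask,
        axes=(-3, -2, -1),
    ).real.astype(np.float32)


def wedge_project(x: Tensor, mask: np.ndarray) -> Tensor:
    """Apply the wedge projector ``A`` (mask in wrap FFT layout) per sample.

    ``A`` is real-linear and self-adjoint, so the vector-Jacobian product
    is ``A`` itself.
    """
    res = Tensor(_fft_mask(x.data, mask), _parents=(x,))
    res._backward = lambda g: x._accumulate(_fft_mask(g, mask))
    return res


def rotate(x: Tensor, g: GroupElement) -> Tensor:
    """Apply ``R_g`` to the spatial axes of (B, C, D, H, W); adjoint = R_g^{-1}."""
    gi = g_inverse(g)

    def _rot(a: np.ndarray, elem: GroupElement) -> np.ndarray:
        B, C = a.shape[:2]
        out = np.empty_like(a)
        for bi in range(B):
            for ci in range(C):
                out[bi, ci] = apply_transform(elem, a[bi, ci])
        return out

    res = Tensor(_rot(x.data, g), _parents=(x,))
    res._backward = lambda gr: x._accumulate(_rot(gr, gi))
    return res


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 4e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
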