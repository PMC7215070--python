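"""A compact reverse-mode automatic differentiation core on numpy arrays.

The basic learner's architecture (convolution stack, multi-head attention
with pooling, pair merge, dense softmax head) is trained by backpropagation;
this module provides the tensor graph and gradients for exactly the
operations that architecture needs.  Gradients are verified against finite
differences in the test suite.

Conventions: `Tensor` wraps a float64 ndarray; ops build a DAG; calling
`backward()` on a scalar tensor accumulates `.grad` on every tensor with
`requires_grad=True`.  Broadcasting in `+` and `*` is supported and
un-broadcast on the way back.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce `grad` back to `shape` by summing over broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # out-of-place accumulation: stored gradients are never mutated, so
        # views passed down by reshape/transpose backwards are safe to keep
        if self.grad is None:
            self.grad = np.broadcast_to(grad, self.data.shape) if (
                grad.shape != self.data.shape
            ) else grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar path preserves dtype
            out = Tensor(self.data + other, parents=(self,))

            def back_s(g):
                if self.requires_grad:
                    self._accum(g)

            out._backward = back_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # scalar path preserves dtype
            out = Tensor(self.data * other, parents=(self,))

            def back_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            out._backward = back_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = back
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = back
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = back
        return out

    # -- reductions & nonlinearities -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties send the full gradient to the first hit."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = np.zeros_like(self.data)
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        np.put_along_axis(mask, idx, 1.0, axis=axis)
        res = out_data if keepdims else out_data.squeeze(axis)
        out = Tensor(res, parents=(self,))

        def back(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(mask * g)

        out._backward = back
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = back
        return out

    def sqrt(self):
        return self**0.5

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def back(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = back
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = back
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution with 'same' zero padding, stride 1.

    x: (N, P, C_in); w: (K, C_in, C_out) with K odd; b: (C_out,).
    Returns (N, P, C_out).
    """
    N, P, Cin = x.shape
    K, Cin_w, Cout = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv1d: expected {Cin_w} input channels, got {Cin}")
    if K % 2 == 0:
        raise ValueError("conv1d_same requires an odd kernel width")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (N,P,Cin,K)
    cols = cols.transpose(0, 1, 3, 2).reshape(N, P, K * Cin)
    wmat = w.data.reshape(K * Cin, Cout)
    out = Tensor(cols @ wmat + b.data, parents=(x, w, b))

    def back(g):  # g: (N, P, Cout)
        if w.requires_grad:
            gw = np.einsum("npi,npo->io", cols, g).reshape(K, Cin, Cout)
            w._accum(gw)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = (g @ wmat.T).reshape(N, P, K, Cin)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + P, :] += gcols[:, :, k, :]
            x._accum(gxp[:, pad : pad + P, :])

    out._backward = back
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels.

    logits: (N, n_classes); labels: (N,) ints.  Fused op for numerical
    stability; gradient is (softmax - onehot) / N.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    tiny = np.finfo(p.dtype).tiny
    nll = -np.log(np.clip(p[np.arange(n), labels], tiny, None)).mean()
    out = Tensor(nll, parents=(logits,))

    def back(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    out._backward = back
    return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
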