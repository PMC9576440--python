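"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

The segmentation network and its compound loss need gradients of
convolutions, pooling, normalization and elementwise maps. This module
provides exactly that set: a :class:`Tensor` records the operations applied
to it and :meth:`Tensor.backward` replays them in reverse topological
order. Convolution is im2col + GEMM, so the heavy lifting stays inside
BLAS. Everything is deterministic given the seeds supplied by callers;
gradients are validated against central finite differences in the test
suite.

Dtype follows the data: training runs in float32, gradient-check tests
in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "batch_norm2d",
    "maxpool2x",
    "upsample_nearest2x",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
    "RMSprop",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        """Wrap ``other``; python scalars adopt this tensor's float dtype."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)) and np.issubdtype(self.data.dtype, np.floating):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor._make(out_data, (self, other), backward)

    # ---- elementwise maps ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        return self**0.5

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            return (g * s * (1.0 - s),)

        return Tensor._make(s, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        dt = self.data.dtype
        factor = np.where(self.data > 0, np.asarray(1.0, dt), np.asarray(slope, dt))
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    def clamp(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # ---- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    # ---- autodiff driver ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=parent.data.dtype)
                else:
                    parent.grad = parent.grad + g
            if node is not self:
                # interior node: consumers are all upstream in reverse
                # topological order, so its tape entry can be freed now
                node._parents = ()
                node._backward = None
                node.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tensors, backward)


# ---- spatial ops -----------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2D cross-correlation, stride 1; NCHW layout, OIHW weights."""
    N, C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"weight expects {Cw} input channels, got {C}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1

    if kh == kw == 1:
        cols = xp.reshape(N, C, Ho * Wo)
    else:
        # im2col: gather the kh*kw shifted views into one contiguous block
        gather = np.empty((N, C, kh, kw, Ho, Wo), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                gather[:, :, i, j] = xp[:, :, i : i + Ho, j : j + Wo]
        cols = gather.reshape(N, C * kh * kw, Ho * Wo)
    wmat = w.data.reshape(F, C * kh * kw)
    out = np.matmul(wmat, cols).reshape(N, F, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, F, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.reshape(N, F, Ho * Wo))
        # dw: sum over batch of (F,L)@(L,K) — batched BLAS, not einsum
        dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        db = None if b is None else gmat.sum(axis=(0, 2)).reshape(b.shape)
        dx = None
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # (N, C*kh*kw, Ho*Wo)
            if kh == kw == 1:
                dxp = dcols.reshape(N, C, Ho, Wo)
            else:
                dcols = dcols.reshape(N, C, kh, kw, Ho, Wo)
                dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, i, j]
            dx = dxp[:, :, p : p + H, p : p + W] if p else dxp
        return (dx, dw) if b is None else (dx, dw, db)

    return Tensor._make(out, parents, backward)


def maxpool2x(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2; spatial dims must be even."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x needs even spatial dims, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xr = (
        x.data.reshape(N, C, Ho, 2, Wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, Ho, Wo, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((N, C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dxr.reshape(N, C, Ho, Wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        return (dx,)

    return Tensor._make(out, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mu: np.ndarray,
    var: np.ndarray,
    eps: float,
    stats_from_batch: bool,
) -> Tensor:
    """Channel normalization with a fused closed-form backward pass.

    ``mu``/``var`` are (1, C, 1, 1) arrays; when ``stats_from_batch``
    they were computed from ``x`` itself and the backward pass carries
    the corresponding mean/variance terms, otherwise (running stats)
    the normalization is an affine map of ``x`` alone.
    """
    std = np.sqrt(var + eps).astype(x.data.dtype)
    mu = mu.astype(x.data.dtype)
    xhat = (x.data - mu) / std
    out = gamma.data * xhat + beta.data
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes, keepdims=True)
        dbeta = g.sum(axis=axes, keepdims=True)
        dxhat = g * gamma.data
        if stats_from_batch:
            dx = (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
            ) / std
        else:
            dx = dxhat / std
        return dx, dgamma, dbeta

    return Tensor._make(out, (x, gamma, beta), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling (exact adjoint: 2×2 grad sum)."""
    N, C, H, W = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)


# ---- modules ---------------------------------------------------------------


class Module:
    """Base class with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def _own_params(self):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value

    def _own_buffers(self):
        for name in getattr(self, "_buffer_names", ()):
            yield name, getattr(self, name)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._own_params():
            yield prefix + name, p
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters(prefix)}
        for name, child in self._children():
            for bname, buf in child._own_buffers():
                state[prefix + name + "." + bname] = buf
            state.update(
                {
                    k: v
                    for k, v in child.state_dict(prefix + name + ".").items()
                    if k not in state
                }
            )
        for bname, buf in self._own_buffers():
            state[prefix + bname] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        for name, child in self._children():
            child.load_state_dict(
                {
                    k[len(name) + 1 :]: v
                    for k, v in state.items()
                    if k.startswith(name + ".")
                }
            )
        for bname, _ in self._own_buffers():
            if bname in state:
                setattr(self, bname, np.asarray(state[bname]))

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3×3 (or 1×1) convolution with He-normal init and a bias."""

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel_size // 2
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float64)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
            var = x.data.var(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        return batch_norm2d(
            x, self.gamma, self.beta, mu, var, self.eps, stats_from_batch=self.training
        )


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class RMSprop:
    """RMSprop with the usual running-average-of-squares update."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        if lr < 0:
            raise ValueError(f"learning rate must be >= 0, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._sq = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            sq *= self.rho
            sq += (1.0 - self.rho) * g * g
            p.data = p.data - (self.lr * g / (np.sqrt(sq) + self.eps)).astype(p.data.dtype)
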