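"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package runs on CPU at desk scale, so the engine favours
clarity and exact reproducibility over throughput: float64 by default, no
operator fusion, no memory pooling.  A :class:`Tensor` wraps an ``ndarray``
and records, for each op, closures that map the output gradient to gradients
of the inputs; :meth:`Tensor.backward` replays them in reverse topological
order.

Only the ops the segmentation model needs are provided: elementwise
arithmetic with broadcasting, matmul, row gather/scatter (the sparse-conv
and voxel scatter/gather primitives build on these), segment max, concat,
leaky ReLU, log-softmax/softmax, reductions, and a per-channel batch norm.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather_rows",
    "scatter_add_rows",
    "segment_max",
    "leaky_relu",
    "log_softmax",
    "softmax",
    "Linear",
    "BatchNorm",
    "MLP",
    "Adam",
    "Module",
    "init_rng",
]

#: default scalar type.  Library-level ops (oracle comparisons, gradient
#: checks) run in float64; the network trains in float32 via
#: :func:`use_dtype`, which roughly halves memory traffic.
DTYPE = np.float64


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily switch the engine's default scalar type."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the tape entries needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # make `ndarray <op> Tensor` defer to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        # parents: sequence of (Tensor, fn) where fn maps d(out) -> d(parent)
        self._parents = tuple(
            (p, fn) for p, fn in parents if p.requires_grad
        )

    # -- graph ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=DTYPE)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ),
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=((self, lambda g: g * sign),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(
            np.log(self.data), parents=((self, lambda g: g / self.data),)
        )

    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def back(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, shape).copy()

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=((self, back),)
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            parents=((self, lambda g: g.reshape(old)),),
        )

    def __getitem__(self, idx):
        # supported for simple slicing; fancy row indexing goes via gather_rows
        shape = self.data.shape

        def back(g):
            out = np.zeros(shape, dtype=DTYPE)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=((self, back),))

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structural ops -----------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        sl = [slice(None)] * tensors[0].data.ndim
        sl[axis] = slice(int(lo), int(hi))
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: g[sl]))
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(parents))


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[i] = x[idx[i]]`` with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.intp)
    shape = x.data.shape

    def back(g):
        out = np.zeros(shape, dtype=DTYPE)
        np.add.at(out, idx, g)
        return out

    return Tensor(x.data[idx], parents=((x, back),))


def scatter_add_rows(x: Tensor, idx: np.ndarray, n_out: int) -> Tensor:
    """``out[idx[i]] += x[i]`` into ``n_out`` zero-initialised rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n_out,) + x.data.shape[1:], dtype=DTYPE)
    np.add.at(out, idx, x.data)
    return Tensor(out, parents=((x, lambda g: g[idx]),))


def segment_max(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Per-segment elementwise max of rows; gradient routes to the argmax row.

    ``seg`` maps each row of ``x`` to a segment id in ``[0, n_seg)``; every
    segment must own at least one row.
    """
    seg = np.asarray(seg, dtype=np.intp)
    out = np.full((n_seg,) + x.data.shape[1:], -np.inf, dtype=DTYPE)
    np.maximum.at(out, seg, x.data)
    # argmax bookkeeping: a row contributes where it attains the segment max.
    # Ties split the gradient between tying rows (sets of measure zero for
    # continuous features; deterministic either way).
    hit = (x.data == out[seg])
    counts = np.zeros_like(out)
    np.add.at(counts, seg, hit.astype(DTYPE))

    def back(g):
        return hit * (g / counts)[seg]

    return Tensor(out, parents=((x, back),))


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope)
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def back(g):
        return g - sm * g.sum(axis=axis, keepdims=True)

    return Tensor(out, parents=((x, back),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


# -- layers --------------------------------------------------------------

def init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: collects parameters from attributes and sub-modules."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name → array view of every parameter and buffer (for I/O)."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_arrays(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_arrays(f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(arrays[key], dtype=DTYPE)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(arrays[key], dtype=DTYPE))
            elif isinstance(v, Module):
                v.load_arrays(arrays, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_arrays(arrays, f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.asarray(arrays[f"{key}.{i}"], dtype=DTYPE)

    def train_mode(self, flag: bool = True) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train_mode(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train_mode(flag)
        if hasattr(self, "training"):
            self.training = flag


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(_fan_in_uniform(rng, (c_in, c_out), c_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class BatchNorm(Module):
    """Per-channel normalisation over rows (the active sites / points)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            n = x.data.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mu
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        gamma, beta = self.gamma, self.beta

        if self.training:
            n = x.data.shape[0]

            def back_x(g):
                gy = g * gamma.data
                return inv * (
                    gy
                    - gy.mean(axis=0)
                    - xhat * (gy * xhat).mean(axis=0)
                )
        else:
            def back_x(g):
                return g * gamma.data * inv

        out = Tensor(
            xhat * gamma.data + beta.data,
            parents=(
                (x, back_x),
                (gamma, lambda g: (g * xhat).sum(axis=0)),
                (beta, lambda g: g.sum(axis=0)),
            ),
        )
        return out


class MLP(Module):
    """Shared per-row perceptron: Linear → BatchNorm → leaky ReLU per layer.

    The final layer is linear-only when ``final_plain`` is set (for logits).
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 final_plain: bool = False, norm: bool = True):
        self.layers = [
            Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])
        ]
        self.norms = [
            BatchNorm(b) if norm else None for b in widths[1:]
        ]
        self.final_plain = final_plain

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, (lin, bn) in enumerate(zip(self.layers, self.norms)):
            x = lin(x)
            if i == n - 1 and self.final_plain:
                break
            if bn is not None:
                x = bn(x)
            x = leaky_relu(x)
        return x


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
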