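"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient
and a closure that propagates incoming gradients to its parents.  Calling
:meth:`Tensor.backward` on a scalar loss walks the recorded graph in
reverse topological order.  Only the operations the segmentation network
needs are provided; all of them live in :mod:`riceseg.nn.functional`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph recording (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "retain_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.retain_grad = False
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def result(data, parents, backward):
        """Build a graph node; drops the tape when no parent needs gradients."""
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd -------------------------------------------------------------
    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here are hundreds of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate_grad(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/tape to bound memory
                if node is not self and not node.retain_grad:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators (thin wrappers over functional) ----------------------------
    def __add__(self, other):
        from . import functional as F

        if isinstance(other, (int, float)):
            return F.shift(self, float(other))
        return F.add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        if isinstance(other, (int, float)):
            return F.scale(self, float(other))
        return F.mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        from . import functional as F

        if isinstance(other, (int, float)):
            return F.shift(self, -float(other))
        return F.add(self, F.scale(as_tensor(other), -1.0))

    def __neg__(self):
        from . import functional as F

        return F.scale(self, -1.0)

    def __matmul__(self, other):
        from . import functional as F

        return F.matmul(self, as_tensor(other))

    def reshape(self, *shape):
        from . import functional as F

        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return F.reshape(self, shape)

    def transpose(self, *axes):
        from . import functional as F

        return F.transpose(self, axes if axes else None)

    def sum(self):
        from . import functional as F

        return F.sum_all(self)

    def mean(self):
        from . import functional as F

        return F.mean_all(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
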