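"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set the segmentation networks in
this package need: dense/strided/dilated/grouped 2-D convolution, batch
normalisation, max pooling, bilinear resampling, elementwise nonlinearities,
channel concatenation and a weighted softmax cross-entropy.  Gradients are
hand-derived and checked against finite differences in the test suite.

Arrays are kept in float64 throughout: the models trained here are small
(desk-scale phantoms), so numerical robustness is worth more than the
throughput of float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    """A numpy array with a gradient slot and a backward closure.

    Only operations created through :mod:`myinet.nn.functional` build the
    graph; the class itself stores the topology (``_parents``) and the local
    vector-Jacobian product (``_backward``).
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_op(cls, data, parents, backward) -> "Tensor":
        t = cls(data)
        t.requires_grad = any(p.requires_grad for p in parents)
        if t.requires_grad:
            t._parents = tuple(parents)
            t._backward = backward
        return t

    # -- properties -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this tensor.

        ``grad`` defaults to 1 for scalar outputs.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order by depth-first traversal
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.accumulate_grad(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
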