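"""Minimal reverse-mode automatic differentiation (NumPy).

Just enough machinery to express and train a small unrolled convolutional
reconstruction network on the CPU: tensors with a backward tape, 3x3
same-padding convolutions via im2col, ReLU, elementwise arithmetic, and the
exact linear physics step of proximal gradient descent as a single fused op
(so its adjoint is applied analytically rather than through a chain of
matmul nodes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "backward", "conv2d", "relu", "add", "mul_scalar",
           "physics_step", "mean_abs_error", "exp_scalar"]


class Var:
    """A node in the computation graph: a value, a gradient slot, and parents."""

    __slots__ = ("value", "grad", "parents", "bw", "name")

    def __init__(self, value, parents=(), bw=None, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.bw = bw
        self.name = name

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def backward(loss: Var) -> None:
    """Reverse-mode sweep from a scalar loss; accumulates into .grad slots."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.accumulate(np.ones_like(loss.value))
    for node in reversed(topo):
        if node.bw is not None and node.grad is not None:
            node.bw(node.grad)


# ---------------------------------------------------------------------------
# ops


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (C*9, H*W) columns of 3x3 same-padded neighborhoods."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (C, H, W, 3, 3) -> (C, 3, 3, H, W) -> (C*9, H*W)
    return win.transpose(0, 3, 4, 1, 2).reshape(c * 9, h * w)


def _col2im_add(dcols: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back to (C, H, W)."""
    c, h, w = shape
    dxp = np.zeros((c, h + 2, w + 2))
    d = dcols.reshape(c, 3, 3, h, w)
    for di in range(3):
        for dj in range(3):
            dxp[:, di:di + h, dj:dj + w] += d[:, di, dj]
    return dxp[:, 1:h + 1, 1:w + 1]


def conv2d(x: Var, weight: Var, bias: Var) -> Var:
    """3x3 same-padding convolution: (Cin,H,W) x (Cout,Cin,3,3) -> (Cout,H,W)."""
    cin, h, w = x.value.shape
    cout = weight.value.shape[0]
    cols = _im2col(x.value)                          # (Cin*9, H*W)
    wmat = weight.value.reshape(cout, cin * 9)
    out = (wmat @ cols + bias.value[:, None]).reshape(cout, h, w)

    def bw(g: np.ndarray) -> None:
        gm = g.reshape(cout, h * w)
        weight.accumulate((gm @ cols.T).reshape(weight.value.shape))
        bias.accumulate(gm.sum(axis=1))
        dcols = wmat.T @ gm                          # (Cin*9, H*W)
        x.accumulate(_col2im_add(dcols, (cin, h, w)))

    return Var(out, parents=(x, weight, bias), bw=bw, name="conv2d")


def relu(x: Var) -> Var:
    mask = x.value > 0

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    return Var(x.value * mask, parents=(x,), bw=bw, name="relu")


def add(a: Var, b: Var) -> Var:
    def bw(g: np.ndarray) -> None:
        a.accumulate(g)
        b.accumulate(g)

    return Var(a.value + b.value, parents=(a, b), bw=bw, name="add")


def mul_scalar(x: Var, s: Var) -> Var:
    """Elementwise scale of a tensor by a scalar Var (broadcast)."""

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * s.value)
        s.accumulate(np.array(np.sum(g * x.value)))

    return Var(x.value * s.value, parents=(x, s), bw=bw, name="mul_scalar")


def exp_scalar(x: Var) -> Var:
    out = np.exp(x.value)

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * out)

    return Var(out, parents=(x,), bw=bw, name="exp")


def physics_step(x: Var, rho: Var, a: np.ndarray, y: np.ndarray) -> Var:
    """Exact data-fidelity step z = x - rho * A^T (A x - y) on a flat image.

    A and y are constants of the call.  The map is affine in x with the
    symmetric Jacobian (I - rho A^T A), so the backward pass reuses the same
    operator; the step-size gradient is -<g, A^T(A x - y)>.
    """
    xv = x.value.reshape(-1)
    grad_term = a.T @ (a @ xv - y)
    out = (xv - rho.value * grad_term).reshape(x.value.shape)

    def bw(g: np.ndarray) -> None:
        gf = g.reshape(-1)
        x.accumulate((gf - rho.value * (a.T @ (a @ gf))).reshape(x.value.shape))
        rho.accumulate(np.array(-float(gf @ grad_term)))

    return Var(out, parents=(x, rho), bw=bw, name="physics_step")


def mean_abs_error(pred: Var, target: np.ndarray) -> Var:
    """(1/N) ||pred - target||_1 — the training loss of the unrolled net."""
    diff = pred.value - target
    n = diff.size

    def bw(g: np.ndarray) -> None:
        pred.accumulate(g * np.sign(diff) / n)

    return Var(np.abs(diff).mean(), parents=(pred,), bw=bw, name="l1")
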