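"""Classical compressed-sensing reconstruction by proximal gradient descent.

Solves min_x 0.5 ||A x - y||^2 + lambda R(x) by alternating an exact
gradient step on the data-fidelity term with the proximal mapping of the
regularizer.  Serves as the interpretable reference that the unrolled
network (:mod:`spirecon.recon_net`) maps onto, and carries the brute-force
oracles used to validate both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import MeasurementRecord
from .patterns import SamplingOperator

__all__ = [
    "ReconSpec",
    "ReconstructionError",
    "initialize",
    "gradient_step",
    "prox_step",
    "pgd_reconstruct",
    "least_squares_oracle",
]

REGULARIZERS = ("l1", "tv", "none")


class ReconstructionError(RuntimeError):
    """Raised when the iteration diverges under conditions that guarantee descent."""


@dataclass
class ReconSpec:
    """Hyperparameters shared by the iterative solver and the unrolled network.

    ``step_size`` is the gradient step rho; ``reg_weight`` the regularization
    weight lambda; ``stage_count``/``channels`` size the unrolled network;
    ``ratio`` is the sampling ratio m/N the acquisition was made at.
    """

    max_iters: int = 500
    step_size: float = 1.0
    reg_weight: float = 0.0
    regularizer: str = "none"
    tolerance: float = 1e-6
    stage_count: int = 3
    channels: int = 16
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be nonnegative")
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if not (0 < self.ratio <= 1):
            raise ValueError("ratio must be in (0, 1]")
        if self.stage_count < 1 or self.channels < 1:
            raise ValueError("stage_count and channels must be >= 1")
        if self.max_iters < 1 or self.tolerance <= 0:
            raise ValueError("max_iters must be >= 1 and tolerance positive")


def _rows(record: MeasurementRecord, op: SamplingOperator) -> np.ndarray:
    idx = record.pattern_indices
    if idx.min() < 0 or idx.max() >= op.n_rows:
        raise IndexError("pattern index out of range for this operator")
    return op.values[idx]


def initialize(record: MeasurementRecord, op: SamplingOperator) -> np.ndarray:
    """Back-projection initial estimate A^T y, reshaped to H x W.

    Parameter-free bridge from the m-dimensional measurement domain to the
    image domain; exact inverse when A is square orthonormal (Hadamard).
    """
    a = _rows(record, op)
    return (a.T @ record.values).reshape(op.height, op.width)


def gradient_step(x: np.ndarray, y: np.ndarray, a: np.ndarray, rho: float) -> np.ndarray:
    """One data-fidelity descent step z = x - rho * A^T (A x - y) (flattened)."""
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    return x - rho * (a.T @ (a @ x - y))


def prox_step(z: np.ndarray, reg_weight: float, regularizer: str = "l1",
              tv_tol: float = 1e-4, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Proximal mapping argmin_x 0.5||x - z||^2 + reg_weight * R(x).

    l1 has the closed-form soft threshold; tv is solved iteratively
    (Chambolle's dual method) to ``tv_tol``; 'none' is the identity.
    """
    if reg_weight < 0:
        raise ValueError("reg_weight must be nonnegative")
    z = np.asarray(z, dtype=np.float64)
    if regularizer == "none" or reg_weight == 0:
        return z.copy()
    if regularizer == "l1":
        return np.sign(z) * np.maximum(np.abs(z) - reg_weight, 0.0)
    if regularizer == "tv":
        from skimage.restoration import denoise_tv_chambolle

        z2 = z.reshape(shape) if shape is not None else z
        if z2.ndim != 2:
            raise ValueError("tv prox needs a 2-D array or an explicit shape")
        out = denoise_tv_chambolle(z2, weight=reg_weight, eps=tv_tol, max_num_iter=200)
        return out.reshape(z.shape)
    raise ValueError(f"unknown regularizer {regularizer!r}")


def _tv_value(x2: np.ndarray) -> float:
    # isotropic TV, matching the Chambolle solver's penalty
    gx = np.diff(x2, axis=0)
    gy = np.diff(x2, axis=1)
    gxp = np.zeros_like(x2)
    gyp = np.zeros_like(x2)
    gxp[:-1] = gx
    gyp[:, :-1] = gy
    return float(np.sum(np.hypot(gxp, gyp)))


def objective(x: np.ndarray, y: np.ndarray, a: np.ndarray, reg_weight: float,
              regularizer: str, shape: tuple[int, int] | None = None) -> float:
    """The regularized objective 0.5||Ax - y||^2 + lambda R(x)."""
    xf = np.asarray(x, dtype=np.float64).reshape(-1)
    resid = a @ xf - y
    val = 0.5 * float(resid @ resid)
    if reg_weight > 0 and regularizer == "l1":
        val += reg_weight * float(np.abs(xf).sum())
    elif reg_weight > 0 and regularizer == "tv":
        val += reg_weight * _tv_value(xf.reshape(shape))
    return val


def spectral_bound(a: np.ndarray) -> float:
    """||A^T A||_2, the Lipschitz constant of the data-fidelity gradient."""
    if min(a.shape) <= 512:
        s = np.linalg.svd(a, compute_uv=False)
        return float(s[0] ** 2)
    # power iteration on A^T A for larger problems
    v = np.ones(a.shape[1]) / np.sqrt(a.shape[1])
    lam = 0.0
    for _ in range(100):
        w = a.T @ (a @ v)
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0:
            return 0.0
        v = w / lam_new
        if abs(lam_new - lam) <= 1e-12 * max(1.0, lam_new):
            break
        lam = lam_new
    return lam_new


def pgd_reconstruct(
    record: MeasurementRecord,
    op: SamplingOperator,
    spec: ReconSpec,
    nonneg: bool = False,
) -> tuple[np.ndarray, dict]:
    """Iterate gradient/prox steps from the A^T y initialization.

    The prox threshold is rho*lambda per iteration, the scaling under which
    the iteration minimizes the stated objective.  Stops when the relative
    change of the estimate falls below ``spec.tolerance`` or at
    ``spec.max_iters``.  If the step size is within the guaranteed-descent
    regime (rho <= 1/||A^T A||) and the objective still rises, the run aborts
    with :class:`ReconstructionError` — that indicates a defect, not noise.

    Returns ``(estimate_2d, info)`` with the per-iteration objective log.
    """
    a = _rows(record, op)
    y = record.values
    shape = (op.height, op.width)
    x = initialize(record, op).reshape(-1)
    rho, lam = spec.step_size, spec.reg_weight

    stable = rho <= 1.0 / max(spectral_bound(a), 1e-300)
    objs = [objective(x, y, a, lam, spec.regularizer, shape)]
    for it in range(spec.max_iters):
        z = gradient_step(x, y, a, rho)
        x_new = prox_step(z, rho * lam, spec.regularizer, shape=shape)
        if nonneg:
            x_new = np.maximum(x_new, 0.0)
        obj = objective(x_new, y, a, lam, spec.regularizer, shape)
        if stable and spec.regularizer in ("none", "l1") and not nonneg:
            if obj > objs[-1] + 1e-9 * (1.0 + abs(objs[-1])):
                raise ReconstructionError(
                    f"objective rose at iteration {it} despite a stable step size"
                )
        objs.append(obj)
        denom = max(np.linalg.norm(x), 1e-300)
        rel_change = np.linalg.norm(x_new - x) / denom
        x = x_new
        if rel_change < spec.tolerance:
            break
    info = {"objectives": objs, "iterations": len(objs) - 1}
    return x.reshape(shape), info


def least_squares_oracle(record: MeasurementRecord, op: SamplingOperator,
                         max_pixels: int = 4096) -> np.ndarray:
    """Minimum-norm least-squares solution by dense pseudoinversion.

    Independent reference for the lambda=0 solver path; guarded to small
    problems because it materializes the full pseudoinverse.
    """
    if op.n_cols > max_pixels:
        raise ValueError(f"oracle limited to N <= {max_pixels}")
    a = _rows(record, op)
    sol, *_ = np.linalg.lstsq(a, record.values, rcond=None)
    return sol.reshape(op.height, op.width)
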