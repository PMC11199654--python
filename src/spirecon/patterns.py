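"""Bipolar single-pixel sampling patterns.

A single-pixel acquisition measures inner products between the scene and a
sequence of spatial modulation patterns displayed on a binary modulator
(a DMD).  Patterns here are *bipolar*: every entry is +1/sqrt(N) or
-1/sqrt(N), realized optically as two complementary binary patterns whose
detector readings are differenced.

This module constructs such operators (random, Hadamard, or learned from
training images by minimizing the information loss of the A^T A x back
projection with a straight-through sign gradient), subsets them for
sampling-ratio augmentation, and merges / unmerges them for the high-speed
zoom imaging mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import hadamard as _hadamard

from ._rng import derive_seed, substream
from .optim import AdamOptimizer

__all__ = [
    "SamplingOperator",
    "ZoomSpec",
    "bipolarize",
    "random_operator",
    "hadamard_operator",
    "matrix_loss",
    "learn_patterns",
    "select_subset",
    "merge_patterns",
    "unmerge_patterns",
    "augmentation_capacity",
]

PROVENANCES = ("learned", "hadamard", "random", "merged", "unmerged")


@dataclass
class SamplingOperator:
    """An M x N bipolar sampling matrix A with its real-valued parent Phi.

    ``values`` holds the bipolarized matrix (entries exactly +-1/sqrt(N));
    each row reshapes losslessly to an ``height x width`` pattern.
    """

    values: np.ndarray
    height: int
    width: int
    provenance: str
    parent: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("pattern matrix must be 2-D")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.height * self.width != self.values.shape[1]:
            raise ValueError(
                f"N={self.values.shape[1]} does not equal "
                f"height*width={self.height * self.width}"
            )
        if not (1 <= self.n_rows):
            raise ValueError("operator needs at least one row")
        if self.provenance in ("learned", "random", "hadamard") and self.n_rows > self.n_cols:
            raise ValueError("M must not exceed N for learned/random/hadamard operators")
        if not self.is_bipolar:
            raise ValueError("entries must be exactly +-1/sqrt(N)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def scale(self) -> float:
        return 1.0 / math.sqrt(self.n_cols)

    @property
    def is_bipolar(self) -> bool:
        s = self.scale
        return bool(np.all((self.values == s) | (self.values == -s)))

    def patterns(self) -> np.ndarray:
        """Rows as an (M, H, W) stack of 2-D patterns."""
        return self.values.reshape(self.n_rows, self.height, self.width)

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the operator to an .npz container."""
        path = Path(path)
        payload = {
            "values": self.values,
            "height": np.int64(self.height),
            "width": np.int64(self.width),
            "provenance": np.bytes_(self.provenance.encode()),
            "seed": np.int64(-1 if self.seed is None else self.seed),
        }
        if self.parent is not None:
            payload["parent"] = self.parent
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "SamplingOperator":
        with np.load(path) as data:
            seed = int(data["seed"])
            return cls(
                values=data["values"],
                height=int(data["height"]),
                width=int(data["width"]),
                provenance=bytes(data["provenance"]).decode(),
                parent=data["parent"] if "parent" in data else None,
                seed=None if seed < 0 else seed,
            )

    def export_pattern_images(self, out_dir: str | Path, limit: int | None = None) -> list[Path]:
        """Dump per-row patterns as 8-bit PNGs for visual inspection."""
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for i, pat in enumerate(self.patterns()):
            if limit is not None and i >= limit:
                break
            img = ((pat > 0) * 255).astype(np.uint8)
            p = out_dir / f"pattern_{i:05d}.png"
            Image.fromarray(img).save(p)
            written.append(p)
        return written


@dataclass(frozen=True)
class ZoomSpec:
    """Neighborhood-merge zoom factor and the grid sizes it relates.

    A z x z merge turns a ``source_side``-pixel pattern grid into a
    ``source_side / z`` one while keeping the field of view.
    """

    factor: int
    source_side: int

    def __post_init__(self) -> None:
        if self.factor not in (1, 2, 4):
            raise ValueError("zoom factor must be 1, 2 or 4")
        if self.source_side <= 0 or self.source_side % self.factor:
            raise ValueError(
                f"zoom factor {self.factor} does not divide side {self.source_side}"
            )

    @property
    def merged_side(self) -> int:
        return self.source_side // self.factor


# ---------------------------------------------------------------------------
# construction


def bipolarize(parent: np.ndarray, height: int, width: int,
               provenance: str = "random", seed: int | None = None) -> SamplingOperator:
    """Map a real parent matrix Phi to the bipolar operator Sign(Phi)/sqrt(N).

    Sign maps non-negative entries (zero included) to +1 and the rest to -1.
    """
    parent = np.asarray(parent, dtype=np.float64)
    if parent.ndim != 2:
        raise ValueError("parent matrix must be 2-D")
    if not np.all(np.isfinite(parent)):
        r, c = np.argwhere(~np.isfinite(parent))[0]
        raise ValueError(f"non-finite parent entry at row {r}, col {c}")
    n = parent.shape[1]
    values = np.where(parent >= 0, 1.0, -1.0) / math.sqrt(n)
    return SamplingOperator(values=values, height=height, width=width,
                            provenance=provenance, parent=parent, seed=seed)


def random_operator(n_rows: int, height: int, width: int, seed: int) -> SamplingOperator:
    """Bipolarized i.i.d. standard-normal parent; the learning initializer."""
    rng = substream(seed, "patterns-init")
    parent = rng.standard_normal((n_rows, height * width))
    return bipolarize(parent, height, width, provenance="random", seed=seed)


def hadamard_operator(side: int, n_rows: int | None = None) -> SamplingOperator:
    """First ``n_rows`` rows of a Hadamard matrix scaled by 1/sqrt(N).

    With ``n_rows == N`` the operator is orthonormal: A^T A = I, so the back
    projection A^T y inverts a noiseless measurement exactly.
    """
    n = side * side
    if n & (n - 1):
        raise ValueError("side*side must be a power of two for Hadamard patterns")
    mat = _hadamard(n).astype(np.float64)
    if n_rows is None:
        n_rows = n
    values = mat[:n_rows] / math.sqrt(n)
    return SamplingOperator(values=values, height=side, width=side, provenance="hadamard")


# ---------------------------------------------------------------------------
# pattern learning


def matrix_loss(op_values: np.ndarray, images: np.ndarray) -> float:
    """Mean over images of (1/N) ||A^T A x - x||_2^2.

    The squared error between an image and the back projection of its own
    simulated measurement; small values mean the pattern set preserves the
    image-domain information of the training distribution.
    """
    a = np.asarray(op_values, dtype=np.float64)
    x = np.atleast_2d(np.asarray(images, dtype=np.float64))  # (B, N)
    n = a.shape[1]
    z = a @ x.T                       # (M, B)
    e = a.T @ z - x.T                 # (N, B)
    return float(np.sum(e * e) / (n * x.shape[0]))


def learn_patterns(
    training_images: list,
    n_rows: int,
    steps: int,
    seed: int,
    *,
    lr: float = 2e-4,
    betas: tuple[float, float] = (0.9, 0.999),
    batch_size: int = 16,
    log_every: int = 50,
) -> tuple[SamplingOperator, dict]:
    """Learn bipolar patterns by minimizing :func:`matrix_loss` over Phi.

    The bipolarization Sign(.) is non-differentiable; its backward pass uses
    the straight-through convention (derivative treated as 1), so gradients
    w.r.t. A flow unchanged into Phi.  Optimization is Adam on minibatches.
    The returned operator is the checkpoint with the lowest full-training-set
    loss, so it is never worse than the random initialization.

    Returns ``(operator, log)`` where ``log`` has the checkpoint steps and
    losses plus the initial/final loss.
    """
    from .forward_model import ImageScene

    if len(training_images) == 0:
        raise ValueError("need at least one training image")
    arrs = []
    for im in training_images:
        arr = im.intensities if isinstance(im, ImageScene) else np.asarray(im, float)
        arrs.append(arr)
    h, w = arrs[0].shape
    if any(a.shape != (h, w) for a in arrs):
        raise ValueError("all training images must share the same height and width")
    n = h * w
    if not (1 <= n_rows <= n):
        raise ValueError(f"M={n_rows} must satisfy 1 <= M <= N={n}")

    x_all = np.stack([a.reshape(-1) for a in arrs])  # (L, N)
    peak = x_all.max()
    if peak > 0:
        x_all = x_all / peak  # scale-free objective; Sign ignores positive scale

    rng = substream(seed, "patterns-learn")
    phi = substream(seed, "patterns-init").standard_normal((n_rows, n))
    sqrt_n = math.sqrt(n)

    def bip(p: np.ndarray) -> np.ndarray:
        return np.where(p >= 0, 1.0, -1.0) / sqrt_n

    opt = AdamOptimizer(lr=lr, betas=betas)
    state = opt.init(phi)

    best_phi = phi.copy()
    best_loss = matrix_loss(bip(phi), x_all)
    log_steps, log_losses = [0], [best_loss]

    n_imgs = x_all.shape[0]
    for step in range(1, steps + 1):
        idx = rng.choice(n_imgs, size=min(batch_size, n_imgs), replace=False)
        xb = x_all[idx]                      # (B, N)
        a = bip(phi)
        z = a @ xb.T                         # (M, B)
        e = a.T @ z - xb.T                   # (N, B)
        # d/dA of mean (1/N)||A^T A x - x||^2 ; straight-through to Phi.
        grad_a = (2.0 / (n * xb.shape[0])) * (z @ e.T + (a @ e) @ xb)
        grad_phi = grad_a / sqrt_n
        phi = opt.step(state, phi, grad_phi)
        if step % log_every == 0 or step == steps:
            loss = matrix_loss(bip(phi), x_all)
            log_steps.append(step)
            log_losses.append(loss)
            if loss < best_loss:
                best_loss = loss
                best_phi = phi.copy()

    op = bipolarize(best_phi, h, w, provenance="learned", seed=seed)
    log = {
        "steps": log_steps,
        "losses": log_losses,
        "initial_loss": log_losses[0],
        "final_loss": best_loss,
    }
    return op, log


# ---------------------------------------------------------------------------
# subsetting (sampling-ratio augmentation)


def augmentation_capacity(n_rows: int) -> int:
    """Number of distinct non-empty row subsets: 2**M - 1."""
    return 2**n_rows - 1


def select_subset(op: SamplingOperator, record, m: int, seed: int):
    """Randomly keep ``m`` of the M pattern/measurement pairs.

    Sampling is without replacement; the original relative row order is
    preserved so the pattern <-> measurement pairing stays auditable.  For a
    noiseless record the subset satisfies y' = A' x exactly, at the reduced
    sampling ratio m/N.
    """
    from .forward_model import MeasurementRecord

    if not (1 <= m <= op.n_rows):
        raise ValueError(f"m={m} must be in [1, {op.n_rows}]")
    if record.values.shape[0] != op.n_rows or not np.array_equal(
        record.pattern_indices, np.arange(op.n_rows)
    ):
        raise ValueError("record does not pair one-to-one with the operator rows")

    rng = substream(seed, "subset")
    idx = np.sort(rng.choice(op.n_rows, size=m, replace=False))

    new_op = replace(
        op,
        values=op.values[idx],
        parent=None if op.parent is None else op.parent[idx],
        meta={**op.meta, "source_rows": idx.tolist()},
    )
    new_record = MeasurementRecord(
        values=record.values[idx],
        pattern_indices=np.arange(m),
        noise_model=record.noise_model,
        photon_scale=record.photon_scale,
        counts_pos=None if record.counts_pos is None else record.counts_pos[idx],
        counts_neg=None if record.counts_neg is None else record.counts_neg[idx],
        seed=record.seed,
        meta={**record.meta, "source_rows": idx.tolist()},
    )
    return new_op, new_record


# ---------------------------------------------------------------------------
# zoom mode: neighborhood merge / unmerge


def merge_patterns(op: SamplingOperator, zoom: ZoomSpec) -> SamplingOperator:
    """Average-pool each pattern z x z, then re-bipolarize on the merged grid.

    Scales the modulation resolution down (e.g. 128x128 -> 32x32 under a 4x4
    merge) while keeping the field of view, for high-speed zoom sampling.
    """
    if op.height != zoom.source_side or op.width != zoom.source_side:
        raise ValueError("operator grid does not match the zoom source side")
    z = zoom.factor
    side = zoom.merged_side
    pooled = op.patterns().reshape(op.n_rows, side, z, side, z).mean(axis=(2, 4))
    parent = pooled.reshape(op.n_rows, side * side)
    merged = bipolarize(parent, side, side, provenance="merged", seed=op.seed)
    merged.meta["zoom_factor"] = z
    merged.meta["source_side"] = zoom.source_side
    return merged


def unmerge_patterns(op: SamplingOperator, zoom: ZoomSpec) -> SamplingOperator:
    """Nearest-neighbor upscale merged patterns back to the source grid.

    Each merged pixel is replicated z x z; entries are rescaled to the source
    convention +-1/sqrt(N_source).  Feeding these to a reconstruction network
    yields source-resolution estimates from merged-grid measurements without
    any architectural change.
    """
    if op.height != zoom.merged_side or op.width != zoom.merged_side:
        raise ValueError("operator grid does not match the zoom merged side")
    z = zoom.factor
    side = zoom.source_side
    up = np.repeat(np.repeat(op.patterns(), z, axis=1), z, axis=2)
    values = np.where(up >= 0, 1.0, -1.0) / math.sqrt(side * side)
    out = SamplingOperator(
        values=values.reshape(op.n_rows, side * side),
        height=side,
        width=side,
        provenance="unmerged",
        seed=op.seed,
        meta={"zoom_factor": z, "merged_side": zoom.merged_side},
    )
    return out
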