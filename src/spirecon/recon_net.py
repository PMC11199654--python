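"""Ratio-conditioned unrolled reconstruction network.

The network unrolls K iterations of proximal gradient descent into a
feed-forward model.  An initialization subnet maps the measurement to the
image domain by the parameter-free back projection A^T y; an extraction
convolution lifts it to a C-channel feature stack, gated by a learned scalar
function of the sampling ratio; each of the K stage modules applies the
*exact* data-fidelity gradient step (with a learnable per-stage step size)
to an image-domain anchor and a small convolutional residual block as the
learned proximal operator; a recovery convolution returns to the image
domain.

Because the physics step is exact and A enters only at run time, a single
trained model reconstructs at any number of measurements m <= M — including
the zoom mode, where nearest-neighbor-upscaled merged patterns are
substituted for A with no architectural change.

Training minimizes the mean absolute reconstruction error with per-sample
random subset augmentation: each pair (y, x) is re-sampled to a random ratio
m/N every time it is visited, which from one pair can in principle generate
2^M - 1 distinct training pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from ._rng import derive_seed, substream
from .forward_model import ImageScene, MeasurementRecord
from .optim import AdamOptimizer
from .patterns import SamplingOperator, ZoomSpec, select_subset, unmerge_patterns
from .recon_classical import ReconSpec

__all__ = ["TrainingPair", "UnrolledNetwork", "build_network", "augment_pair", "train"]


@dataclass
class TrainingPair:
    """A measurement / ground-truth pair with its pattern reference and ratio."""

    record: MeasurementRecord
    scene: ImageScene
    operator: SamplingOperator
    ratio: float

    def __post_init__(self) -> None:
        if self.record.n_measurements != self.operator.n_rows:
            raise ValueError("measurement length does not match operator rows")
        if self.scene.height * self.scene.width != self.operator.n_cols:
            raise ValueError("scene size does not match operator columns")


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    cout, cin = shape[0], shape[1]
    std = math.sqrt(2.0 / ((cin + cout) * 9))
    return rng.normal(0.0, std, size=shape)


class UnrolledNetwork:
    """Parameter registry + pure forward function of (y, A, r).

    Holds no state between calls; two forward passes with identical inputs
    and parameters are bitwise identical.
    """

    def __init__(self, spec: ReconSpec, seed: int):
        self.spec = spec
        self.seed = seed
        c, k = spec.channels, spec.stage_count
        p: dict[str, ad.Var] = {}

        def param(name: str, value: np.ndarray) -> None:
            p[name] = ad.Var(value, name=name)

        rng = substream(seed, "net-init")
        param("ext_w", _glorot(rng, (c, 1, 3, 3)))
        param("ext_b", np.zeros(c))
        # ratio gate s(r) = exp(a + b*log r); b = -1 makes s ~ 1/r at init,
        # undoing the ~r amplitude of the A^T y back projection.
        param("gate_a", np.array(0.0))
        param("gate_b", np.array(-1.0))
        for i in range(k):
            param(f"s{i}_out_w", _glorot(rng, (1, c, 3, 3)))
            param(f"s{i}_out_b", np.zeros(1))
            param(f"s{i}_rho", np.array(float(spec.step_size)))
            param(f"s{i}_in_w", _glorot(rng, (c, 1, 3, 3)))
            param(f"s{i}_in_b", np.zeros(c))
            param(f"s{i}_r1_w", _glorot(rng, (c, c, 3, 3)))
            param(f"s{i}_r1_b", np.zeros(c))
            param(f"s{i}_r2_w", _glorot(rng, (c, c, 3, 3)))
            param(f"s{i}_r2_b", np.zeros(c))
        param("rec_w", _glorot(rng, (1, c, 3, 3)))
        param("rec_b", np.zeros(1))
        self.params = p

    # ---- configuration helpers ------------------------------------------

    def parameters(self) -> dict[str, ad.Var]:
        return self.params

    def zero_grad(self) -> None:
        for v in self.params.values():
            v.zero_grad()

    def disable_learned(self, rho: float) -> "UnrolledNetwork":
        """Identity-wired copy: the forward pass becomes K literal gradient steps.

        Extraction/anchoring convolutions are set to channel-0 delta kernels,
        the residual blocks and the ratio gate to zero/one, and every stage
        step size to ``rho`` — the network then reproduces classical PGD with
        an identity prox, step for step.
        """
        other = UnrolledNetwork(self.spec, self.seed)
        c = self.spec.channels
        delta_up = np.zeros((c, 1, 3, 3))
        delta_up[0, 0, 1, 1] = 1.0
        delta_down = np.zeros((1, c, 3, 3))
        delta_down[0, 0, 1, 1] = 1.0
        p = other.params
        p["ext_w"].value = delta_up.copy()
        p["ext_b"].value = np.zeros(c)
        p["gate_a"].value = np.array(0.0)
        p["gate_b"].value = np.array(0.0)
        for i in range(self.spec.stage_count):
            p[f"s{i}_out_w"].value = delta_down.copy()
            p[f"s{i}_out_b"].value = np.zeros(1)
            p[f"s{i}_rho"].value = np.array(float(rho))
            p[f"s{i}_in_w"].value = delta_up.copy()
            p[f"s{i}_in_b"].value = np.zeros(c)
            p[f"s{i}_r1_w"].value = np.zeros((c, c, 3, 3))
            p[f"s{i}_r1_b"].value = np.zeros(c)
            p[f"s{i}_r2_w"].value = np.zeros((c, c, 3, 3))
            p[f"s{i}_r2_b"].value = np.zeros(c)
        p["rec_w"].value = delta_down.copy()
        p["rec_b"].value = np.zeros(1)
        return other

    # ---- forward ---------------------------------------------------------

    def _forward_var(self, y: np.ndarray, a: np.ndarray,
                     r: float, shape: tuple[int, int]) -> ad.Var:
        if not (0 < r <= 1):
            raise ValueError("sampling ratio r must be in (0, 1]")
        if a.shape[0] != y.shape[0]:
            raise ValueError("measurement length does not match pattern count")
        h, w = shape
        if a.shape[1] != h * w:
            raise ValueError("pattern length does not match image shape")
        p = self.params

        x0 = ad.Var((a.T @ y).reshape(1, h, w), name="x0")  # F_IS: back projection
        feats = ad.conv2d(x0, p["ext_w"], p["ext_b"])

        logr = math.log(r)
        gate_a, gate_b = p["gate_a"], p["gate_b"]
        u = ad.Var(gate_a.value + logr * gate_b.value, parents=(gate_a, gate_b),
                   bw=lambda g: (gate_a.accumulate(g), gate_b.accumulate(g * logr)),
                   name="gate_affine")
        feats = ad.mul_scalar(feats, ad.exp_scalar(u))

        for i in range(self.spec.stage_count):
            anchor = ad.conv2d(feats, p[f"s{i}_out_w"], p[f"s{i}_out_b"])
            z = ad.physics_step(anchor, p[f"s{i}_rho"], a, y)
            fz = ad.conv2d(z, p[f"s{i}_in_w"], p[f"s{i}_in_b"])
            h1 = ad.relu(ad.conv2d(fz, p[f"s{i}_r1_w"], p[f"s{i}_r1_b"]))
            h2 = ad.conv2d(h1, p[f"s{i}_r2_w"], p[f"s{i}_r2_b"])
            feats = ad.add(fz, h2)

        out = ad.conv2d(feats, p["rec_w"], p["rec_b"])
        return out

    def forward(self, y: np.ndarray, a: np.ndarray, r: float,
                shape: tuple[int, int]) -> np.ndarray:
        """Single deterministic pass; accepts any m <= M without rebuilding."""
        out = self._forward_var(np.asarray(y, float), np.asarray(a, float), r, shape)
        return out.value.reshape(shape)

    def reconstruct(self, record: MeasurementRecord, op: SamplingOperator,
                    r: float | None = None) -> np.ndarray:
        """Reconstruct from a record; r defaults to m / N of the acquisition."""
        a = op.values[record.pattern_indices]
        if r is None:
            r = record.n_measurements / op.n_cols
        return self.forward(record.values, a, r, (op.height, op.width))

    def zoom_reconstruct(self, record: MeasurementRecord, op_merged: SamplingOperator,
                         zoom: ZoomSpec, r: float | None = None) -> np.ndarray:
        """Source-resolution reconstruction from merged-grid measurements.

        Substitutes the nearest-neighbor-upscaled patterns for A with no
        architectural change.  The conditioning ratio defaults to
        m / merged-pixel-count: upscaled patterns are block-constant, so the
        back projection has the amplitude of an acquisition on the merged
        grid, and that is the scale the ratio gate must compensate.  The
        *reported* sampling ratio of the acquisition is still m / N_source.
        """
        op_src = unmerge_patterns(op_merged, zoom) if zoom.factor > 1 else op_merged
        a = op_src.values[record.pattern_indices]
        if r is None:
            r = record.n_measurements / (zoom.merged_side**2)
        return self.forward(record.values, a, r, (op_src.height, op_src.width))

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path, pattern_fingerprint: str | None = None) -> None:
        meta = {
            "spec": {
                "max_iters": self.spec.max_iters,
                "step_size": self.spec.step_size,
                "reg_weight": self.spec.reg_weight,
                "regularizer": self.spec.regularizer,
                "tolerance": self.spec.tolerance,
                "stage_count": self.spec.stage_count,
                "channels": self.spec.channels,
                "ratio": self.spec.ratio,
            },
            "seed": self.seed,
            "pattern_fingerprint": pattern_fingerprint,
            "measurement_normalization": "none (raw A^T y; ratio gate rescales)",
        }
        arrays = {name: var.value for name, var in self.params.items()}
        np.savez(path, __meta__=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UnrolledNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = cls(ReconSpec(**meta["spec"]), seed=meta["seed"])
            for name, var in net.params.items():
                var.value = np.array(data[name])
        return net


def build_network(spec: ReconSpec, seed: int) -> UnrolledNetwork:
    """Construct an unrolled network with deterministic initialization."""
    return UnrolledNetwork(spec, seed)


# ---------------------------------------------------------------------------
# training


def augment_pair(pair: TrainingPair, op: SamplingOperator, seed: int) -> TrainingPair:
    """Random-ratio augmentation: keep a uniform m in {1..M} of the pairs.

    Delegates to :func:`spirecon.patterns.select_subset`, so the subset
    satisfies y' = A' x on noiseless data; the new ratio is m/N <= M/N.
    """
    m = int(substream(seed, "augment-m").integers(1, op.n_rows + 1))
    sub_op, sub_rec = select_subset(op, pair.record, m, derive_seed(seed, "augment-sel"))
    return TrainingPair(record=sub_rec, scene=pair.scene, operator=sub_op,
                        ratio=m / op.n_cols)


def train(
    net: UnrolledNetwork,
    dataset: list[TrainingPair],
    op: SamplingOperator,
    epochs: int,
    batch_size: int = 16,
    seed: int = 0,
    lr: float = 2e-4,
    lr_final: float = 2e-6,
    augment: bool = True,
) -> dict:
    """End-to-end training of all network parameters.

    Mean absolute error loss, Adam (0.9 / 0.999) with a geometric learning
    rate decay from ``lr`` to ``lr_final`` over the run, per-sample random
    subset augmentation, fully seeded.  Returns a log with per-epoch mean
    losses; aborts on a non-finite loss.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    opt = AdamOptimizer(lr=lr)
    states = {name: opt.init(var.value) for name, var in net.params.items()}
    order_rng = substream(seed, "train-order")
    n = len(dataset)
    steps_total = max(epochs * math.ceil(n / batch_size), 1)
    decay = (lr_final / lr) ** (1.0 / max(steps_total - 1, 1))

    epoch_losses: list[float] = []
    step = 0
    for epoch in range(epochs):
        perm = order_rng.permutation(n)
        batch_losses: list[float] = []
        for start in range(0, n, batch_size):
            batch = perm[start:start + batch_size]
            net.zero_grad()
            total = 0.0
            for j in batch:
                pair = dataset[j]
                if augment:
                    pair = augment_pair(pair, op, derive_seed(seed, "aug", epoch, int(j)))
                a = pair.operator.values[pair.record.pattern_indices]
                out = net._forward_var(
                    pair.record.values, a, pair.ratio,
                    (pair.scene.height, pair.scene.width),
                )
                loss = ad.mean_abs_error(out, pair.scene.intensities[None, :, :])
                ad.backward(loss)
                total += float(loss.value)
            mean_loss = total / len(batch)
            if not np.isfinite(mean_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}"
                )
            batch_losses.append(mean_loss)
            opt.lr = lr * decay**step
            for name, var in net.params.items():
                if var.grad is None:
                    continue
                var.value = opt.step(states[name], var.value, var.grad / len(batch))
            step += 1
        epoch_losses.append(float(np.mean(batch_losses)))
    return {"epoch_losses": epoch_losses, "steps": step}
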