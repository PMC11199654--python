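"""Synthetic fluorescent scenes and paired datasets.

No public acquisition data exists for this kind of instrument, so every
other module is exercised on synthetic stand-ins for the three sample
classes the method targets: sparse bright microspheres (5 um beads, about
9 px across at the instrument's 20x scale on a 128 px field), nuclei
(smooth elliptical blobs with bright internal speckle), and thin
curvilinear F-actin-like filaments.  A block-constant kind supports zoom-
mode experiments.  Intensities are expected photons per pixel per pattern
exposure, so photon-budget scenarios are directly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import derive_seed, substream
from .forward_model import ImageScene, MeasurementRecord, measure, measure_photons
from .patterns import SamplingOperator

__all__ = ["SceneSpec", "gen_scene", "sparsity", "make_dataset", "default_spec",
           "photon_scale_for_total"]

KINDS = ("microspheres", "nucleus", "filaments", "block_constant")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene.

    ``count`` is the number of features (disks / blobs / filaments / active
    blocks); ``feature_size`` is the characteristic radius or width in
    pixels; intensities are drawn from ``intensity_range`` on top of
    ``background``.  ``mask_margin`` sets the valid-pixel threshold above
    background.
    """

    kind: str
    height: int = 32
    width: int = 32
    count: int = 4
    feature_size: float = 2.0
    intensity_range: tuple[float, float] = (0.6, 1.0)
    background: float = 0.02
    mask_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if self.height <= 0 or self.width <= 0 or self.feature_size <= 0:
            raise ValueError("sizes must be positive")
        if self.count < 0 or self.background < 0:
            raise ValueError("count and background must be nonnegative")


#: defaults per kind and grid side.  Counts and sizes scale with area so the
#: sparsity ordering microspheres < filaments < nucleus holds at any side;
#: the 128-px microsphere preset occupies ~1000 valid pixels (13 disks of
#: radius 4.5 px, a 5 um bead at the instrument's 20x scale), the
#: photon-budget scenario's scene.
def default_spec(kind: str, side: int = 32, seed: int = 0) -> SceneSpec:
    scale = side / 128.0
    if kind == "microspheres":
        return SceneSpec(kind, side, side, count=max(1, round(13 * scale**2)),
                         feature_size=max(1.0, 4.5 * scale), seed=seed)
    if kind == "nucleus":
        return SceneSpec(kind, side, side, count=max(2, round(3 * scale**2)),
                         feature_size=max(6.0, 0.22 * side),
                         intensity_range=(0.35, 0.7), seed=seed)
    if kind == "filaments":
        return SceneSpec(kind, side, side, count=max(2, round(14 * scale**2)),
                         feature_size=max(1.0, 1.5 * scale),
                         intensity_range=(0.5, 0.9), seed=seed)
    if kind == "block_constant":
        return SceneSpec(kind, side, side, count=max(1, round(20 * scale**2)),
                         feature_size=max(2.0, 4 * scale), seed=seed)
    raise ValueError(f"unknown scene kind {kind!r}")


def _disk_stamp(canvas: np.ndarray, cy: float, cx: float, radius: float,
                amplitude: float) -> None:
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    canvas += amplitude * np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _gen_microspheres(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((spec.height, spec.width))
    r = spec.feature_size
    centers: list[tuple[float, float]] = []
    placed = 0
    attempts = 0
    max_attempts = 200 * max(spec.count, 1)
    lo, hi = spec.intensity_range
    while placed < spec.count:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.count} non-overlapping disks of radius {r} "
                f"on a {spec.height}x{spec.width} grid after {max_attempts} tries"
            )
        attempts += 1
        cy = rng.uniform(r, spec.height - r)
        cx = rng.uniform(r, spec.width - r)
        if any(np.hypot(cy - py, cx - px) < 2 * r + 1 for py, px in centers):
            continue
        _disk_stamp(img, cy, cx, r, rng.uniform(lo, hi))
        centers.append((cy, cx))
        placed += 1
    return img


def _gen_nucleus(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((spec.height, spec.width))
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    lo, hi = spec.intensity_range
    for _ in range(spec.count):
        cy = rng.uniform(0.25 * spec.height, 0.75 * spec.height)
        cx = rng.uniform(0.25 * spec.width, 0.75 * spec.width)
        ax_a = spec.feature_size * rng.uniform(0.7, 1.2)
        ax_b = spec.feature_size * rng.uniform(0.5, 0.9)
        theta = rng.uniform(0, np.pi)
        u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        q = (u / ax_a) ** 2 + (v / ax_b) ** 2
        body = np.exp(-2.0 * q**2)  # flat-topped blob with a soft rim
        amp = rng.uniform(lo, hi)
        # bright internal puncta ("speckles")
        speck = np.zeros_like(img)
        n_speck = max(3, int(ax_a * ax_b / 8))
        for _ in range(n_speck):
            sy = np.clip(cy + rng.normal(0, ax_a / 2), 0, spec.height - 1)
            sx = np.clip(cx + rng.normal(0, ax_b / 2), 0, spec.width - 1)
            _disk_stamp(speck, sy, sx, 1.0, rng.uniform(0.3, 0.8))
        img += amp * body * (1.0 + gaussian_filter(speck, 0.7))
    return img


def _gen_filaments(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((spec.height, spec.width))
    lo, hi = spec.intensity_range
    n_steps = 4 * (spec.height + spec.width)
    for _ in range(spec.count):
        y = rng.uniform(0, spec.height)
        x = rng.uniform(0, spec.width)
        heading = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(lo, hi)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.12)  # smooth curvature
            y += 0.5 * np.sin(heading)
            x += 0.5 * np.cos(heading)
            if not (0 <= y < spec.height and 0 <= x < spec.width):
                break
            iy, ix = int(y), int(x)
            fy, fx = y - iy, x - ix
            # bilinear splat: anti-aliased ~1 px stroke
            for dy in (0, 1):
                for dx in (0, 1):
                    py, px = iy + dy, ix + dx
                    if py < spec.height and px < spec.width:
                        wgt = (fy if dy else 1 - fy) * (fx if dx else 1 - fx)
                        img[py, px] = max(img[py, px], amp * wgt)
    if spec.feature_size > 1.0:
        img = gaussian_filter(img, (spec.feature_size - 1.0) / 2.0)
    return img


def _gen_blocks(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    bs = max(1, int(round(spec.feature_size)))
    gh, gw = spec.height // bs, spec.width // bs
    lo, hi = spec.intensity_range
    grid = np.zeros((gh, gw))
    n_active = min(spec.count, gh * gw)
    idx = rng.choice(gh * gw, size=n_active, replace=False)
    grid.reshape(-1)[idx] = rng.uniform(lo, hi, size=n_active)
    img = np.kron(grid, np.ones((bs, bs)))
    full = np.zeros((spec.height, spec.width))
    full[: img.shape[0], : img.shape[1]] = img
    return full


def gen_scene(spec: SceneSpec) -> ImageScene:
    """Render a scene; bitwise reproducible for identical spec + seed."""
    rng = substream(spec.seed, "scene", spec.kind)
    gen = {
        "microspheres": _gen_microspheres,
        "nucleus": _gen_nucleus,
        "filaments": _gen_filaments,
        "block_constant": _gen_blocks,
    }[spec.kind]
    img = gen(spec, rng) + spec.background
    mask = img > spec.background + spec.mask_margin
    scene = ImageScene(intensities=img, valid_mask=mask,
                       meta={"kind": spec.kind, "seed": spec.seed})
    if spec.count > 0 and not mask.any():
        scene.meta["empty"] = True
    return scene


def sparsity(scene: ImageScene, threshold: float | None = None) -> float:
    """Fraction of pixels occupied by the sample (valid pixels / N)."""
    if scene.valid_mask is not None and threshold is None:
        mask = scene.valid_mask
    elif threshold is not None:
        mask = scene.intensities > threshold
    else:
        raise ValueError("scene has no valid_mask and no threshold was given")
    return float(mask.sum() / mask.size)


def photon_scale_for_total(scene: ImageScene, target_total: float = 400.0) -> float:
    """Photon scale at which one pattern exposure pair collects ~target_total photons.

    The two complementary binary exposures together see every pixel once, so
    the expected total count is photon_scale * sum(x).
    """
    total = float(scene.intensities.sum())
    if total <= 0:
        raise ValueError("scene has zero total intensity")
    return target_total / total


def make_dataset(
    spec: SceneSpec,
    op: SamplingOperator,
    n_pairs: int,
    seed: int,
    noise_model: str = "none",
    noise_param: float = 0.0,
    photon_scale: float = 1.0,
    test_size: int | None = None,
):
    """Generate ``n_pairs`` scenes, measure each, and split train/test.

    ``test_size`` defaults to ~4% of the pairs (minimum 1), the proportion of
    the 1150/50 full-scale split.  Returns ``(train_pairs, test_pairs)``.
    """
    from .recon_net import TrainingPair

    if n_pairs < 2:
        raise ValueError("need at least two pairs to split")
    if test_size is None:
        test_size = max(1, round(n_pairs * 50 / 1200))
    if not (1 <= test_size < n_pairs):
        raise ValueError("test_size must leave at least one training pair")

    pairs = []
    for i in range(n_pairs):
        scene = gen_scene(replace(spec, seed=derive_seed(seed, "scene", i)))
        mseed = derive_seed(seed, "measure", i)
        if noise_model == "poisson_differential":
            rec = measure_photons(op, scene, photon_scale, seed=mseed)
        else:
            rec = measure(op, scene, noise_model, noise_param, seed=mseed)
        pairs.append(TrainingPair(record=rec, scene=scene, operator=op,
                                  ratio=op.n_rows / op.n_cols))

    order = substream(seed, "split").permutation(n_pairs)
    test_idx = set(order[:test_size].tolist())
    train = [pairs[i] for i in range(n_pairs) if i not in test_idx]
    test = [pairs[i] for i in range(n_pairs) if i in test_idx]
    return train, test
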