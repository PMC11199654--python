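"""Single-pixel acquisition simulation.

The forward model is y = A x + n: each measurement is the inner product of
the scene with one bipolar pattern.  Optically a +-1 pattern is displayed as
two complementary binary patterns; the detector (a photon-counting PMT)
records photon counts under each, and the two counts are differenced.  The
photon model is therefore a difference of two independent Poisson variates
whose rates are the positive- and negative-part inner products scaled by the
photon flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import row_rng
from .patterns import SamplingOperator

__all__ = [
    "ImageScene",
    "MeasurementRecord",
    "measure",
    "decompose_bipolar",
    "measure_photons",
    "photon_budget",
]

NOISE_MODELS = ("none", "gaussian", "poisson_differential")


@dataclass
class ImageScene:
    """A nonnegative H x W intensity field.

    ``intensities`` are expected photon emission rates per pixel per pattern
    exposure (arbitrary units until multiplied by a photon scale).
    ``valid_mask`` marks sample-occupied pixels; photon budgets are quoted
    per valid pixel.
    """

    intensities: np.ndarray
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite and nonnegative")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.intensities.shape:
                raise ValueError("valid_mask shape must match intensities")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    def flatten(self) -> np.ndarray:
        return self.intensities.reshape(-1)

    def n_valid(self) -> int:
        if self.valid_mask is None:
            raise ValueError("scene has no valid_mask")
        return int(self.valid_mask.sum())

    # ---- I/O -------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, self.intensities.astype(np.float32))
        else:
            from PIL import Image

            peak = self.intensities.max()
            arr = self.intensities / peak if peak > 0 else self.intensities
            Image.fromarray((arr * 255).astype(np.uint8)).save(path)

    @classmethod
    def load(cls, path: str | Path, mask_threshold: float | None = None) -> "ImageScene":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = np.asarray(tifffile.imread(path), dtype=np.float64)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(path).convert("F"), dtype=np.float64)
        arr = np.clip(arr, 0.0, None)
        mask = None if mask_threshold is None else arr > mask_threshold
        return cls(intensities=arr, valid_mask=mask)


@dataclass
class MeasurementRecord:
    """A measurement vector with its provenance.

    ``pattern_indices[i]`` names the operator row that produced ``values[i]``.
    For photon records the raw complementary counts are retained and
    ``values`` is the count difference mapped back to the bipolar convention,
    so reconstruction code is noise-model agnostic.
    """

    values: np.ndarray
    pattern_indices: np.ndarray
    noise_model: str = "none"
    photon_scale: float = 0.0
    counts_pos: np.ndarray | None = None
    counts_neg: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        self.pattern_indices = np.asarray(self.pattern_indices, dtype=np.int64).reshape(-1)
        if self.values.shape != self.pattern_indices.shape or self.values.size < 1:
            raise ValueError("values and pattern_indices must be equal-length, nonempty")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for name in ("counts_pos", "counts_neg"):
            c = getattr(self, name)
            if c is not None:
                c = np.asarray(c, dtype=np.int64).reshape(-1)
                if c.shape != self.values.shape or np.any(c < 0):
                    raise ValueError(f"{name} must be nonnegative, one per measurement")
                setattr(self, name, c)

    @property
    def n_measurements(self) -> int:
        return self.values.size

    # ---- I/O: CSV with a '#'-commented metadata header --------------------

    def save_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "pattern_index": self.pattern_indices,
            "value": self.values,
        })
        if self.counts_pos is not None:
            df["counts_pos"] = self.counts_pos
            df["counts_neg"] = self.counts_neg
        with open(path, "w") as fh:
            fh.write(f"# noise_model={self.noise_model}\n")
            fh.write(f"# photon_scale={self.photon_scale!r}\n")
            fh.write(f"# seed={-1 if self.seed is None else self.seed}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "MeasurementRecord":
        import pandas as pd

        meta: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        df = pd.read_csv(path, comment="#")
        seed = int(meta.get("seed", -1))
        return cls(
            values=df["value"].to_numpy(),
            pattern_indices=df["pattern_index"].to_numpy(),
            noise_model=meta.get("noise_model", "none"),
            photon_scale=float(meta.get("photon_scale", 0.0)),
            counts_pos=df["counts_pos"].to_numpy() if "counts_pos" in df else None,
            counts_neg=df["counts_neg"].to_numpy() if "counts_neg" in df else None,
            seed=None if seed < 0 else seed,
        )


# ---------------------------------------------------------------------------


def _check_shapes(op: SamplingOperator, scene: ImageScene) -> None:
    if (scene.height, scene.width) != (op.height, op.width):
        raise ValueError(
            f"scene {scene.height}x{scene.width} does not match operator grid "
            f"{op.height}x{op.width}"
        )


def measure(
    op: SamplingOperator,
    scene: ImageScene,
    noise_model: str = "none",
    noise_param: float = 0.0,
    seed: int = 0,
) -> MeasurementRecord:
    """Acquire y = A x (+ optional i.i.d. Gaussian noise).

    Gaussian noise is drawn per row from a counter-based stream, so the first
    m rows of a larger acquisition equal a smaller one with the same seed.
    """
    _check_shapes(op, scene)
    if noise_model not in ("none", "gaussian"):
        raise ValueError("measure() supports 'none' or 'gaussian'; "
                         "use measure_photons() for photon counting")
    if noise_param < 0:
        raise ValueError("noise parameter must be nonnegative")
    y = op.values @ scene.flatten()
    if noise_model == "gaussian" and noise_param > 0:
        noise = np.array([
            row_rng(seed, "gaussian", i).normal(0.0, noise_param)
            for i in range(op.n_rows)
        ])
        y = y + noise
    return MeasurementRecord(
        values=y,
        pattern_indices=np.arange(op.n_rows),
        noise_model=noise_model,
        seed=seed,
    )


def decompose_bipolar(op: SamplingOperator) -> tuple[np.ndarray, np.ndarray]:
    """Split bipolar rows into the complementary binary patterns shown on the DMD.

    Returns (pattern_pos, pattern_neg) with entries in {0, 1};
    (pattern_pos - pattern_neg)/sqrt(N) reproduces the rows exactly and
    pattern_pos + pattern_neg is all ones.
    """
    if not op.is_bipolar:
        raise ValueError("operator is not bipolar")
    pos = (op.values > 0).astype(np.float64)
    return pos, 1.0 - pos


def measure_photons(
    op: SamplingOperator,
    scene: ImageScene,
    photon_scale: float,
    seed: int = 0,
) -> MeasurementRecord:
    """Photon-counting differential acquisition.

    For each pattern the two complementary binary exposures collect
    Poisson(photon_scale * <pattern_pos, x>) and
    Poisson(photon_scale * <pattern_neg, x>) photons independently; the
    normalized difference (counts_pos - counts_neg)/(photon_scale*sqrt(N))
    is an unbiased estimate of the noiseless bipolar measurement A x.
    """
    _check_shapes(op, scene)
    if not (photon_scale > 0):
        raise ValueError("photon_scale must be positive")
    pos, neg = decompose_bipolar(op)
    x = scene.flatten()
    lam_pos = photon_scale * (pos @ x)
    lam_neg = photon_scale * (neg @ x)
    counts_pos = np.empty(op.n_rows, dtype=np.int64)
    counts_neg = np.empty(op.n_rows, dtype=np.int64)
    for i in range(op.n_rows):
        rng = row_rng(seed, "poisson", i)
        counts_pos[i] = rng.poisson(lam_pos[i])
        counts_neg[i] = rng.poisson(lam_neg[i])
    values = (counts_pos - counts_neg) / (photon_scale * math.sqrt(op.n_cols))
    return MeasurementRecord(
        values=values,
        pattern_indices=np.arange(op.n_rows),
        noise_model="poisson_differential",
        photon_scale=photon_scale,
        counts_pos=counts_pos,
        counts_neg=counts_neg,
        seed=seed,
    )


def photon_budget(record: MeasurementRecord, scene: ImageScene) -> float:
    """Mean detected photons per valid pixel per single-pattern measurement.

    The total count of the two complementary exposures, averaged over
    patterns, divided by the number of sample-occupied pixels.
    """
    if record.counts_pos is None or record.counts_neg is None:
        raise ValueError("record has no photon counts")
    if scene.valid_mask is None:
        raise ValueError("scene has no valid_mask")
    n_valid = scene.n_valid()
    if n_valid == 0:
        raise ValueError("scene has no valid pixels")
    total = record.counts_pos + record.counts_neg
    return float(total.mean() / n_valid)
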