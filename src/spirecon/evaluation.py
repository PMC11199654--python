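"""Reconstruction metrics, sampling-ratio sweeps, and acquisition arithmetic.

PSNR and SSIM are the quality metrics; the acquisition arithmetic relates
the modulator refresh rate R, the measurement count m, and the pixel count
N: sampling ratio m/N, frame rate F = R/(2m) in the differential +-1
sampling mode (each bipolar pattern costs two binary exposures), and
megapixel throughput F*N/1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .forward_model import ImageScene, MeasurementRecord
from .patterns import SamplingOperator, select_subset

__all__ = [
    "AcquisitionSpec",
    "psnr",
    "ssim",
    "sampling_ratio",
    "format_ratio",
    "frame_rate",
    "throughput",
    "ratio_sweep",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Modulator refresh rate, measurement count, pixel count, sampling mode."""

    dmd_refresh_hz: float
    n_measurements: int
    n_pixels: int
    differential: bool = True

    def __post_init__(self) -> None:
        if self.dmd_refresh_hz <= 0:
            raise ValueError("refresh rate must be positive")
        if self.n_measurements < 1 or self.n_pixels < 1:
            raise ValueError("measurement and pixel counts must be >= 1")


def psnr(estimate: np.ndarray, truth: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; inf for identical images.

    ``data_range`` defaults to the peak of the ground truth (recorded by
    callers in output metadata).
    """
    estimate = np.asarray(estimate, float)
    truth = np.asarray(truth, float)
    if estimate.shape != truth.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(truth.max())
    mse = float(np.mean((estimate - truth) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(estimate: np.ndarray, truth: np.ndarray,
         data_range: float | None = None) -> float:
    """Structural similarity with the standard window and constants."""
    from skimage.metrics import structural_similarity

    estimate = np.asarray(estimate, float)
    truth = np.asarray(truth, float)
    if estimate.shape != truth.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(truth.max())
    win = min(7, min(truth.shape) - (1 - min(truth.shape) % 2))
    return float(structural_similarity(truth, estimate, data_range=data_range,
                                       win_size=win))


def sampling_ratio(m: int, n_pixels: int) -> float:
    """Sampling ratio as a percentage, 100 * m / N."""
    if m < 1 or n_pixels < 1:
        raise ValueError("m and N must be >= 1")
    return 100.0 * m / n_pixels


def format_ratio(percent: float, decimals: int = 2) -> str:
    """Display rounding of a percentage, isolated from the computation."""
    return f"{percent:.{decimals}f}"


def frame_rate(spec: AcquisitionSpec) -> float:
    """Imaging frame rate: R/(2m) differential, R/m otherwise (exact rational)."""
    divisor = 2 * spec.n_measurements if spec.differential else spec.n_measurements
    return float(Fraction(spec.dmd_refresh_hz).limit_denominator() / divisor)


def throughput(spec: AcquisitionSpec) -> float:
    """Pixel throughput in megapixels per second: frame_rate * N / 1e6."""
    divisor = 2 * spec.n_measurements if spec.differential else spec.n_measurements
    rate = Fraction(spec.dmd_refresh_hz).limit_denominator() * spec.n_pixels
    return float(rate / divisor / 10**6)


def ratio_sweep(
    reconstruct: Callable[[MeasurementRecord, SamplingOperator], np.ndarray],
    test_pairs: Sequence,
    m_list: Sequence[int],
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Quality-vs-ratio curves by randomized measurement selection.

    For each requested m and seed, a random subset of each test pair's
    measurements (and the matching pattern rows) is reconstructed and scored
    against the ground truth; PSNR/SSIM are averaged across the test set.
    Returns a tidy frame with one row per (m, seed).
    """
    rows = []
    for m in m_list:
        for seed in seeds:
            psnrs, ssims = [], []
            for i, pair in enumerate(test_pairs):
                sub_op, sub_rec = select_subset(
                    pair.operator, pair.record, m, derive_seed(seed, "sweep", m, i)
                )
                est = reconstruct(sub_rec, sub_op)
                psnrs.append(psnr(est, pair.scene.intensities))
                ssims.append(ssim(est, pair.scene.intensities))
            rows.append({
                "m": m,
                "ratio_pct": sampling_ratio(m, test_pairs[0].operator.n_cols),
                "psnr_mean": float(np.mean(psnrs)),
                "psnr_std": float(np.std(psnrs)),
                "ssim_mean": float(np.mean(ssims)),
                "ssim_std": float(np.std(ssims)),
                "seed": seed,
            })
    return pd.DataFrame(rows)
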