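"""Resampling, amplitude normalization and wavelet-threshold denoising.

Pipeline order is fixed: resample -> normalize -> denoise. Denoising
performs a three-level sym3 decomposition, soft-thresholds every detail
band with its own universal threshold ``sigma * sqrt(2 ln N)`` (sigma
from the median absolute detail coefficient divided by 0.6745), leaves
the approximation band untouched, and reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import logging

import numpy as np
from scipy import signal

from ._wavelet import wavedec, waverec
from .records import PCGRecord

log = logging.getLogger(__name__)

TARGET_FS = 2000.0


@dataclass
class DenoiseParams:
    wavelet_name: str = "sym3"
    levels: int = 3
    threshold_mode: str = "soft"  # "soft" or "hard"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def resample(record: PCGRecord, target_fs: float = TARGET_FS) -> PCGRecord:
    """Polyphase rational resampling with anti-alias filtering."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if record.samples.size < 2:
        raise ValueError("signal too short to resample")
    if record.fs == target_fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    out = signal.resample_poly(record.samples, frac.numerator, frac.denominator)
    log.info(
        "resampled %s: %d samples @ %g Hz -> %d samples @ %g Hz",
        record.participant_id, record.samples.size, record.fs, out.size, target_fs,
    )
    return record.with_samples(out, fs=target_fs)


def normalize(record: PCGRecord) -> PCGRecord:
    """Scale so that max |sample| = 1."""
    peak = np.max(np.abs(record.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return record.with_samples(record.samples / peak)


def noise_sigma(detail_coeffs: np.ndarray) -> float:
    """Robust noise scale: median(|detail|) / 0.6745."""
    detail_coeffs = np.asarray(detail_coeffs, dtype=float)
    if detail_coeffs.size == 0:
        raise ValueError("empty coefficient sequence")
    return float(np.median(np.abs(detail_coeffs)) / 0.6745)


def universal_threshold(sigma: float, n: int) -> float:
    """Universal shrinkage threshold ``sigma * sqrt(2 ln n)`` (natural log)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(sigma * np.sqrt(2.0 * np.log(n)))


def _shrink(c: np.ndarray, thr: float, mode: str) -> np.ndarray:
    if mode == "soft":
        return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
    return np.where(np.abs(c) > thr, c, 0.0)


def wavelet_denoise(record: PCGRecord, params: DenoiseParams | None = None) -> PCGRecord:
    """Per-level universal-threshold wavelet shrinkage of the detail bands."""
    params = params or DenoiseParams()
    x = record.samples
    if x.size < 2**params.levels:
        raise ValueError(
            f"signal of length {x.size} too short for {params.levels}-level decomposition"
        )
    coeffs, lengths = wavedec(x, params.levels, params.wavelet_name)
    out = [coeffs[0]]  # approximation band kept as-is
    for cd in coeffs[1:]:
        thr = universal_threshold(noise_sigma(cd), cd.size) if np.any(cd) else 0.0
        out.append(_shrink(cd, thr, params.threshold_mode))
    y = waverec(out, lengths, params.wavelet_name)
    return record.with_samples(y[: x.size])


def preprocess(record: PCGRecord, target_fs: float = TARGET_FS,
               denoise_params: DenoiseParams | None = None) -> PCGRecord:
    """resample -> normalize -> denoise."""
    return wavelet_denoise(normalize(resample(record, target_fs)), denoise_params)
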