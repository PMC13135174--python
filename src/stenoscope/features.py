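"""Band spectral energies, energy ratios and train-set standardization.

Energy convention: the one-sided analysis spectrum of each mode is
scaled so that summing over [0, fs/2] reproduces the time-domain energy
``sum(x^2) / fs`` (Parseval; units V^2*s). Each mode's energy integrates
its full spectral support — the nominal band widened by the raised-cosine
transitions — so that, by the tight-frame identity, e1 + e2 + e3 equals
the segment energy exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ewt import EWTFilterBank, ModeSet, decompose

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ("e1", "e2", "e3", "P1", "P2")


@dataclass
class FeatureVector:
    e1: float
    e2: float
    e3: float
    P1: Optional[float]
    P2: Optional[float]
    participant_id: str = ""
    cycle_index: int = -1

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "cycle_index": self.cycle_index,
            "e1": self.e1, "e2": self.e2, "e3": self.e3,
            "P1": self.P1, "P2": self.P2,
        }


def _one_sided_weights(nfft: int) -> np.ndarray:
    half = nfft // 2 + 1
    w = np.full(half, 2.0)
    w[0] = 1.0
    if nfft % 2 == 0:
        w[-1] = 1.0
    return w


def spectral_energy(
    spectrum: np.ndarray, fs: float, nfft: int, band_hz: tuple
) -> float:
    """Energy of a one-sided spectrum over ``band_hz`` (V^2*s).

    ``spectrum`` holds FFT coefficients on the one-sided grid of an
    ``nfft``-point transform of a signal sampled at ``fs``.
    """
    lo, hi = band_hz
    if lo > hi:
        raise ValueError(f"inverted band {band_hz}")
    if lo < 0 or hi > fs / 2.0:
        raise ValueError(f"band {band_hz} outside [0, {fs / 2}]")
    spectrum = np.asarray(spectrum)
    freqs = np.arange(spectrum.size) * fs / nfft
    mask = (freqs >= lo) & (freqs <= hi)
    w = _one_sided_weights(nfft)
    return float(np.sum(w[mask] * np.abs(spectrum[mask]) ** 2) / (nfft * fs))


def compute_features(
    mode_set: ModeSet, participant_id: str = "", cycle_index: int = -1
) -> FeatureVector:
    """e(1)..e(3) over the mode supports, plus ratios P1 = e2/e1, P2 = e3/e1."""
    tau_hz = _tau_hz(mode_set)
    energies = []
    for n in range(3):
        lo, hi = mode_set.bands_hz[n]
        lo = max(0.0, lo - tau_hz) if n > 0 else 0.0
        hi = min(mode_set.fs / 2.0, hi + tau_hz) if n < 2 else mode_set.fs / 2.0
        energies.append(
            spectral_energy(
                mode_set.analysis_spectra[n], mode_set.fs, mode_set.nfft, (lo, hi)
            )
        )
    e1, e2, e3 = energies
    if e1 > 0:
        p1, p2 = e2 / e1, e3 / e1
    else:
        log.warning(
            "e1 = 0 for %s cycle %d; ratios undefined", participant_id, cycle_index
        )
        p1 = p2 = None
    return FeatureVector(e1, e2, e3, p1, p2, participant_id, cycle_index)


def _tau_hz(mode_set: ModeSet) -> float:
    return mode_set.tau * (mode_set.fs / 2.0) / np.pi


def features_from_segment(segment, bank: EWTFilterBank,
                          participant_id: str = "", cycle_index: int = -1) -> FeatureVector:
    samples = segment.samples if hasattr(segment, "samples") else segment
    pid = getattr(segment, "participant_id", participant_id)
    ci = getattr(segment, "cycle_index", cycle_index)
    return compute_features(decompose(samples, bank), pid, ci)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    exponent = int(np.floor(np.log10(abs(x))))
    return float(round(x, digits - 1 - exponent))


def aggregate_cohort(
    rows: pd.DataFrame,
    group_by: Optional[Sequence[str]] = None,
    features: Sequence[str] = FEATURE_COLUMNS,
    sig_figs: Optional[int] = None,
) -> pd.DataFrame:
    """Per-group mean and SD of each feature column.

    With ``sig_figs`` set, values are rounded to that many significant
    figures for display (internal computation stays full precision).
    """
    if rows.empty:
        raise ValueError("empty feature table")
    features = [f for f in features if f in rows.columns]
    if group_by:
        out = rows.groupby(list(group_by))[features].agg(["mean", "std"])
    else:
        out = rows[features].agg(["mean", "std"]).T  # index = feature
    if sig_figs is not None:
        out = out.map(lambda v: round_sig(v, sig_figs) if pd.notna(v) else v)
    return out


@dataclass
class Standardizer:
    """Column-wise location/scale learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray
    columns: tuple

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        out[list(self.columns)] = (rows[list(self.columns)].to_numpy() - self.mean) / self.scale
        return out


def fit_standardizer(
    train_rows: pd.DataFrame, columns: Sequence[str] = FEATURE_COLUMNS
) -> Standardizer:
    columns = tuple(columns)
    if len(train_rows) < 2:
        raise ValueError("need at least 2 training rows")
    X = train_rows[list(columns)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD so transformed columns have SD exactly 1
    for col, s in zip(columns, scale):
        if s == 0:
            raise ValueError(f"zero-variance feature: {col}")
    return Standardizer(mean=mean, scale=scale, columns=columns)
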