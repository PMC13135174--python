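"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Ordered class labels for stenosis severity.
CLASS_ORDER = ("mild", "moderate", "severe")


def stenosis_to_class(stenosis_pct: float) -> str:
    """Map an angiographic stenosis percentage to a severity class.

    Boundaries: < 50 -> mild, 50..75 inclusive -> moderate, > 75 -> severe.
    Normal subjects (0 %) fall in the mild class.
    """
    if not 0.0 <= stenosis_pct <= 100.0:
        raise ValueError(f"stenosis_pct must be in [0, 100], got {stenosis_pct}")
    if stenosis_pct < 50.0:
        return "mild"
    if stenosis_pct <= 75.0:
        return "moderate"
    return "severe"


@dataclass
class PCGRecord:
    """A single-channel phonocardiogram with optional annotations.

    Attributes
    ----------
    samples : ndarray
        Real amplitudes (dimensionless once normalized to [-1, 1]).
    fs : float
        Sampling rate in Hz.
    participant_id : str
        Opaque identifier.
    r_times : ndarray or None
        ECG R-peak times in seconds, strictly increasing.
    stenosis_pct : float or None
        Angiographic stenosis in [0, 100].
    label : str or None
        Severity class; must agree with ``stenosis_pct`` when both set.
    """

    samples: np.ndarray
    fs: float
    participant_id: str = ""
    r_times: Optional[np.ndarray] = None
    stenosis_pct: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.r_times is not None:
            self.r_times = np.asarray(self.r_times, dtype=float)
            if self.r_times.size > 1 and not np.all(np.diff(self.r_times) > 0):
                raise ValueError("r_times must be strictly increasing")
        if self.stenosis_pct is not None:
            implied = stenosis_to_class(self.stenosis_pct)
            if self.label is None:
                self.label = implied
            elif self.label != implied:
                raise ValueError(
                    f"label {self.label!r} inconsistent with stenosis "
                    f"{self.stenosis_pct}% (implies {implied!r})"
                )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, fs: Optional[float] = None) -> "PCGRecord":
        return replace(self, samples=np.asarray(samples, dtype=float), fs=fs or self.fs)


@dataclass
class S2Event:
    """A detected second heart sound."""

    peak_time: float
    end_time: float
    peak_envelope: float

    def __post_init__(self):
        if self.end_time < self.peak_time:
            raise ValueError("end_time must not precede peak_time")


@dataclass
class DiastoleSegment:
    """Fixed 128 ms diastolic analysis window (256 samples at 2000 Hz)."""

    samples: np.ndarray
    fs: float
    participant_id: str
    cycle_index: int
    start_time: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(0.128 * self.fs))
        if self.samples.size != expected:
            raise ValueError(
                f"segment must hold {expected} samples at fs={self.fs}, "
                f"got {self.samples.size}"
            )


@dataclass
class GroundTruth:
    """Per-cycle event times for a simulated record (segmentation oracle)."""

    s1_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    s2_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    s2_ends: np.ndarray = field(default_factory=lambda: np.empty(0))
    murmur_amplitude: float = 0.0

    def __post_init__(self):
        self.s1_onsets = np.asarray(self.s1_onsets, dtype=float)
        self.s2_onsets = np.asarray(self.s2_onsets, dtype=float)
        self.s2_ends = np.asarray(self.s2_ends, dtype=float)
        for name in ("s1_onsets", "s2_onsets", "s2_ends"):
            t = getattr(self, name)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")
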