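"""Fixed-boundary Meyer-type filter bank and three-mode decomposition.

The frequency axis is normalized to [0, pi] (omega = pi * f / (fs/2)).
Band edges sit at fixed frequencies (default 150 and 500 Hz) with
raised-cosine transitions of half-width tau (default 0.1*pi) shaped by
the polynomial ``beta(x) = x^2 (3 - 2x)``. The three squared responses
form an exact partition of unity, i.e. a tight frame over [0, pi].

Two quantities come out of a decomposition:

* time-domain modes, filtered with the *squared* responses so that the
  plain sum of the three modes reconstructs the input exactly; and
* analysis spectra (input spectrum times each response), whose energies
  partition the segment energy exactly by the tight-frame identity.

Band energies are computed from the analysis spectra; the time-domain
modes carry the additive decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BOUNDARIES_HZ = (150.0, 500.0)
DEFAULT_TAU = 0.1 * np.pi
DEFAULT_NFFT = 1024


def beta_fn(x):
    """Transition polynomial: 0 for x<=0, 1 for x>=1, x^2(3-2x) between."""
    x = np.asarray(x, dtype=float)
    out = np.clip(x, 0.0, 1.0)
    out = out * out * (3.0 - 2.0 * out)
    if out.ndim == 0:
        return float(out)
    return out


def _rise(omega, wn, tau):
    """sin(pi/2 * beta(.)) ramp across [wn - tau, wn + tau]."""
    return np.sin(0.5 * np.pi * beta_fn((omega - wn + tau) / (2.0 * tau)))


def _fall(omega, wn, tau):
    """cos(pi/2 * beta(.)) rolloff across [wn - tau, wn + tau]."""
    return np.cos(0.5 * np.pi * beta_fn((omega - wn + tau) / (2.0 * tau)))


@dataclass
class EWTFilterBank:
    """Three-band tight-frame filter bank sampled on a full FFT grid."""

    fs: float
    boundaries_hz: tuple
    tau: float
    nfft: int
    responses: np.ndarray = field(repr=False)  # (3, nfft), real in [0, 1]

    @property
    def freqs_hz(self) -> np.ndarray:
        """|frequency| in Hz for every FFT bin (two-sided grid)."""
        k = np.arange(self.nfft)
        k = np.minimum(k, self.nfft - k)
        return k * self.fs / self.nfft

    def band_support_hz(self, n: int) -> tuple:
        """Frequency interval (Hz) outside which response n vanishes."""
        tau_hz = self.tau * (self.fs / 2.0) / np.pi
        lo_edges = (0.0,) + self.boundaries_hz
        hi_edges = self.boundaries_hz + (self.fs / 2.0,)
        lo = max(0.0, lo_edges[n] - tau_hz) if n > 0 else 0.0
        hi = min(self.fs / 2.0, hi_edges[n] + tau_hz) if n < 2 else self.fs / 2.0
        return lo, hi


def build_filter_bank(
    fs: float = 2000.0,
    boundaries_hz: tuple = DEFAULT_BOUNDARIES_HZ,
    tau: float = DEFAULT_TAU,
    nfft: int = DEFAULT_NFFT,
) -> EWTFilterBank:
    """Construct the scaling filter and two wavelet filters on the FFT grid."""
    b1, b2 = (float(b) for b in boundaries_hz)
    if not 0 < b1 < b2 < fs / 2.0:
        raise ValueError(
            f"boundaries must satisfy 0 < b1 < b2 < Nyquist, got {boundaries_hz}"
        )
    w1 = np.pi * b1 / (fs / 2.0)
    w2 = np.pi * b2 / (fs / 2.0)
    if w1 - tau <= 0 or w1 + tau >= w2 - tau or w2 + tau > np.pi:
        raise ValueError(
            f"transition half-width tau={tau:.4f} overlaps band edges "
            f"w1={w1:.4f}, w2={w2:.4f}"
        )
    # symmetric two-sided grid: omega in [0, pi] via |k| folding
    k = np.arange(nfft)
    omega = 2.0 * np.pi * np.minimum(k, nfft - k) / nfft

    phi1 = np.where(
        omega <= w1 - tau, 1.0, np.where(omega >= w1 + tau, 0.0, _fall(omega, w1, tau))
    )
    psi1 = np.where(
        (omega >= w1 + tau) & (omega <= w2 - tau),
        1.0,
        np.where(
            (omega > w1 - tau) & (omega < w1 + tau),
            _rise(omega, w1, tau),
            np.where((omega > w2 - tau) & (omega < w2 + tau), _fall(omega, w2, tau), 0.0),
        ),
    )
    psi2 = np.where(
        omega >= w2 + tau, 1.0,
        np.where(omega <= w2 - tau, 0.0, _rise(omega, w2, tau)),
    )
    responses = np.vstack([phi1, psi1, psi2])
    return EWTFilterBank(
        fs=fs, boundaries_hz=(b1, b2), tau=tau, nfft=nfft, responses=responses
    )


@dataclass
class ModeSet:
    """Result of decomposing one segment."""

    modes: np.ndarray            # (3, n) time-domain, sum == input
    analysis_spectra: np.ndarray  # (3, nfft//2 + 1) one-sided, complex
    fs: float
    nfft: int
    n_samples: int
    bands_hz: tuple              # nominal band of each mode
    tau: float = DEFAULT_TAU     # transition half-width, rad/sample

    def __iter__(self):
        return iter(self.modes)


def decompose(segment: np.ndarray, bank: EWTFilterBank) -> ModeSet:
    """Split a segment into three modes (see module docstring)."""
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if n > bank.nfft:
        raise ValueError(f"segment length {n} exceeds nfft {bank.nfft}")
    spectrum = np.fft.fft(segment, bank.nfft)
    half = bank.nfft // 2 + 1
    analysis = (spectrum[None, :] * bank.responses)[:, :half]
    # analysis + synthesis with the same filter == one pass of |response|^2;
    # squared responses sum to 1 so the modes add back to the input exactly
    modes = np.fft.ifft(spectrum[None, :] * bank.responses**2, axis=1).real[:, :n]
    b1, b2 = bank.boundaries_hz
    return ModeSet(
        modes=modes,
        analysis_spectra=analysis,
        fs=bank.fs,
        nfft=bank.nfft,
        n_samples=n,
        bands_hz=((0.0, b1), (b1, b2), (b2, bank.fs / 2.0)),
        tau=bank.tau,
    )


def reconstruct(modes) -> np.ndarray:
    """Elementwise sum of the three modes (exact tight-frame inverse)."""
    modes = np.asarray(modes if not isinstance(modes, ModeSet) else modes.modes)
    if modes.ndim != 2 or len({m.size for m in modes}) != 1:
        raise ValueError("modes must be equal-length 1-D signals")
    return modes.sum(axis=0)
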