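"""Minimal orthogonal discrete wavelet transform (periodized).

Only what the denoiser needs: multilevel analysis/synthesis with the
sym3 filter pair. Circular (periodized) convolution is used at every
level, which gives exact perfect reconstruction for orthogonal filters;
odd-length inputs are padded by repeating the last sample and trimmed
on reconstruction.
"""

from __future__ import annotations

import numpy as np

# sym3 orthonormal scaling filter (identical to db3; symlets and
# Daubechies wavelets coincide for 2 and 3 vanishing moments).
_SYM3_LO = np.array(
    [
        0.3326705529509569,
        0.8068915093133388,
        0.4598775021193313,
        -0.1350110200102546,
        -0.0854412738822415,
        0.0352262918821007,
    ]
)

_FILTERS = {"sym3": _SYM3_LO, "db3": _SYM3_LO}


def _qmf_pair(name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = _FILTERS[name]
    except KeyError:
        raise ValueError(f"unsupported wavelet {name!r}; available: {sorted(_FILTERS)}")
    n = np.arange(lo.size)
    hi = ((-1.0) ** n) * lo[::-1]  # conjugate quadrature mirror
    return lo, hi


def _circ_filter(x: np.ndarray, h: np.ndarray, adjoint: bool) -> np.ndarray:
    """Circular convolution with h (adjoint=True -> correlation)."""
    n = x.size
    H = np.fft.rfft(h, n)
    if adjoint:
        H = np.conj(H)
    return np.fft.irfft(np.fft.rfft(x) * H, n)


def dwt_periodized(x: np.ndarray, wavelet: str = "sym3"):
    """One analysis level; returns (approx, detail), each of size ceil(n/2)."""
    lo, hi = _qmf_pair(wavelet)
    x = np.asarray(x, dtype=float)
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    ca = _circ_filter(x, lo, adjoint=True)[::2]
    cd = _circ_filter(x, hi, adjoint=True)[::2]
    return ca, cd


def idwt_periodized(ca: np.ndarray, cd: np.ndarray, wavelet: str = "sym3") -> np.ndarray:
    if ca.size != cd.size:
        raise ValueError("approximation/detail length mismatch")
    lo, hi = _qmf_pair(wavelet)
    n = 2 * ca.size
    up_a = np.zeros(n)
    up_d = np.zeros(n)
    up_a[::2] = ca
    up_d[::2] = cd
    return _circ_filter(up_a, lo, adjoint=False) + _circ_filter(up_d, hi, adjoint=False)


def wavedec(x: np.ndarray, level: int, wavelet: str = "sym3"):
    """Multilevel analysis: returns [cA_J, cD_J, ..., cD_1] plus length bookkeeping."""
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.size < 2**level:
        raise ValueError(f"signal of length {x.size} too short for {level} levels")
    details = []
    lengths = []
    approx = x
    for _ in range(level):
        lengths.append(approx.size)
        approx, cd = dwt_periodized(approx, wavelet)
        details.append(cd)
    return [approx] + details[::-1], lengths


def waverec(coeffs, lengths, wavelet: str = "sym3") -> np.ndarray:
    approx = coeffs[0]
    details = coeffs[1:]
    for cd, orig_len in zip(details, lengths[::-1]):
        approx = idwt_periodized(approx, cd, wavelet)[:_even(orig_len)][:orig_len]
    return approx


def _even(n: int) -> int:
    return n + (n % 2)
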