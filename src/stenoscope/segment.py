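"""Second-heart-sound detection and diastole windowing.

S2 candidates are envelope peaks of the high-pass-filtered signal
(cutoff 200 Hz; the nominal 200-2000 Hz passband collapses to a
high-pass at fs = 2000). Among alternating heart-sound peaks, S2 is the
peak followed by the longer inter-peak gap (diastole exceeds systole);
with ECG R-times available, the peak inside (0.25, 0.55) x RR after
each R-peak is taken instead. S2 end is the first post-peak time where
the envelope drops below 10 % of the peak envelope. The diastolic
window is fixed: 100-228 ms after S2 end (256 samples at 2000 Hz).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .records import DiastoleSegment, PCGRecord, S2Event

log = logging.getLogger(__name__)

HIGHPASS_HZ = 200.0
ENV_SMOOTH_S = 0.020
MIN_PEAK_SEPARATION_S = 0.200
PEAK_HEIGHT_FRACTION = 0.30
S2_END_FRACTION = 0.10
DIASTOLE_OFFSET_S = 0.100
DIASTOLE_LENGTH_S = 0.128


def envelope(samples: np.ndarray, fs: float, smooth_s: float = ENV_SMOOTH_S) -> np.ndarray:
    """Smoothed analytic-magnitude envelope (moving average, default 20 ms)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty input")
    env = np.abs(sps.hilbert(samples))
    win = max(1, int(round(smooth_s * fs)))
    if win > 1:
        kernel = np.ones(win) / win
        padded = np.pad(env, (win // 2, win - 1 - win // 2), mode="reflect")
        env = np.convolve(padded, kernel, mode="valid")
    return env


def _highpass(samples: np.ndarray, fs: float, cutoff: float = HIGHPASS_HZ) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples)


def _s2_from_alternation(peak_times: np.ndarray, peak_heights: np.ndarray) -> np.ndarray:
    """Pick the S2 parity: peaks followed by the longer inter-peak gap."""
    m = peak_times.size
    if m == 1:
        return np.array([0])
    gaps = np.diff(peak_times)
    # majority vote over parities: mean following-gap per parity class
    mean_gap = [np.mean(gaps[p::2]) if gaps[p::2].size else -np.inf for p in (0, 1)]
    parity = int(np.argmax(mean_gap))
    return np.arange(parity, m, 2)


def detect_s2(
    record: PCGRecord,
    r_times: Optional[np.ndarray] = None,
    highpass_hz: float = HIGHPASS_HZ,
) -> list[S2Event]:
    """Locate S2 peaks and their envelope-defined end times."""
    fs = record.fs
    if r_times is None:
        r_times = record.r_times
    filtered = _highpass(record.samples, fs, highpass_hz)
    env = envelope(filtered, fs)
    height = PEAK_HEIGHT_FRACTION * np.percentile(env, 95)
    if height <= 0:
        log.info("%s: silent record, no S2 events", record.participant_id)
        return []
    idx, props = sps.find_peaks(
        env, height=height, distance=int(round(MIN_PEAK_SEPARATION_S * fs))
    )
    if idx.size == 0:
        log.info("%s: no envelope peaks found", record.participant_id)
        return []
    times = idx / fs
    heights = env[idx]

    if r_times is not None and len(r_times) >= 2:
        r_times = np.asarray(r_times, dtype=float)
        rr = np.diff(r_times)
        rr = np.append(rr, np.median(rr))
        s2_idx = []
        for r, dur in zip(r_times, rr):
            lo, hi = r + 0.25 * dur, r + 0.55 * dur
            in_win = np.where((times > lo) & (times < hi))[0]
            if in_win.size:
                s2_idx.append(in_win[np.argmax(heights[in_win])])
        s2_idx = np.unique(s2_idx).astype(int)
    else:
        s2_idx = _s2_from_alternation(times, heights)

    events = []
    for i in s2_idx:
        peak = idx[i]
        thr = S2_END_FRACTION * env[peak]
        below = np.where(env[peak:] < thr)[0]
        if below.size == 0:
            continue  # envelope never decays inside the record
        end = peak + below[0]
        events.append(
            S2Event(peak_time=peak / fs, end_time=end / fs, peak_envelope=float(env[peak]))
        )
    log.info("%s: %d S2 events from %d peaks", record.participant_id, len(events), idx.size)
    return events


def extract_diastoles(
    record: PCGRecord,
    s2_events: Sequence[S2Event],
    n_keep: int = 10,
    s1_onsets: Optional[np.ndarray] = None,
) -> list[DiastoleSegment]:
    """Fixed 256-sample windows starting 100 ms after each S2 end.

    Windows running past the record end are dropped; so are windows that
    would overlap the next cycle's S1 onset when those onsets are known.
    The first ``n_keep`` valid windows are retained.
    """
    fs = record.fs
    length = int(round(DIASTOLE_LENGTH_S * fs))
    segments: list[DiastoleSegment] = []
    for cycle, ev in enumerate(s2_events):
        start = int(round((ev.end_time + DIASTOLE_OFFSET_S) * fs))
        stop = start + length
        if stop > record.samples.size:
            continue
        if s1_onsets is not None:
            nxt = np.asarray(s1_onsets, dtype=float)
            nxt = nxt[nxt > ev.end_time]
            if nxt.size and stop / fs > nxt[0]:
                continue
        segments.append(
            DiastoleSegment(
                samples=record.samples[start:stop],
                fs=fs,
                participant_id=record.participant_id,
                cycle_index=cycle,
                start_time=start / fs,
            )
        )
        if len(segments) == n_keep:
            break
    log.info(
        "%s: kept %d/%d diastole windows", record.participant_id, len(segments), len(s2_events)
    )
    return segments
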