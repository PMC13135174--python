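"""Synthetic phonocardiogram cohorts with ground-truth event times.

Each cardiac cycle holds S1 and S2 as Gaussian-windowed tone bursts.
Real valve sounds carry a broadband closure transient, so each burst
mixes its low-frequency fundamental with a smaller high-frequency
component under the same envelope; that component is what survives the
200 Hz detection high-pass. A band-limited Gaussian murmur whose
amplitude grows monotonically with stenosis percentage occupies early
diastole, and white background noise is added at a configurable SNR.

The default murmur gain is ``scale * (stenosis/100)**1.5`` with the
scale calibrated once so that a simulated 30 %-stenosis cohort has a
mean second-band energy near 1e-6 V^2*s after the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .io import manifest_from_rows
from .records import GroundTruth, PCGRecord

#: (low %, high %, participants) for each stenosis group of the default cohort.
DEFAULT_COHORT_GROUPS = (
    (0.0, 0.0, 10),
    (30.0, 30.0, 10),
    (40.0, 50.0, 10),
    (50.0, 60.0, 15),
    (70.0, 75.0, 10),
    (85.0, 85.0, 10),
    (90.0, 95.0, 10),
)

#: Calibrated so cohort-mean e(2) at 30 % stenosis lands near 1e-6 V^2*s.
DEFAULT_MURMUR_GAIN_SCALE = 0.04


@dataclass
class SimParams:
    fs: float = 2000.0
    heart_rate_bpm: tuple = (75.0, 5.0)  # mean, SD
    s1_freq: float = 60.0
    s2_freq: float = 90.0
    s1_dur: float = 0.070
    s2_dur: float = 0.060
    s1_amp: float = 1.0
    s2_amp: float = 0.8
    click_freq: float = 320.0   # broadband valve-closure component
    click_gain: float = 0.30    # relative to the burst amplitude
    systole_fraction: float = 0.375
    murmur_band: tuple = (180.0, 700.0)
    murmur_onset: float = 0.060   # after S2 end
    murmur_dur: float = 0.240
    murmur_gain_scale: float = DEFAULT_MURMUR_GAIN_SCALE
    murmur_gain_power: float = 1.5
    cycle_gain_jitter_sd: float = 0.20  # lognormal SD of per-cycle murmur gain
    rumble_gain: float = 0.021          # stenosis-independent low-frequency rumble
    rumble_band: tuple = (15.0, 45.0)
    noise_snr_db: Optional[float] = 50.0  # None disables background noise

    def __post_init__(self):
        cycle = 60.0 / self.heart_rate_bpm[0]
        for name in ("s1_dur", "s2_dur", "murmur_dur"):
            d = getattr(self, name)
            if not 0 < d < cycle:
                raise ValueError(f"{name}={d} must be positive and shorter than a cycle")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must be in (0, 1)")
        if not 0 < self.murmur_band[0] < self.murmur_band[1] <= self.fs / 2.0:
            raise ValueError(f"invalid murmur band {self.murmur_band}")


def murmur_gain(stenosis_pct: float, params: SimParams) -> float:
    """Murmur amplitude for a stenosis percentage (0 at 0 %, strictly increasing)."""
    if not 0.0 <= stenosis_pct <= 100.0:
        raise ValueError(f"stenosis_pct must be in [0, 100], got {stenosis_pct}")
    return params.murmur_gain_scale * (stenosis_pct / 100.0) ** params.murmur_gain_power


def _burst(t: np.ndarray, center: float, dur: float, freq: float,
           amp: float, click_freq: float, click_gain: float,
           phases: tuple) -> np.ndarray:
    sigma = dur / 6.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    tone = np.sin(2 * np.pi * freq * (t - center) + phases[0])
    click = np.sin(2 * np.pi * click_freq * (t - center) + phases[1])
    return amp * env * (tone + click_gain * click)


def _envelope_end(center: float, dur: float) -> float:
    """Time the clean Gaussian envelope falls below 10 % of its peak."""
    return center + (dur / 6.0) * np.sqrt(2.0 * np.log(10.0))


def simulate_participant(
    stenosis_pct: float,
    n_cycles: int,
    params: Optional[SimParams] = None,
    seed: int = 0,
    participant_id: str = "sim",
) -> tuple[PCGRecord, GroundTruth]:
    """One synthetic record with per-cycle ground-truth event times."""
    params = params or SimParams()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    fs = params.fs
    hr_mean, hr_sd = params.heart_rate_bpm
    cycle_lens = 60.0 / np.clip(rng.normal(hr_mean, hr_sd, n_cycles), 40.0, 150.0)
    lead_in = 0.10
    total = lead_in + float(np.sum(cycle_lens)) + 0.6
    n = int(round(total * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    gain = murmur_gain(stenosis_pct, params)
    s1_onsets, s2_onsets, s2_ends = [], [], []
    t0 = lead_in
    for c in range(n_cycles):
        cyc = cycle_lens[c]
        s1_c = t0 + params.s1_dur / 2.0
        s2_on = t0 + params.systole_fraction * cyc
        s2_c = s2_on + params.s2_dur / 2.0
        x += _burst(t, s1_c, params.s1_dur, params.s1_freq, params.s1_amp,
                    params.click_freq, params.click_gain,
                    (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)))
        x += _burst(t, s2_c, params.s2_dur, params.s2_freq, params.s2_amp,
                    params.click_freq, params.click_gain,
                    (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)))
        s2_end = _envelope_end(s2_c, params.s2_dur)
        if gain > 0:
            cyc_gain = gain * rng.lognormal(0.0, params.cycle_gain_jitter_sd)
            x += _murmur(t, s2_end + params.murmur_onset, params.murmur_dur,
                         cyc_gain, params, rng)
        s1_onsets.append(t0)
        s2_onsets.append(s2_on)
        s2_ends.append(s2_end)
        t0 += cyc

    if params.rumble_gain > 0:
        # continuous hemodynamic rumble; lands in the first band so e(1)
        # has a stable, stenosis-independent scale
        white = rng.normal(0.0, 1.0, n)
        sos = sps.butter(4, params.rumble_band, btype="bandpass", fs=fs, output="sos")
        rumble = sps.sosfiltfilt(sos, white)
        x += params.rumble_gain * rumble / np.std(rumble)

    if params.noise_snr_db is not None:
        sig_power = float(np.mean(x**2))
        noise_power = sig_power / 10.0 ** (params.noise_snr_db / 10.0)
        x += rng.normal(0.0, np.sqrt(noise_power), n)

    record = PCGRecord(
        samples=x,
        fs=fs,
        participant_id=participant_id,
        r_times=np.asarray(s1_onsets) - 0.02,
        stenosis_pct=stenosis_pct,
    )
    truth = GroundTruth(
        s1_onsets=np.asarray(s1_onsets),
        s2_onsets=np.asarray(s2_onsets),
        s2_ends=np.asarray(s2_ends),
        murmur_amplitude=gain,
    )
    return record, truth


def _murmur(t: np.ndarray, start: float, dur: float, gain: float,
            params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with smooth 30 ms on/off ramps."""
    fs = params.fs
    white = rng.normal(0.0, 1.0, t.size)
    sos = sps.butter(4, params.murmur_band, btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    band /= np.std(band)
    ramp = 0.030
    u_on = np.clip((t - start) / ramp, 0.0, 1.0)
    u_off = np.clip((start + dur - t) / ramp, 0.0, 1.0)
    window = (u_on**2 * (3 - 2 * u_on)) * (u_off**2 * (3 - 2 * u_off))
    return gain * band * window


def simulate_cohort(
    groups: Sequence[tuple] = DEFAULT_COHORT_GROUPS,
    params: Optional[SimParams] = None,
    seed: int = 0,
    n_cycles: int = 14,
):
    """Simulate one record per participant across the stenosis groups.

    Returns ``(manifest, records, truths)`` where records/truths are dicts
    keyed by participant id. Per-participant stenosis is drawn uniformly
    within its group range; per-participant seeds derive from the master
    seed so the cohort is reproducible as a whole.
    """
    params = params or SimParams()
    groups = list(groups)
    rng = np.random.default_rng(seed)
    seed_seq = np.random.SeedSequence(seed)
    n_total = sum(g[2] for g in groups)
    child_seeds = seed_seq.spawn(max(n_total, 1))

    rows, records, truths = [], {}, {}
    i = 0
    for gi, (lo, hi, count) in enumerate(groups):
        for _ in range(count):
            pid = f"P{i + 1:03d}"
            stenosis = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            child = int(child_seeds[i].generate_state(1)[0])
            rec, truth = simulate_participant(
                stenosis, n_cycles, params, seed=child, participant_id=pid
            )
            rows.append(
                {"participant_id": pid, "stenosis_pct": stenosis, "path": "", "group": gi}
            )
            records[pid] = rec
            truths[pid] = truth
            i += 1
    return manifest_from_rows(rows), records, truths
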