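import numpy as np
import pandas as pd
import pytest

import stenoscope as st
from stenoscope.ewt import ModeSet, decompose
from stenoscope.features import (
    FEATURE_COLUMNS,
    aggregate_cohort,
    compute_features,
    fit_standardizer,
    round_sig,
    spectral_energy,
)

# Per-diastole feature rows for one 30 %-stenosis subject and one normal
# subject (six cycles each), used as worked examples for the aggregation.
CAD_ROWS = pd.DataFrame({
    "e1": [0.0015, 3.8e-4, 7.7e-4, 0.0015, 6.2e-4, 4.0e-4],
    "e2": [2.8e-6, 1.1e-6, 1.9e-6, 1.9e-6, 1.5e-6, 1.1e-6],
    "e3": [1.7e-7, 8.9e-8, 1.5e-7, 2.4e-7, 1.0e-7, 8.4e-8],
    "P1": [0.0018, 0.0028, 0.0025, 0.0013, 0.0024, 0.0029],
    "P2": [1.1e-4, 2.3e-4, 2.0e-4, 1.6e-4, 1.7e-4, 2.1e-4],
})
NORMAL_ROWS = pd.DataFrame({
    "e1": [3.4e-4, 3.8e-4, 9.8e-4, 0.0014, 0.0017, 0.0013],
    "e2": [2.2e-8, 3.4e-8, 1.6e-8, 2.1e-8, 1.0e-8, 1.6e-8],
    "e3": [1.8e-10, 3.4e-10, 6.9e-11, 1.8e-10, 7.8e-11, 1.7e-10],
    "P1": [6.4e-5, 8.8e-5, 1.6e-5, 1.5e-5, 6.0e-6, 1.2e-5],
    "P2": [5.4e-7, 8.8e-7, 7.0e-8, 1.3e-7, 4.5e-8, 1.3e-7],
})


def _fake_mode_set(spectra, nfft=1024, fs=2000.0):
    half = nfft // 2 + 1
    arr = np.zeros((3, half), dtype=complex)
    for i, spec in enumerate(spectra):
        arr[i, : len(spec)] = spec
    return ModeSet(
        modes=np.zeros((3, 256)),
        analysis_spectra=arr,
        fs=fs,
        nfft=nfft,
        n_samples=256,
        bands_hz=((0.0, 150.0), (150.0, 500.0), (500.0, 1000.0)),
    )


class TestSpectralEnergy:
    def test_zero(self):
        assert spectral_energy(np.zeros(513), 2000.0, 1024, (0.0, 1000.0)) == 0.0

    def test_tone_parseval(self, bank):
        x = np.sin(2 * np.pi * 300 * np.arange(256) / 2000.0)
        fv = compute_features(decompose(x, bank))
        # A^2 T / 2 for a unit tone over 0.128 s
        assert fv.e1 + fv.e2 + fv.e3 == pytest.approx(0.064, rel=0.02)

    def test_inverted_band(self):
        with pytest.raises(ValueError, match="inverted"):
            spectral_energy(np.zeros(513), 2000.0, 1024, (500.0, 100.0))

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            spectral_energy(np.zeros(513), 2000.0, 1024, (0.0, 1500.0))


class TestComputeFeatures:
    def test_equal_energies_give_unit_ratio(self):
        spec100 = np.zeros(60, dtype=complex)
        spec100[51] = 3.0  # ~100 Hz bin
        spec300 = np.zeros(200, dtype=complex)
        spec300[154] = 3.0  # ~300 Hz bin
        fv = compute_features(_fake_mode_set([spec100, spec300, []]))
        assert fv.P1 == pytest.approx(1.0)
        assert fv.P2 == 0.0

    def test_zero_e1_flags_ratios(self, caplog):
        with caplog.at_level("WARNING"):
            fv = compute_features(_fake_mode_set([[], [1.0], []]))
        assert fv.P1 is None and fv.P2 is None
        assert "undefined" in caplog.text

    def test_circular_shift_invariance(self, rng):
        # circular shift is a pure phase factor only when nfft equals the
        # segment length (no zero padding)
        x = rng.normal(size=256)
        bank256 = st.build_filter_bank(nfft=256)
        a = compute_features(decompose(x, bank256))
        b = compute_features(decompose(np.roll(x, 37), bank256))
        assert a.e1 == pytest.approx(b.e1, rel=1e-9)
        assert a.e2 == pytest.approx(b.e2, rel=1e-9)
        assert a.e3 == pytest.approx(b.e3, rel=1e-9)

    def test_amplitude_scaling(self, bank, rng):
        x = rng.normal(size=256)
        a = compute_features(decompose(x, bank))
        b = compute_features(decompose(3.0 * x, bank))
        assert b.e1 == pytest.approx(9.0 * a.e1, rel=1e-9)
        assert b.e2 == pytest.approx(9.0 * a.e2, rel=1e-9)
        assert b.P1 == pytest.approx(a.P1, rel=1e-9)
        assert b.P2 == pytest.approx(a.P2, rel=1e-9)


class TestAggregate:
    def test_cad_mean_row(self):
        means = aggregate_cohort(CAD_ROWS, sig_figs=2)["mean"]
        assert means["e1"] == pytest.approx(8.6e-4)
        assert means["e2"] == pytest.approx(1.7e-6)
        assert means["P1"] == pytest.approx(0.0023)
        assert means["P2"] == pytest.approx(1.8e-4)

    def test_normal_mean_row(self):
        means = aggregate_cohort(NORMAL_ROWS, sig_figs=2)["mean"]
        assert means["e2"] == pytest.approx(2.0e-8)
        assert means["e3"] == pytest.approx(1.7e-10)

    def test_single_row(self):
        df = pd.DataFrame({c: [0.5] for c in FEATURE_COLUMNS})
        means = aggregate_cohort(df)["mean"]
        assert all(means[c] == 0.5 for c in FEATURE_COLUMNS)

    def test_empty(self):
        with pytest.raises(ValueError):
            aggregate_cohort(pd.DataFrame())

    def test_round_sig(self):
        assert round_sig(1.98333e-8, 2) == pytest.approx(2.0e-8)
        assert round_sig(0.0022833, 2) == pytest.approx(0.0023)
        assert round_sig(0.0, 2) == 0.0


class TestStandardizer:
    def _train(self, rng, n=50):
        data = rng.normal(2.0, 3.0, size=(n, 5))
        return pd.DataFrame(data, columns=list(FEATURE_COLUMNS))

    def test_train_columns_standardized(self, rng):
        train = self._train(rng)
        std = fit_standardizer(train)
        out = std.transform(train)[list(FEATURE_COLUMNS)].to_numpy()
        assert np.max(np.abs(out.mean(axis=0))) < 1e-12
        assert np.allclose(out.std(axis=0), 1.0)

    def test_row_at_train_mean_maps_to_zero(self, rng):
        train = self._train(rng)
        std = fit_standardizer(train)
        row = pd.DataFrame([train[list(FEATURE_COLUMNS)].mean()], columns=list(FEATURE_COLUMNS))
        assert np.allclose(std.transform(row).to_numpy(), 0.0, atol=1e-12)

    def test_affine_shift(self, rng):
        train = self._train(rng)
        std = fit_standardizer(train)
        test = self._train(rng, n=10)
        shifted = test.copy()
        shifted["e2"] = shifted["e2"] + 5.0
        delta = std.transform(shifted)["e2"] - std.transform(test)["e2"]
        sd_train = train["e2"].std(ddof=0)
        assert np.allclose(delta, 5.0 / sd_train)

    def test_zero_variance_named(self, rng):
        train = self._train(rng)
        train["e3"] = 1.0
        with pytest.raises(ValueError, match="e3"):
            fit_standardizer(train)

    def test_needs_two_rows(self, rng):
        with pytest.raises(ValueError):
            fit_standardizer(self._train(rng, n=1))
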