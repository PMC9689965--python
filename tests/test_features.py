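"""Relative power, spectral entropy, and Lempel-Ziv complexity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import lz76_brute
from restalpha.montage import CHANNELS_64
from restalpha.preprocessing import BANDS, EpochSet
from restalpha.features import (
    band_power,
    binarize_epoch,
    build_feature_table,
    epoch_set_features,
    lempel_ziv_complexity,
    lz76_pattern_count,
    n_band_bins,
    power_spectral_entropy,
    relative_power_level,
)

FS = 160.0
ALPHA = BANDS[1]


def flat_spectrum_signal(n, fs, band, rng):
    """Random-phase synthesis with exactly flat in-band magnitudes."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = (freqs >= band.low) & (freqs <= band.high)
    spec = np.zeros(len(freqs), complex)
    spec[mask] = np.exp(2j * np.pi * rng.random(mask.sum()))
    return np.fft.irfft(spec, n)


class TestBandPower:
    def test_constant_signal(self):
        assert band_power(np.full(123, 3.0)) == pytest.approx(9.0)

    def test_zero_signal(self):
        assert band_power(np.zeros(50)) == 0.0

    def test_sinusoid_closed_form(self):
        t = np.arange(1600) / FS
        x = 2.5 * np.sin(2 * np.pi * 10 * t)  # integer number of cycles
        assert band_power(x) == pytest.approx(2.5**2 / 2, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.array([]))


class TestRelativePower:
    def test_simplex_sum_is_exactly_one(self, rng):
        rpl = relative_power_level(rng.standard_normal(1500), FS)
        assert sum(rpl.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in rpl.values())

    def test_pure_alpha_sinusoid_dominates(self):
        t = np.arange(1500) / FS
        rpl = relative_power_level(np.sin(2 * np.pi * 10 * t), FS)
        assert rpl["alpha"] >= 0.95

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(1500)
        a = relative_power_level(x, FS)
        b = relative_power_level(10 * x, FS)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_all_zero_epoch_rejected(self):
        with pytest.raises(ValueError):
            relative_power_level(np.zeros(1500), FS)


class TestSpectralEntropy:
    def test_flat_spectrum_approaches_log_bin_bound(self, rng):
        n_bins = n_band_bins(1500, FS, ALPHA)
        x = flat_spectrum_signal(1500, FS, ALPHA, rng)
        pse = power_spectral_entropy(x, FS, ALPHA)
        assert pse <= np.log(n_bins) + 1e-9
        assert pse > 0.95 * np.log(n_bins)

    def test_single_sinusoid_concentrated(self):
        t = np.arange(1500) / FS
        x = np.sin(2 * np.pi * 10 * t)
        n_bins = n_band_bins(1500, FS, ALPHA)
        assert power_spectral_entropy(x, FS, ALPHA) < 0.25 * np.log(n_bins)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(1500)
        a = power_spectral_entropy(x, FS, ALPHA)
        assert power_spectral_entropy(7.3 * x, FS, ALPHA) == pytest.approx(a, rel=1e-9)

    def test_narrow_band_with_one_bin_rejected(self, rng):
        from restalpha.preprocessing import BandDefinition

        tiny = BandDefinition("tiny", 10.0, 10.05)  # < 2 bins at 1500 samples
        with pytest.raises(ValueError, match="bins"):
            power_spectral_entropy(rng.standard_normal(1500), FS, tiny)


class TestLempelZiv:
    def test_constant_sequence_minimal_count(self):
        n = 1500
        assert lz76_pattern_count(np.ones(n, dtype=np.uint8)) == 2
        lzc = lempel_ziv_complexity(np.full(n, 4.2))
        assert lzc == pytest.approx(2 * np.log2(n) / n, rel=1e-12)

    def test_periodic_sequence_low_complexity(self):
        n = 1500
        seq = np.tile([0, 1], n // 2)
        assert lz76_pattern_count(seq) * np.log2(n) / n < 0.05

    def test_random_sequences_near_one(self):
        rng = np.random.default_rng(99)
        n = 1500
        vals = [
            lz76_pattern_count(rng.integers(0, 2, n)) * np.log2(n) / n
            for _ in range(20)
        ]
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_matches_brute_force_parser(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 500))
            seq = rng.integers(0, 2, n)
            assert lz76_pattern_count(seq) == lz76_brute(seq)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=120))
    def test_matches_brute_force_parser_hypothesis(self, bits):
        seq = np.array(bits, dtype=np.uint8)
        assert lz76_pattern_count(seq) == lz76_brute(seq)

    def test_median_binarization_ties_to_one(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])  # median 2 -> ties map to 1
        assert binarize_epoch(x).tolist() == [0, 1, 1, 1]

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(1500)
        assert lempel_ziv_complexity(x) == lempel_ziv_complexity(5.0 * x)


class TestBandwidthMonotonicity:
    def test_wider_inband_noise_does_not_decrease_entropy_or_complexity(self):
        """Narrow 9.5-10.5 Hz noise vs the full alpha band, 20 seeds."""
        from restalpha.preprocessing import BandDefinition
        from restalpha.features import bandpass_array

        narrow = BandDefinition("narrow", 9.5, 10.5)
        pse_n, pse_w, lzc_n, lzc_w = [], [], [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal(1500)
            xn = bandpass_array(x, FS, narrow)
            xw = bandpass_array(x, FS, ALPHA)
            pse_n.append(power_spectral_entropy(xn, FS, ALPHA, prefiltered=True))
            pse_w.append(power_spectral_entropy(xw, FS, ALPHA, prefiltered=True))
            lzc_n.append(lempel_ziv_complexity(xn))
            lzc_w.append(lempel_ziv_complexity(xw))
        assert np.median(pse_w) >= np.median(pse_n)
        assert np.median(lzc_w) >= np.median(lzc_n)


class TestFeatureTable:
    def _epoch_set(self, rng, n_epochs=6, n_ch=2):
        epochs = rng.standard_normal((n_epochs, n_ch, 1500))
        return EpochSet("S001", "eyes_open", epochs, FS, CHANNELS_64[:n_ch])

    def test_cell_is_mean_over_epochs(self, rng):
        es = self._epoch_set(rng)
        table = epoch_set_features(es, features=("PSE",))
        # recompute one cell by hand from per-epoch values
        per_epoch = [
            power_spectral_entropy(es.epochs[e, 0], FS, ALPHA) for e in range(6)
        ]
        cell = table[
            (table.band == "alpha") & (table.channel == CHANNELS_64[0])
        ]["value"].iloc[0]
        assert cell == pytest.approx(np.mean(per_epoch), rel=1e-9)

    def test_identical_epochs_equal_single_epoch_value(self, rng):
        one = rng.standard_normal((1, 2, 1500))
        es6 = EpochSet("S", "eyes_open", np.repeat(one, 6, axis=0), FS, CHANNELS_64[:2])
        es1 = EpochSet("S", "eyes_open", one, FS, CHANNELS_64[:2])
        t6 = epoch_set_features(es6)
        t1 = epoch_set_features(es1)
        assert np.allclose(t6["value"].to_numpy(), t1["value"].to_numpy())

    def test_table_dimensions(self, rng):
        sets = []
        for subj in ("S001", "S002"):
            for state in ("eyes_open", "eyes_closed"):
                sets.append(
                    EpochSet(subj, state, rng.standard_normal((2, 3, 1500)), FS, CHANNELS_64[:3])
                )
        table = build_feature_table(sets)
        # subjects x states x bands x channels x features
        assert len(table) == 2 * 2 * 4 * 3 * 3

    def test_subject_missing_state_dropped(self, rng):
        sets = [
            EpochSet("S001", "eyes_open", rng.standard_normal((1, 2, 1500)), FS, CHANNELS_64[:2]),
            EpochSet("S001", "eyes_closed", rng.standard_normal((1, 2, 1500)), FS, CHANNELS_64[:2]),
            EpochSet("S002", "eyes_open", rng.standard_normal((1, 2, 1500)), FS, CHANNELS_64[:2]),
        ]
        table = build_feature_table(sets)
        assert set(table.subject) == {"S001"}
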