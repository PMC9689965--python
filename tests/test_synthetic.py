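"""Synthetic cohort generator: contracts, calibration, reproducibility."""

import numpy as np
import pytest

from restalpha.features import epoch_set_features
from restalpha.performance import crossval_accuracy
from restalpha.preprocessing import MI_BAND, bandpass_array, epoch_rest
from restalpha.synthetic import (
    CohortSpec,
    ground_truth,
    make_cohort,
    make_mi_trials,
    make_resting_recording,
    screening_cohort_spec,
    subject_parameters,
)


class TestSpecValidation:
    def test_rest_duration_too_short(self):
        with pytest.raises(ValueError, match="epoch"):
            CohortSpec(n_subjects=2, rest_duration=5.0)

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError, match="planted_rho"):
            CohortSpec(n_subjects=2, planted_rho=1.5)

    def test_negative_band_fraction(self):
        with pytest.raises(ValueError, match="non-negative"):
            CohortSpec(n_subjects=2, band_power_profile={"alpha": -0.1, "beta": 1.0})

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)

    def test_unknown_resting_state(self):
        spec = CohortSpec(n_subjects=2)
        with pytest.raises(ValueError, match="state"):
            make_resting_recording(spec, 0, "eyes_shut")


class TestRestingRuns:
    def test_one_minute_run_has_9600_samples(self):
        spec = CohortSpec(n_subjects=2, seed=0)
        rec = make_resting_recording(spec, 0, "eyes_open")
        assert rec.data.shape == (64, 9600)
        assert rec.sample_rate == 160.0

    def test_pure_alpha_profile_yields_alpha_rpl_near_one(self):
        spec = CohortSpec(
            n_subjects=2,
            band_power_profile={"theta": 0, "alpha": 1.0, "beta": 0, "gamma": 0},
            alpha_range=None,
            background_fraction=0.0,
            seed=3,
        )
        rec = make_resting_recording(spec, 0, "eyes_open")
        table = epoch_set_features(epoch_rest(rec), channels=("Cz",), features=("RPL",))
        alpha = table[table.band == "alpha"]["value"].iloc[0]
        assert alpha > 0.97

    def test_equal_profile_rpl_calibration_monte_carlo(self):
        """Mean measured RPL per band within +-0.05 of 0.25 over 50 runs."""
        vals = {b: [] for b in ("theta", "alpha", "beta", "gamma")}
        for seed in range(50):
            spec = CohortSpec(
                n_subjects=2,
                band_power_profile={k: 0.25 for k in vals},
                alpha_range=None,
                background_fraction=0.0,
                seed=seed,
            )
            rec = make_resting_recording(spec, 0, "eyes_open")
            table = epoch_set_features(
                epoch_rest(rec), channels=("C3", "Pz"), features=("RPL",)
            )
            for b in vals:
                vals[b].extend(table[table.band == b]["value"].tolist())
        for b, v in vals.items():
            assert abs(np.mean(v) - 0.25) < 0.05, (b, np.mean(v))

    def test_eyes_closed_adds_posterior_alpha(self):
        spec = CohortSpec(n_subjects=2, seed=5)
        eo = make_resting_recording(spec, 0, "eyes_open")
        ec = make_resting_recording(spec, 0, "eyes_closed")
        oz = eo.channel_labels.index("Oz")
        p_eo = np.mean(bandpass_array(eo.data[oz], 160.0, MI_BAND) ** 2)
        p_ec = np.mean(bandpass_array(ec.data[oz], 160.0, MI_BAND) ** 2)
        assert p_ec > 1.5 * p_eo

    def test_same_seed_bit_identical(self):
        a = make_resting_recording(CohortSpec(n_subjects=3, seed=9), 1, "eyes_open")
        b = make_resting_recording(CohortSpec(n_subjects=3, seed=9), 1, "eyes_open")
        assert np.array_equal(a.data, b.data)

    def test_subject_data_stable_under_cohort_growth(self):
        small = CohortSpec(n_subjects=3, seed=9)
        big = CohortSpec(n_subjects=10, seed=9)
        a = make_resting_recording(small, 2, "eyes_closed")
        b = make_resting_recording(big, 2, "eyes_closed")
        assert np.array_equal(a.data, b.data)


class TestMiTrials:
    def test_shapes_and_labels(self):
        spec = CohortSpec(n_subjects=2, trials_per_class=10, seed=0)
        ts = make_mi_trials(spec, 0)
        assert ts.trials.shape == (40, 64, 640)
        counts = {lb: int((ts.labels == lb).sum()) for lb in set(ts.labels)}
        assert counts == {
            "left_hand": 10, "right_hand": 10, "both_hands": 10, "feet": 10
        }

    def test_zero_separability_gives_chance_accuracy(self):
        accs = []
        for seed in range(3):
            spec = CohortSpec(
                n_subjects=2, separability_range=(0.0, 0.0),
                trials_per_class=20, seed=seed,
            )
            ts = make_mi_trials(spec, 0)
            tr = bandpass_array(ts.trials, 160.0, MI_BAND)
            accs.append(crossval_accuracy(tr, ts.labels, folds=5, reps=2, seed=seed).mean)
        assert abs(np.mean(accs) - 25.0) < 8.0

    def test_max_separability_exceeds_80_percent(self):
        spec = CohortSpec(
            n_subjects=2, separability_range=(0.95, 0.95), trials_per_class=75, seed=1
        )
        ts = make_mi_trials(spec, 0)
        tr = bandpass_array(ts.trials, 160.0, MI_BAND)
        acc = crossval_accuracy(tr, ts.labels, folds=10, reps=2, seed=1).mean
        assert acc > 80.0

    def test_accuracy_monotone_in_separability(self):
        """Spearman > 0.9 across 5 separability levels (10 seeds each)."""
        from scipy.stats import spearmanr

        levels = [0.05, 0.3, 0.5, 0.7, 0.95]
        means = []
        for s in levels:
            accs = []
            for seed in range(10):
                spec = CohortSpec(
                    n_subjects=2, separability_range=(s, s),
                    trials_per_class=15, seed=100 + seed,
                )
                ts = make_mi_trials(spec, 0)
                tr = bandpass_array(ts.trials, 160.0, MI_BAND)
                accs.append(
                    crossval_accuracy(tr, ts.labels, folds=5, reps=1, seed=seed).mean
                )
            means.append(np.mean(accs))
        rho = spearmanr(levels, means).statistic
        assert rho > 0.9

    def test_distinct_seeds_distinct_paths(self):
        a = make_mi_trials(CohortSpec(n_subjects=2, trials_per_class=5, seed=1), 0)
        b = make_mi_trials(CohortSpec(n_subjects=2, trials_per_class=5, seed=2), 0)
        assert not np.array_equal(a.trials, b.trials)


class TestGroundTruth:
    def test_planted_rho_recovered_in_ground_truth(self):
        gt = ground_truth(CohortSpec(n_subjects=100, planted_rho=0.5, seed=21))
        r = np.corrcoef(gt.alpha_fraction, gt.separability)[0, 1]
        assert abs(r - 0.5) < 0.15

    def test_null_rho_near_zero(self):
        gt = ground_truth(CohortSpec(n_subjects=100, planted_rho=0.0, seed=22))
        r = np.corrcoef(gt.alpha_fraction, gt.separability)[0, 1]
        assert abs(r) < 0.2

    def test_one_row_per_subject(self):
        gt = ground_truth(CohortSpec(n_subjects=105, seed=0))
        assert len(gt) == 105
        assert gt.subject.is_unique

    def test_separability_within_range(self):
        spec = CohortSpec(n_subjects=50, separability_range=(0.2, 0.6), seed=1)
        gt = ground_truth(spec)
        assert gt.separability.between(0.2, 0.6).all()

    def test_groups_follow_separability_thresholds(self):
        from restalpha.synthetic import GROUP_SEPARABILITY_THRESHOLDS

        gt = ground_truth(CohortSpec(n_subjects=50, seed=4))
        lo, hi = GROUP_SEPARABILITY_THRESHOLDS
        expected = np.where(
            gt.separability >= hi, "H", np.where(gt.separability >= lo, "M", "L")
        )
        assert (gt.intended_group == expected).all()


def test_make_cohort_returns_complete_bundle():
    spec = CohortSpec(n_subjects=2, trials_per_class=3, rest_duration=10, seed=0)
    recs, trials, gt = make_cohort(spec)
    assert set(recs) == {(s, st) for s in range(2) for st in ("eyes_open", "eyes_closed")}
    assert set(trials) == {0, 1}
    assert len(gt) == 2


def test_screening_preset_overrides():
    spec = screening_cohort_spec(n_subjects=10, seed=3)
    assert spec.planted_rho == 0.9
    assert spec.alpha_link_exponent > 1
    assert subject_parameters(spec, 0)["subject"] == "S001"
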