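"""Feature extraction, undersampling, and nested-CV decoding."""

import itertools

import numpy as np
import pytest

from trialaudit.classify import (
    ClassifierConfig,
    FeatureSpec,
    OfflineDecoder,
    balance_by_undersampling,
    extract_features,
    nested_cv_classify,
    nested_cv_on_features,
    run_offline_reanalysis,
)
from trialaudit.simulate import SyntheticConfig, effect_config, generate_dataset, hrf

from conftest import make_dataset, random_dataset

FAST_CFG = ClassifierConfig(c_grid=(0.01, 1.0), outer_folds=5, inner_folds=3, seed=0)


class TestFeatures:
    def test_constant_signal_baseline_corrected_is_zero(self):
        ds = make_dataset([np.full((3, 2, 10), 7.0)], [np.full((2, 2, 10), 7.0)],
                          sampling_rate=2.0, t0=-2.0)
        table = extract_features(ds.days[0], FeatureSpec(baseline_window_s=(-2.0, 0.0),
                                                         response_window_s=(0.5, 2.0)),
                                 ds.time_axis)
        assert np.all(table.X == 0.0)
        assert table.n_trials == 5

    def test_noiseless_effect_feature_equals_hrf_window_mean(self):
        """beta = 2 noiseless data: every yes-feature equals 2x the mean of
        h over the response-window samples (direct quadrature oracle)."""
        cfg = SyntheticConfig(sessions_per_day=2, trials_per_condition=2, n_channels=3,
                              effect_amplitude=2.0, shared_noise_sd=0.0,
                              channel_noise_sd=0.0)
        ds = generate_dataset(cfg)
        spec = FeatureSpec()
        table = extract_features(ds.days[0], spec, ds.time_axis)
        t = ds.time_axis
        h = hrf(t)
        sel = (t >= spec.response_window_s[0]) & (t <= spec.response_window_s[1])
        expected = 2.0 * h[sel].mean()  # baseline of h is 0
        for x, label in zip(table.X, table.y):
            target = expected if label == "yes" else 0.0
            np.testing.assert_allclose(x, target, rtol=1e-12, atol=1e-12)

    def test_feature_length_is_channel_count(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, n_channels=20, n_tp=12)
        table = extract_features(
            ds.days[0],
            FeatureSpec(baseline_window_s=(-1.0, 0.0), response_window_s=(0.5, 4.0)),
            ds.time_axis,
        )
        assert table.X.shape[1] == 20

    def test_full_timecourse_length(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n_channels=4, n_tp=12)
        spec = FeatureSpec(representation="full_timecourse",
                           baseline_window_s=(-1.0, 0.0), response_window_s=(0.0, 3.0))
        t = ds.time_axis
        n_resp = int(((t >= 0.0) & (t <= 3.0)).sum())
        table = extract_features(ds.days[0], spec, t)
        assert table.X.shape[1] == 4 * n_resp

    def test_empty_window_errors(self):
        rng = np.random.default_rng(2)
        ds = random_dataset(rng, n_tp=6)
        with pytest.raises(ValueError, match="response"):
            extract_features(ds.days[0],
                             FeatureSpec(response_window_s=(40.0, 50.0),
                                         baseline_window_s=(-1.0, 0.0)),
                             ds.time_axis)


class TestBalancing:
    def test_already_balanced_keeps_everything(self):
        labels = np.array(["yes", "no"] * 5)
        np.testing.assert_array_equal(balance_by_undersampling(labels, 0), np.arange(10))

    def test_majority_class_trimmed(self):
        labels = np.array(["yes"] * 7 + ["no"] * 3)
        kept = balance_by_undersampling(labels, 1)
        assert len(kept) == 6
        assert (labels[kept] == "yes").sum() == 3
        assert (labels[kept] == "no").sum() == 3
        removed = set(range(10)) - set(kept.tolist())
        assert all(labels[i] == "yes" for i in removed)

    def test_uniform_over_majority_subsets_enumeration_oracle(self):
        """4 yes / 2 no: each of the C(4,2) = 6 kept yes-pairs should appear
        with frequency 1/6 (+- 0.02) over 1e4 seeds."""
        labels = np.array(["yes"] * 4 + ["no"] * 2)
        counts = {frozenset(c): 0 for c in itertools.combinations(range(4), 2)}
        n = 10_000
        for seed in range(n):
            kept = balance_by_undersampling(labels, seed)
            counts[frozenset(i for i in kept if labels[i] == "yes")] += 1
        assert len(counts) == 6
        for c in counts.values():
            assert c / n == pytest.approx(1 / 6, abs=0.02)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            balance_by_undersampling(np.array(["yes", "yes"]), 0)


class TestNestedCV:
    def test_separable_features_are_perfectly_decoded(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.array(["yes", "no"] * (n // 2))
        X = rng.standard_normal((n, 5)) * 0.01
        X[:, 0] += np.where(y == "yes", 10.0, -10.0)
        day = nested_cv_on_features(X, y, FAST_CFG)
        assert day.accuracy == 1.0
        assert all(f.accuracy == 1.0 for f in day.folds)

    def test_balance_law_in_every_fold(self):
        rng = np.random.default_rng(4)
        y = np.array(["yes"] * 70 + ["no"] * 30)
        X = rng.standard_normal((100, 6))
        day = nested_cv_on_features(X, y, FAST_CFG)
        for f in day.folds:
            counts = set(f.balanced_class_counts.values())
            assert len(counts) == 1  # equal class counts after balancing

    def test_pooled_counts_partition_all_trials(self):
        rng = np.random.default_rng(5)
        y = np.array(["yes", "no"] * 30)
        X = rng.standard_normal((60, 4))
        day = nested_cv_on_features(X, y, FAST_CFG)
        assert day.n == 60
        seen = np.concatenate([f.test_indices for f in day.folds])
        assert sorted(seen.tolist()) == list(range(60))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        y = np.array(["yes", "no"] * 25)
        X = rng.standard_normal((50, 4))
        d1 = nested_cv_on_features(X, y, FAST_CFG)
        d2 = nested_cv_on_features(X, y, FAST_CFG)
        assert d1.k == d2.k and d1.selected_c == d2.selected_c

    def test_heldout_labels_cannot_leak(self):
        """Permuting the labels of a held-out block changes neither the
        selected C nor the trained model's decision values on that block."""
        rng = np.random.default_rng(7)
        y = np.array(["yes", "no"] * 30)
        X = rng.standard_normal((60, 8))
        cfg = ClassifierConfig(c_grid=(0.01, 1.0, 100.0), outer_folds=5,
                               inner_folds=3, seed=3)
        base = nested_cv_on_features(X, y, cfg)
        splits = [(np.setdiff1d(np.arange(60), f.test_indices), f.test_indices)
                  for f in base.folds]
        for fold_i in (0, 2):
            y_mut = y.copy()
            test_idx = splits[fold_i][1]
            y_mut[test_idx] = np.where(y[test_idx] == "yes", "no", "yes")
            mut = nested_cv_on_features(X, y_mut, cfg, outer_splits=splits)
            assert mut.folds[fold_i].selected_c == base.folds[fold_i].selected_c
            np.testing.assert_allclose(mut.folds[fold_i].decision_values,
                                       base.folds[fold_i].decision_values)

    def test_requires_both_classes_and_enough_trials(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="both classes"):
            nested_cv_on_features(X, np.array(["yes"] * 20), FAST_CFG)
        with pytest.raises(ValueError, match="outer_folds"):
            nested_cv_on_features(X[:4], np.array(["yes", "no"] * 2), FAST_CFG)


class TestReanalysis:
    def test_single_day_report(self):
        ds = generate_dataset(SyntheticConfig(sessions_per_day=4, trials_per_condition=5,
                                              n_channels=4, seed=9))
        rep = run_offline_reanalysis(ds, cfg=FAST_CFG)
        assert len(rep.days) == 1
        assert rep.mean_accuracy == rep.days[0].accuracy
        assert rep.days[0].n == 40
        d = rep.to_dict()
        assert d["days"][0]["k"] + 0 <= 40
        assert "mean accuracy" in rep.summary()

    def test_null_days_rarely_significant(self):
        """5-day null dataset: at least 4 days should be non-significant at
        alpha = 0.05 (nominal one-sided binomial behaviour)."""
        ds = generate_dataset(SyntheticConfig(n_days=5, sessions_per_day=3,
                                              trials_per_condition=6, n_channels=6,
                                              seed=10))
        rep = run_offline_reanalysis(ds, cfg=FAST_CFG)
        assert rep.n_significant_days <= 1
        # p-values are reported per day, uncorrected
        assert len(rep.to_dict()["days"]) == 5

    def test_effect_strong_recovery_single_seed(self):
        ds = generate_dataset(effect_config("effect-strong", seed=0))
        rep = OfflineDecoder(ds, config=ClassifierConfig(seed=0)).fit()
        assert rep.days[0].accuracy >= 0.75
        assert rep.days[0].chance_test.p_value < 0.01

    def test_nested_cv_classify_matches_feature_route(self):
        ds = generate_dataset(SyntheticConfig(sessions_per_day=4, trials_per_condition=5,
                                              n_channels=4, seed=11))
        fspec = FeatureSpec()
        day = nested_cv_classify(ds.days[0], fspec, FAST_CFG, ds.time_axis)
        table = extract_features(ds.days[0], fspec, ds.time_axis)
        ref = nested_cv_on_features(table.X, table.y, FAST_CFG, day_id=ds.days[0].day_id)
        assert day.k == ref.k and day.selected_c == ref.selected_c
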