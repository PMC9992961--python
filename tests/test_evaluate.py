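import numpy as np
import pytest

from eegfusion.evaluate import (ConfusionMatrix, PipelineConfig, accuracy,
                                confusion, csp_baseline, five_fold_cv,
                                fit_fold, kappa, kappa_from_confusion,
                                paired_t_test, score_fold)
from eegfusion.preprocess import preprocess
from eegfusion.synth import SynthConfig, generate_mi_dataset


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(ConfusionMatrix([[10, 0], [0, 10]])) == 1.0

    def test_coin_flip(self):
        assert accuracy(ConfusionMatrix([[5, 5], [5, 5]])) == 0.5

    def test_three_class_trace_over_total(self):
        cm = ConfusionMatrix([[30, 10, 5], [5, 20, 10], [5, 5, 10]])
        assert cm.total == 100
        assert accuracy(cm) == pytest.approx(0.60)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy(ConfusionMatrix(np.zeros((2, 2), dtype=int)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ConfusionMatrix([[1, -1], [0, 2]])


class TestKappa:
    def test_fixed_points(self):
        assert kappa(0.5, 2) == 0.0
        assert kappa(1.0, 2) == 1.0
        assert kappa(1 / 3, 3) == pytest.approx(0.0)

    def test_reported_binary_value(self):
        assert round(kappa(0.7852, 2), 4) == 0.5704

    def test_reported_three_class_values(self):
        assert round(kappa(0.5706, 3), 4) == 0.3559
        assert round(kappa(0.5108, 3), 4) == 0.2662
        assert round(kappa(0.5024, 3), 4) == 0.2536

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kappa(0.5, 1)
        with pytest.raises(ValueError):
            kappa(1.5, 2)

    def test_marginal_chance_variant(self):
        cm = ConfusionMatrix([[40, 10], [10, 40]])
        # symmetric margins -> marginal pe = 0.5 = uniform pe
        assert kappa_from_confusion(cm, "marginal") == \
            pytest.approx(kappa_from_confusion(cm, "uniform"))


class TestConfusion:
    def test_diagonal_when_equal(self):
        cm = confusion([0, 1, 1, 2], [0, 1, 1, 2], n_classes=3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_single_error_placement(self):
        cm = confusion([0], [1], n_classes=2)
        # rows = predicted, columns = true
        assert cm.counts[1, 0] == 1 and cm.counts.sum() == 1

    def test_column_sums_are_true_counts(self, rng):
        y_true = rng.integers(0, 3, size=200)
        y_pred = rng.integers(0, 3, size=200)
        cm = confusion(y_true, y_pred, n_classes=3)
        assert np.array_equal(cm.counts.sum(axis=0), np.bincount(y_true, minlength=3))
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(y_pred, minlength=3))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            confusion([0, 3], [0, 1], n_classes=2)


class TestPairedT:
    def test_identical_vectors_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])

    def test_constant_difference_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([0.8, 0.7, 0.9], [0.6, 0.5, 0.7])

    def test_matches_closed_form(self):
        a = [0.8, 0.7, 0.9]
        b = [0.61, 0.5, 0.69]
        t, p = paired_t_test(a, b)
        d = np.array(a) - np.array(b)
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_ref, abs=1e-6)
        # closed-form two-sided p for Student t with 2 dof
        p_ref = 1.0 - t_ref / np.sqrt(2.0 + t_ref ** 2)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_sign_convention(self):
        t, _ = paired_t_test([0.9, 0.8, 0.85], [0.5, 0.45, 0.52])
        assert t > 0


@pytest.fixture(scope="module")
def cv_data():
    cfg = SynthConfig(n_classes=2, n_trials_per_class=50, n_channels=8,
                      duration=2.0, erd_depth=0.8, seed=17)
    return generate_mi_dataset(cfg)


class TestFiveFoldCV:
    def test_stratification_arithmetic(self, cv_data):
        report = five_fold_cv(cv_data, PipelineConfig(pipeline="csp"), seed=0)
        for fold in report.per_fold:
            cm = np.asarray(fold["confusion"])
            assert cm.sum() == 20
            assert list(cm.sum(axis=0)) == [10, 10]

    def test_mean_is_average_of_folds(self, cv_data):
        report = five_fold_cv(cv_data, PipelineConfig(pipeline="csp"), seed=0)
        assert report.mean_accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in report.per_fold]))

    def test_seed_determinism(self, cv_data):
        cfg = PipelineConfig(pipeline="csp")
        r1 = five_fold_cv(cv_data, cfg, seed=3)
        r2 = five_fold_cv(cv_data, cfg, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_too_few_trials_rejected(self, cv_data):
        small = cv_data.subset(np.r_[0:3, 50:53])
        with pytest.raises(ValueError, match="5-fold"):
            five_fold_cv(small, PipelineConfig(pipeline="csp"), seed=0)

    def test_permuted_labels_near_chance(self, cv_data):
        rng = np.random.default_rng(0)
        shuffled = cv_data.subset(np.arange(cv_data.n_trials))
        shuffled.labels = rng.permutation(shuffled.labels)
        report = five_fold_cv(shuffled, PipelineConfig(pipeline="csp"), seed=1)
        assert abs(report.mean_accuracy - 0.5) <= 0.15

    def test_report_serializes(self, cv_data):
        import json
        report = five_fold_cv(cv_data, PipelineConfig(pipeline="csp"), seed=0)
        text = json.dumps(report.to_dict())
        assert "mean_accuracy" in text


class TestCSPBaseline:
    def test_no_signal_is_chance(self):
        accs = []
        for seed in (1, 2, 3):
            ds = generate_mi_dataset(SynthConfig(
                n_classes=2, n_trials_per_class=25, n_channels=8,
                duration=2.0, erd_depth=0.0, seed=seed))
            accs.append(csp_baseline(ds, seed=seed).mean_accuracy)
        assert abs(np.median(accs) - 0.5) <= 0.1

    def test_strong_signal_recovered(self):
        accs = []
        for seed in (1, 2, 3):
            ds = preprocess(generate_mi_dataset(SynthConfig(
                n_classes=2, n_trials_per_class=25, erd_depth=0.8, seed=seed)))
            accs.append(csp_baseline(ds, seed=seed).mean_accuracy)
        assert np.median(accs) >= 0.85

    def test_feature_dimensionality(self, cv_data):
        from eegfusion.csp import fit_csp_ovr
        from eegfusion.evaluate import _log_variance_features
        models = fit_csp_ovr(cv_data)
        feats = _log_variance_features(cv_data, models, m=2)
        assert feats.shape == (cv_data.n_trials, 2 * 2 * len(models))

    def test_monotone_in_erd_depth(self):
        # separability is non-decreasing in erd_depth on average
        depths = [0.0, 0.4, 0.8]
        means = []
        for depth in depths:
            accs = [csp_baseline(generate_mi_dataset(SynthConfig(
                n_classes=2, n_trials_per_class=20, n_channels=8,
                duration=2.0, erd_depth=depth, seed=seed)), seed=seed
            ).mean_accuracy for seed in (1, 2, 3)]
            means.append(np.mean(accs))
        assert means[0] - 0.1 <= means[1] + 1e-9
        assert means[1] <= means[2] + 0.05
        assert means[2] > 0.9


class TestNoLeakage:
    def test_fit_fold_ignores_absent_test_data(self, cv_data):
        cfg = PipelineConfig(
            pipeline="csp")
        train_idx = np.r_[0:40, 50:90]
        m1 = fit_fold(cv_data.subset(train_idx), cfg, seed=0)
        # corrupt would-be test trials; fits must be byte-identical
        corrupted = cv_data.subset(np.arange(cv_data.n_trials))
        corrupted.data[40:50] = 0.123
        corrupted.data[90:100] = -0.5
        m2 = fit_fold(corrupted.subset(train_idx), cfg, seed=0)
        assert m1.state_bytes() == m2.state_bytes()

    def test_fusion_fits_are_leakage_free(self):
        ds = generate_mi_dataset(SynthConfig(
            n_classes=2, n_trials_per_class=8, n_channels=6, duration=1.0,
            erd_depth=0.8, seed=19))
        from eegfusion.branches import EEGCNNConfig, TFCNNConfig, TrainConfig
        cfg = PipelineConfig(
            pipeline="fusion",
            eeg_cnn=EEGCNNConfig(filters=(2, 2), fc_units=8),
            tf_cnn=TFCNNConfig(width_multiplier=0.03125, fc_units=16),
            train=TrainConfig(epochs=2, learning_rate=1e-3, batch_size=8),
        )
        train_idx = np.r_[0:6, 8:14]
        m1 = fit_fold(ds.subset(train_idx), cfg, seed=0)
        corrupted = ds.subset(np.arange(ds.n_trials))
        corrupted.data[6:8] = 0.0
        corrupted.data[14:16] = 9.9
        m2 = fit_fold(corrupted.subset(train_idx), cfg, seed=0)
        assert m1.state_bytes() == m2.state_bytes()
        # scoring the same test fold is deterministic
        s1 = score_fold(m1, ds.subset(np.r_[6:8, 14:16]), cfg)
        s2 = score_fold(m2, ds.subset(np.r_[6:8, 14:16]), cfg)
        assert s1["accuracy"] == s2["accuracy"]
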