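"""Splits, metrics, statistical tests, the SGD loop and the CV/ablation drivers."""

import numpy as np
import pytest
from scipy import stats

from bmnet import (BMNetConfig, CohortSpec, LossConfig, SplitError,
                   TrainConfig, confusion_metrics, delong_test,
                   generate_cohort, holdout_split, paired_fold_ttest, roc_auc,
                   run_ablation, run_cv_experiment, stratified_kfold_split,
                   train_model)


class TestStratifiedKFold:
    def test_emci_lmci_fold_sizes(self):
        """A 290/147 cohort at k=5 must give class-0 folds of 58 and class-1
        folds of sizes {30, 30, 29, 29, 29}."""
        y = np.r_[np.zeros(290, int), np.ones(147, int)]
        split = stratified_kfold_split(y, 5, seed=0)
        sizes0, sizes1 = [], []
        for fold in range(5):
            mask = split.assignment == fold
            sizes0.append(int(np.sum(mask & (y == 0))))
            sizes1.append(int(np.sum(mask & (y == 1))))
        assert sizes0 == [58] * 5
        assert sorted(sizes1, reverse=True) == [30, 30, 29, 29, 29]

    def test_degenerate_k_raises(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        with pytest.raises(SplitError):
            stratified_kfold_split(y, 1, seed=0)
        with pytest.raises(SplitError, match="smallest class"):
            stratified_kfold_split(y, 6, seed=0)

    @pytest.mark.parametrize("n0,n1,k", [(23, 17, 4), (50, 10, 5), (9, 8, 3)])
    def test_folds_partition_cohort(self, n0, n1, k):
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        split = stratified_kfold_split(y, k, seed=1)
        seen = set()
        for fold in range(k):
            _, test_idx = split.fold_indices(fold)
            assert seen.isdisjoint(test_idx)
            seen.update(test_idx.tolist())
        assert seen == set(range(n0 + n1))


class TestHoldoutSplit:
    def test_bad_fractions_raise(self):
        with pytest.raises(SplitError, match="sum to 1"):
            holdout_split(np.array([0, 1] * 10), fractions=(0.8, 0.1, 0.2))

    def test_partition_and_stratification(self):
        y = np.r_[np.zeros(200, int), np.ones(100, int)]
        split = holdout_split(y, seed=3)
        sizes = [int(np.sum(split.assignment == part)) for part in range(3)]
        assert sum(sizes) == 300
        assert sizes[0] == 240 and sizes[1] == 30 and sizes[2] == 30
        for part in range(3):
            frac1 = np.mean(y[split.assignment == part])
            assert abs(frac1 - 1 / 3) < 0.05


class TestConfusionMetrics:
    def test_forced_confusion_table(self):
        # TP=8, FN=2, TN=7, FP=3
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        p = np.r_[np.full(8, 0.9), np.full(2, 0.1),
                  np.full(7, 0.1), np.full(3, 0.9)]
        m = confusion_metrics(p, y)
        assert m["sen"] == pytest.approx(0.8)
        assert m["spe"] == pytest.approx(0.7)
        assert m["acc"] == pytest.approx(0.75)
        assert m["ppv"] == pytest.approx(8 / 11)
        assert m["npv"] == pytest.approx(7 / 9)
        # F1 = 2TP/(2TP+FP+FN) = 16/21 (harmonic mean of 8/11 and 8/10)
        assert m["f1"] == pytest.approx(16 / 21)
        assert m["undefined"] == ()

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(np.array([0.1, 0.9, 0.2, 0.8]), y)
        for key in ("acc", "ppv", "npv", "sen", "spe", "f1"):
            assert m[key] == 1.0

    def test_all_positive_predictions_flag_undefined_npv(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(np.full(4, 0.9), y)
        assert m["spe"] == 0.0
        assert m["npv"] is None
        assert "npv" in m["undefined"]

    def test_acc_identity_with_sen_spe(self, rng):
        y = rng.integers(0, 2, size=50)
        p = rng.uniform(size=50)
        m = confusion_metrics(p, y)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        acc = (m["sen"] * n_pos + m["spe"] * n_neg) / (n_pos + n_neg)
        assert m["acc"] == pytest.approx(acc, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_total_ties_give_half(self):
        assert roc_auc(np.full(6, 0.4), np.array([0, 0, 0, 1, 1, 1])) == 0.5

    def test_exhaustive_pair_enumeration_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == pytest.approx(3 / 4)

    def test_matches_pair_enumeration_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            scores = np.round(rng.uniform(size=n), 1)  # force ties sometimes
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(1.0 if ps > ns else 0.5 if ps == ns else 0.0
                       for ps in pos for ns in neg)
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLong:
    def test_self_comparison_p_is_one(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        res = delong_test(scores, scores, labels)
        assert res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_aucs_equal_mann_whitney(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        sa, sb = rng.uniform(size=40), rng.uniform(size=40)
        res = delong_test(sa, sb, labels)
        assert res.auc_a == pytest.approx(roc_auc(sa, labels), abs=1e-12)
        assert res.auc_b == pytest.approx(roc_auc(sb, labels), abs=1e-12)

    def test_antisymmetric_in_model_order(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        sa, sb = rng.uniform(size=30), rng.uniform(size=30)
        ab = delong_test(sa, sb, labels)
        ba = delong_test(sb, sa, labels)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.z == pytest.approx(-ba.z)


class TestPairedFoldTTest:
    def test_identical_vectors_give_p_one(self):
        res = paired_fold_ttest(np.full(5, 0.8), np.full(5, 0.8))
        assert res.p_value == 1.0 and res.degenerate

    def test_constant_nonzero_difference_flagged_degenerate(self):
        res = paired_fold_ttest(np.full(5, 0.9), np.full(5, 0.8))
        assert res.degenerate and res.p_value == 0.0

    def test_matches_from_scratch_t_formula(self, rng):
        a = rng.uniform(0.6, 0.9, size=5)
        b = rng.uniform(0.6, 0.9, size=5)
        res = paired_fold_ttest(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * (1 - stats.t.cdf(abs(t), df=len(d) - 1))
        assert res.t == pytest.approx(t, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)


class TestTrainModel:
    def _data(self, shift=3.0, n=100, regions=10, seed=0):
        spec = CohortSpec(n_per_class=(n, n), n_regions=regions, mean_shift=shift)
        cohort = generate_cohort(spec, seed).cohort
        return cohort.features, cohort.labels

    def _cfg(self, regions=10):
        return BMNetConfig(n_regions=regions, conv_channels=(4, 8), bp_rank=8,
                           bp_out=16, embedding_dim=8)

    def test_fixed_seed_reproduces_final_loss(self):
        X, y = self._data(n=30)
        tcfg = TrainConfig(epochs=4, seed=11)
        _, log_a = train_model(X, y, self._cfg(), LossConfig(), tcfg)
        _, log_b = train_model(X, y, self._cfg(), LossConfig(), tcfg)
        assert log_a[-1]["total_loss"] == log_b[-1]["total_loss"]

    def test_separable_cohort_reaches_high_training_accuracy(self):
        X, y = self._data(shift=3.0, n=100)
        model, _ = train_model(X, y, self._cfg(), LossConfig(),
                               TrainConfig(epochs=50, seed=0))
        acc = np.mean((model.forward(X).probability >= 0.5) == y)
        assert acc >= 0.95

    def test_joint_loss_linearity_visible_in_log(self):
        X, y = self._data(n=30)
        for lam in (0.0, 0.05):
            lcfg = LossConfig(lam=lam, metric_kind="triplet") if lam else \
                LossConfig(lam=0.0, metric_kind="triplet")
            _, log = train_model(X, y, self._cfg(), lcfg,
                                 TrainConfig(epochs=3, seed=2))
            for entry in log:
                assert entry["total_loss"] == pytest.approx(
                    entry["ce_loss"] + lam * entry["metric_loss"], abs=1e-12)
                assert entry["metric_loss"] > 0  # mined and computed either way

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 10))
        from bmnet import TrainingError
        with pytest.raises(TrainingError, match="both classes"):
            train_model(X, np.zeros(10, int), self._cfg(), LossConfig(),
                        TrainConfig(epochs=1))


class TestRunCvExperiment:
    def test_report_structure_and_summary_arithmetic(self, small_cohort):
        cfg = BMNetConfig(n_regions=8, conv_channels=(4, 6), bp_rank=4,
                          bp_out=8, embedding_dim=6)
        report = run_cv_experiment(small_cohort, cfg, LossConfig(),
                                   TrainConfig(epochs=3, seed=0), k=3)
        assert len(report.per_fold) == 3
        for metric in ("acc", "auc", "sen", "spe"):
            vals = report.fold_values(metric)
            assert report.summary[metric]["mean"] == pytest.approx(
                vals.mean(), abs=1e-12)
        assert np.all(np.isfinite(report.oof_scores))

    def test_rerun_bit_identical(self, small_cohort):
        cfg = BMNetConfig(n_regions=8, conv_channels=(4, 6), bp_rank=4,
                          bp_out=8, embedding_dim=6)
        args = (small_cohort, cfg, LossConfig(metric_kind="contrastive"),
                TrainConfig(epochs=2, seed=5))
        assert run_cv_experiment(*args, k=3).to_json() == \
            run_cv_experiment(*args, k=3).to_json()


class TestRunAblation:
    @pytest.fixture(scope="class")
    @staticmethod
    def ablation():
        spec = CohortSpec(n_per_class=(16, 12), n_regions=8, mean_shift=1.0)
        cohort = generate_cohort(spec, 2).cohort
        cfg = BMNetConfig(n_regions=8, conv_channels=(3, 4), bp_rank=4,
                          bp_out=8, embedding_dim=4)
        tcfg = TrainConfig(epochs=2, batch_size=8, seed=9)
        return cohort, cfg, tcfg, run_ablation(cohort, cfg, tcfg, k=2)

    def test_six_variants_present_with_stats(self, ablation):
        *_, result = ablation
        assert set(result.reports) == {"Baseline", "Baseline+BP", "Tri-loss",
                                       "Tri-loss+BP", "Con-loss", "Con-loss+BP"}
        assert set(result.stats_vs_baseline) == set(result.reports) - {"Baseline"}
        for entry in result.stats_vs_baseline.values():
            assert 0 <= entry["delong_p"] <= 1

    def test_all_variants_share_fold_assignments(self, ablation):
        cohort, cfg, tcfg, result = ablation
        expected = stratified_kfold_split(cohort.labels, 2, tcfg.seed)
        np.testing.assert_array_equal(result.folds.assignment, expected.assignment)
        for rep in result.reports.values():
            assert rep.config["k"] == 2

    def test_baseline_row_equals_direct_cv_run(self, ablation):
        cohort, cfg, tcfg, result = ablation
        direct_cfg = BMNetConfig.from_dict({**cfg.to_dict(), "use_bp": False})
        direct = run_cv_experiment(cohort, direct_cfg,
                                   LossConfig(metric_kind="none"), tcfg, k=2)
        assert direct.to_json() == result.reports["Baseline"].to_json()
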