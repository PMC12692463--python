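"""Metrics identities, CV protocols, LOSO balancing, training contracts."""

import numpy as np
import pandas as pd
import pytest

import neurofuse as nf
from neurofuse.model import ModelConfig
from neurofuse.train_eval import (MetricsReport, TrainConfig,
                                  balanced_test_indices, compute_metrics,
                                  evaluate, kfold_cv, loso_cv, train,
                                  tsne_embed, export_embeddings, _prepare)


class TestComputeMetrics:
    def test_enumerated_confusion_matrix_identities(self):
        """Counts (TP=3, FN=1, TN=2, FP=2) give the closed-form metrics."""
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        m = compute_metrics(labels, predicted=pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 2, 2)
        assert m.accuracy == pytest.approx(0.625)
        assert m.recall == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)
        assert m.balanced_accuracy == pytest.approx(0.625)

    def test_brute_force_counting_on_random_instances(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, size=30)
            pred = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            m = compute_metrics(labels, predicted=pred)
            n = len(labels)
            acc = sum(int(a == b) for a, b in zip(labels, pred)) / n
            assert m.accuracy == pytest.approx(acc)
            m.validate()

    def test_perfectly_ranked_scores_auc_one(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        assert compute_metrics(labels, scores=scores).auc == 1.0

    def test_auc_matches_trapezoidal_roc_integration(self, rng):
        """Rank-statistic AUC equals the trapezoid-integrated ROC built by
        sweeping all thresholds, including tied scores."""
        for trial in range(10):
            labels = rng.integers(0, 2, size=50)
            if labels.sum() in (0, 50):
                continue
            scores = np.round(rng.uniform(size=50), 2)  # force ties
            m = compute_metrics(labels, scores=scores)
            thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
            fpr, tpr = [], []
            for t in thresholds:
                pred = scores >= t
                tp = ((labels == 1) & pred).sum()
                fp = ((labels == 0) & pred).sum()
                tpr.append(tp / (labels == 1).sum())
                fpr.append(fp / (labels == 0).sum())
            auc_trap = np.trapezoid(tpr, fpr)
            assert abs(m.auc - auc_trap) < 1e-9

    def test_single_class_auc_missing(self):
        with pytest.warns(UserWarning, match="AUC"):
            m = compute_metrics(np.ones(4, dtype=int),
                                scores=np.array([0.2, 0.6, 0.7, 0.9]))
        assert m.auc is None

    def test_threshold_half_on_scores(self):
        labels = np.array([0, 1])
        m = compute_metrics(labels, scores=np.array([0.49, 0.51]))
        assert (m.tn, m.tp) == (1, 1)

    def test_self_validation_catches_corruption(self):
        m = compute_metrics(np.array([0, 1]), predicted=np.array([0, 1]))
        m.accuracy = 0.123
        with pytest.raises(AssertionError):
            m.validate()


class TestBalancedDownsampling:
    def test_50_33_site_evaluated_on_33_33(self):
        labels = np.r_[np.ones(50, dtype=int), np.zeros(33, dtype=int)]
        idx = np.arange(83)
        out = balanced_test_indices(labels, idx, np.random.default_rng(0))
        assert labels[out].sum() == 33
        assert (1 - labels[out]).sum() == 33
        assert len(np.unique(out)) == 66  # without replacement

    def test_balanced_site_is_noop(self):
        labels = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        out = balanced_test_indices(labels, np.arange(20),
                                    np.random.default_rng(0))
        assert sorted(out) == list(range(20))

    def test_seeded_downsampling_reproducible(self):
        labels = np.r_[np.ones(40, dtype=int), np.zeros(20, dtype=int)]
        a = balanced_test_indices(labels, np.arange(60),
                                  np.random.default_rng(5))
        b = balanced_test_indices(labels, np.arange(60),
                                  np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def test_history_shape_and_determinism(self, tiny_cohort,
                                           tiny_model_config):
        cohort, _ = tiny_cohort
        tc = TrainConfig.desk_scale(epochs=2, seed=3)
        _, h1 = train(cohort, tiny_model_config, tc)
        _, h2 = train(cohort, tiny_model_config, tc)
        assert len(h1) == 2
        assert set(h1.columns) >= {"loss_disease", "loss_site",
                                   "reported_objective", "train_accuracy"}
        assert abs(h1.loss_disease.iloc[-1] - h2.loss_disease.iloc[-1]) < 1e-6

    def test_beta_positive_single_site_rejected(self, tiny_cohort,
                                                tiny_model_config):
        cohort, _ = tiny_cohort
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        single_site = np.where(cohort.sites == 0)[0]
        with pytest.raises(ValueError, match="two training sites"):
            train(cohort, tiny_model_config, tc, train_idx=single_site)

    def test_separable_toy_cohort_reaches_high_train_accuracy(self):
        """beta=0, strongly separable disease effect: training accuracy
        climbs toward 1 within a few epochs."""
        cfg = nf.SimulationConfig(
            n_sites=1, subjects_per_site=(12, 12), d_regions=8,
            t_ranges=[(90, 94)], gmv_dims=(10, 10, 10),
            ts_disease_shift=4.0, gmv_disease_shift=4.0,
            ts_offset_sd=0.0, ts_gain_sd=0.0, gmv_offset_sd=0.0,
            gmv_gain_sd=0.0, seed=2)
        cohort, _ = nf.simulate_cohort(cfg)
        mc = ModelConfig.compact(d_in=8, n_sites=1, use_grl=False)
        tc = TrainConfig.desk_scale(epochs=10, seed=0)
        _, hist = train(cohort, mc, tc)
        assert hist.train_accuracy.iloc[-1] > 0.95


class TestKFold:
    def test_folds_partition_and_stratify(self, tiny_cohort,
                                          tiny_model_config):
        from sklearn.model_selection import StratifiedKFold
        cohort, _ = tiny_cohort
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = []
        for _, te in skf.split(np.zeros(len(cohort)), cohort.labels):
            seen.extend(te)
            assert set(cohort.labels[te]) == {0, 1}
        assert sorted(seen) == list(range(len(cohort)))

    def test_kfold_cv_reports_and_summary(self, tiny_cohort):
        cohort, _ = tiny_cohort
        mc = ModelConfig.compact(d_in=8, n_sites=3)
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        tc.k_folds = 3
        reports, summary = kfold_cv(cohort, mc, tc)
        assert len(reports) == 3
        accs = [r.accuracy for r in reports]
        assert summary.loc["accuracy", "mean"] == pytest.approx(
            np.mean(accs))
        assert summary.loc["accuracy", "sd"] == pytest.approx(
            np.std(accs, ddof=1))


class TestLOSO:
    def test_one_row_per_site_and_no_training_leakage(self, tiny_cohort):
        cohort, _ = tiny_cohort
        mc = ModelConfig.compact(d_in=8, n_sites=3)
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        table = loso_cv(cohort, mc, tc)
        assert len(table) == 3
        assert sorted(table.site) == [0, 1, 2]
        # every site is balanced by construction in the fixture (4/4)
        assert (table.n_mdd == table.n_hc).all()

    def test_too_few_sites_rejected(self, tiny_cohort):
        cohort, _ = tiny_cohort
        mc = ModelConfig.compact(d_in=8, n_sites=3)
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        sub = np.where(cohort.sites < 2)[0]
        import dataclasses
        small = dataclasses.replace(
            cohort, records=[cohort.records[i] for i in sub],
            ts=[cohort.ts[i] for i in sub], gmv=cohort.gmv[sub],
            labels=cohort.labels[sub], sites=cohort.sites[sub], n_sites=2)
        with pytest.raises(ValueError, match="three sites"):
            loso_cv(small, mc, tc)


class TestEmbeddings:
    def test_export_shape_and_tsne_determinism(self, tiny_cohort):
        cohort, _ = tiny_cohort
        mc = ModelConfig.compact(d_in=8, n_sites=3)
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        model, _ = train(cohort, mc, tc)
        table = export_embeddings(model, cohort)
        assert len(table) == len(cohort)
        assert table.shape[1] == mc.ts.d_out + 3
        a = tsne_embed(table, seed=4)
        b = tsne_embed(table, seed=4)
        np.testing.assert_allclose(a[["tsne1", "tsne2"]].to_numpy(),
                                   b[["tsne1", "tsne2"]].to_numpy())
        assert set(a.columns) == {"subject_id", "site_id", "label",
                                  "tsne1", "tsne2"}
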