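"""Splitting, resampling, metrics, training and the per-SOC suite."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.modeling import _roc_auc, default_params


def brute_force_auc(y_true, y_prob):
    """Exhaustive positive-negative pair concordance with 0.5 tie credit."""
    pos = [p for t, p in zip(y_true, y_prob) if t == 1]
    neg = [p for t, p in zip(y_true, y_prob) if t == 0]
    if not pos or not neg:
        return math.nan
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    def test_stratified_proportions(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 30 + [0] * 70)
        X = rng.random((100, 4))
        train, test = pv.split_data(X, y, pv.SplitSpec(0.2, True, 0))
        assert len(train) == 80 and len(test) == 20
        assert abs(int(y[test].sum()) - 6) <= 1  # class ratio preserved +-1
        assert len(set(train) & set(test)) == 0
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        X = np.arange(80).reshape(40, 2).astype(float)
        s = pv.SplitSpec(0.25, True, 7)
        a = pv.split_data(X, y, s)
        b = pv.split_data(X, y, s)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            pv.SplitSpec(test_fraction=fraction)

    def test_single_class_falls_back_with_warning(self):
        y = np.zeros(20, dtype=int)
        X = np.random.default_rng(0).random((20, 3))
        with pytest.warns(UserWarning, match="stratify"):
            train, test = pv.split_data(X, y, pv.SplitSpec(0.2, True, 0))
        assert len(train) == 16 and len(test) == 4


class TestSmoteTomek:
    @staticmethod
    def _imbalanced(n_min=10, n_maj=90, seed=0):
        rng = np.random.default_rng(seed)
        X_min = rng.normal(0, 1, size=(n_min, 5))
        X_maj = rng.normal(3, 1, size=(n_maj, 5))
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * n_min + [0] * n_maj)
        return X, y

    def test_smote_balances_then_tomek_cleans(self):
        X, y = self._imbalanced()
        Xr, yr, info = pv.resample_smote_tomek(X, y, seed=0)
        assert info["post_smote_counts"] == {0: 90, 1: 90}
        assert info["post_counts"][0] <= 90  # Tomek removes only majority members
        assert info["post_counts"][1] == 90

    def test_synthetic_rows_are_convex_combinations(self):
        X, y = self._imbalanced(n_min=8, n_maj=40)
        Xr, yr, info = pv.resample_smote_tomek(X, y, seed=3)
        X_min = X[y == 1]
        synth = Xr[yr == 1][len(X_min):][: info["n_synthetic"]]
        lo, hi = X_min.min(axis=0), X_min.max(axis=0)
        assert (synth >= lo - 1e-9).all() and (synth <= hi + 1e-9).all()

    def test_balanced_input_smote_noop(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        Xr, yr, info = pv.resample_smote_tomek(X, y, seed=0)
        assert info["n_synthetic"] == 0
        assert info["post_smote_counts"] == {0: 10, 1: 10}

    def test_seeded_determinism(self):
        X, y = self._imbalanced()
        a = pv.resample_smote_tomek(X, y, seed=5)
        b = pv.resample_smote_tomek(X, y, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_minority_reduces_k_with_warning(self):
        X, y = self._imbalanced(n_min=3, n_maj=30)
        with pytest.warns(UserWarning, match="reduced to k=2"):
            Xr, yr, info = pv.resample_smote_tomek(X, y, k_neighbors=5, seed=0)
        assert info["k_used"] == 2
        assert info["post_smote_counts"] == {0: 30, 1: 30}

    def test_minority_below_two_skips_with_warning(self):
        X, y = self._imbalanced(n_min=1, n_maj=10)
        with pytest.warns(UserWarning, match="skipping"):
            Xr, yr, info = pv.resample_smote_tomek(X, y, seed=0)
        assert info["skipped"] is True
        np.testing.assert_array_equal(Xr, X)


class TestMetrics:
    def test_worked_confusion_example(self):
        # tp=2, fp=1, fn=1, tn=96
        y_true = np.array([1, 1, 1, 0] + [0] * 96)
        y_pred = np.array([1, 1, 0, 1] + [0] * 96)
        y_prob = y_pred.astype(float)
        m = pv.compute_metrics(y_true, y_prob, y_pred)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 96)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(191 / 291)
        assert m.accuracy == pytest.approx(98 / 100)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = pv.compute_metrics(y, y.astype(float), y)
        assert m.accuracy == 1.0 and m.mcc == 1.0 and m.roc_auc == 1.0

    def test_auc_tie_free_pair_enumeration(self):
        # one concordant and one discordant positive-negative pair
        m = pv.compute_metrics([1, 0, 1], [0.9, 0.8, 0.3], [1, 1, 0])
        assert m.roc_auc == pytest.approx(0.5)

    def test_undefined_conventions_flagged(self):
        m = pv.compute_metrics([0, 0, 1], [0.1, 0.2, 0.3], [0, 0, 0])
        assert m.precision == 0.0 and m.flags["precision_undefined"]
        assert m.f1 == 0.0 and m.flags["f1_undefined"]
        assert m.mcc == 0.0 and m.flags["mcc_degenerate"]
        m2 = pv.compute_metrics([0, 0, 0], [0.1, 0.2, 0.3], [0, 1, 0])
        assert math.isnan(m2.roc_auc) and m2.flags["roc_auc_undefined"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pv.compute_metrics([1, 0], [0.5], [1])

    def test_all_metrics_match_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(4, 60))
            y_true = rng.integers(0, 2, n)
            y_prob = np.round(rng.random(n), 2)  # force ties
            y_pred = (y_prob > 0.5).astype(int)
            m = pv.compute_metrics(y_true, y_prob, y_pred)
            want = brute_force_auc(y_true, y_prob)
            if math.isnan(want):
                assert math.isnan(m.roc_auc)
            else:
                assert m.roc_auc == pytest.approx(want, abs=1e-10)
            tp = int(((y_true == 1) & (y_pred == 1)).sum())
            fp = int(((y_true == 0) & (y_pred == 1)).sum())
            fn = int(((y_true == 1) & (y_pred == 0)).sum())
            tn = int(((y_true == 0) & (y_pred == 0)).sum())
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))


class TestTraining:
    @staticmethod
    def _data(n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 6))
        y = (X[:, 0] + 0.2 * rng.random(n) > 0.6).astype(int)
        return X, y

    def test_forest_of_one_equals_its_tree(self):
        X, y = self._data()
        forest = pv.train_classifier(
            X, y, "forest",
            {"n_estimators": 1, "max_features": 1.0, "class_weight": None,
             "min_samples_split": 2, "min_samples_leaf": 1},
            seed=0,
        )
        single = forest.estimators_[0]
        np.testing.assert_array_equal(
            forest.predict(X), (single.predict(X) > 0.5).astype(int)
        )

    def test_unconstrained_tree_fits_consistent_labels_perfectly(self):
        X, y = self._data()
        tree = pv.train_classifier(X, y, "tree", default_params("tree"), seed=0)
        assert (tree.predict(X) == y).all()

    def test_deterministic_given_seed(self):
        X, y = self._data()
        a = pv.train_classifier(X, y, "forest", seed=3).predict_proba(X)
        b = pv.train_classifier(X, y, "forest", seed=3).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pv.train_classifier(np.empty((0, 3)), np.empty(0), "forest")

    def test_unknown_kind_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="kind"):
            pv.train_classifier(X, y, "svm")


class TestOptimization:
    @staticmethod
    def _data(seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((40, 5))
        y = (X[:, 1] > 0.5).astype(int)
        return X, y

    def test_single_trial_returns_default_configuration(self):
        X, y = self._data()
        best, trials = pv.optimize_hyperparameters(
            X, y, kind="tree", n_trials=1, cv_folds=2, seed=0, resample=False
        )
        assert len(trials) == 1
        assert best == default_params("tree")

    def test_best_is_argmax_of_trial_log(self):
        X, y = self._data()
        best, trials = pv.optimize_hyperparameters(
            X, y, kind="forest", n_trials=6, cv_folds=2, seed=1,
            resample=False,
            space=pv.SearchSpace(n_estimators=(10, 30)),
        )
        best_score = max(t["score"] for t in trials)
        assert any(t["params"] == best and t["score"] == best_score for t in trials)

    def test_search_never_loses_to_default(self):
        # trial 0 evaluates the default configuration, so the optimum
        # dominates it (ties allowed) under the same CV protocol
        for seed in (0, 1, 2):
            X, y = self._data(seed)
            _, trials = pv.optimize_hyperparameters(
                X, y, kind="tree", n_trials=5, cv_folds=2, seed=seed,
                resample=False,
            )
            assert max(t["score"] for t in trials) >= trials[0]["score"]

    def test_invalid_trial_count(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            pv.optimize_hyperparameters(X, y, n_trials=0)


class TestRunAllSocs:
    @staticmethod
    def _suite(seed=0):
        rng = np.random.default_rng(seed)
        n = 80
        drugs = [f"d{i:03d}" for i in range(n)]
        targets = [f"t{j}" for j in range(6)]
        X = rng.random((n, 6)) * (rng.random((n, 6)) < 0.5)
        labels = np.zeros((n, 2), dtype=int)
        labels[:, 0] = (X[:, 0] > 0.55).astype(int)  # learnable SOC
        labels[rng.choice(n, 8, replace=False), 1] = 1  # noise SOC
        features = pv.InteractionMatrix(drugs, targets, X)
        lab = pv.SignalLabelMatrix(drugs, ["SOC A", "SOC B"], labels)
        return features, lab

    def test_bundle_bookkeeping(self):
        features, labels = self._suite()
        res = pv.run_all_socs(
            features, labels,
            pv.RunSettings(n_trials=0, optimize=False, seed=0),
        )
        assert len(res.bundles) == 4  # 2 SOCs x 2 kinds
        frame = res.metrics_frame()
        assert set(frame["model_kind"]) == {"forest", "tree"}
        assert set(frame["soc"]) == {"SOC A", "SOC B"}

    def test_identical_metrics_give_degenerate_t(self):
        from pvsignal.modeling import _paired_ttest

        out = _paired_ttest([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert out["degenerate"] is True and out["statistic"] == 0.0

    def test_pooled_percentages_conserve_test_cells(self):
        features, labels = self._suite()
        res = pv.run_all_socs(
            features, labels, pv.RunSettings(n_trials=0, optimize=False)
        )
        for kind in ("forest", "tree"):
            pooled = res.pooled[kind]
            pct = sum(pooled[f"pct_{k}"] for k in ("tp", "fp", "fn", "tn"))
            assert pct == pytest.approx(100.0)
            n_test = sum(
                len(b.test_idx) for b in res.bundles
                if b.kind == kind and b.trainable
            )
            assert pooled["total"] == n_test

    def test_untrainable_soc_is_marked_and_excluded(self):
        features, labels = self._suite()
        labels.labels[:, 1] = 0
        labels.labels[0, 1] = 1  # a single positive: untrainable
        res = pv.run_all_socs(
            features, labels, pv.RunSettings(n_trials=0, optimize=False)
        )
        socb = [b for b in res.bundles if b.soc == "SOC B"]
        assert all(not b.trainable for b in socb)
        assert all("positive" in b.reason for b in socb)
        assert res.comparison["roc_auc"]["n"] == 1  # only SOC A pairs

    def test_misaligned_drugs_rejected(self):
        features, labels = self._suite()
        labels.drug_ids[0] = "other"
        with pytest.raises(ValueError, match="identical drugs"):
            pv.run_all_socs(features, labels)
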