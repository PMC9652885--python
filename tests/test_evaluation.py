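import numpy as np
import pandas as pd
import pytest

from eegsel.evaluation import (_zscore_train_test, evaluate_configuration,
                               fisher_score, fisher_scores, lpo_folds)
from eegsel.features import FeatureTable


def make_table(X, n_mci, n_hc, seed=0):
    ids = [f"MCI{i}" for i in range(n_mci)] + [f"HC{i}" for i in range(n_hc)]
    values = pd.DataFrame(np.asarray(X, dtype=float),
                          index=pd.Index(ids, name="subject_id"),
                          columns=[f"f{j}" for j in range(np.shape(X)[1])])
    labels = pd.Series(["MCI"] * n_mci + ["HC"] * n_hc, index=values.index)
    return FeatureTable(values, labels)


def random_table(n_mci=6, n_hc=6, n_feat=10, seed=0):
    rng = np.random.default_rng(seed)
    return make_table(rng.standard_normal((n_mci + n_hc, n_feat)), n_mci, n_hc)


class TestFisherScore:
    def test_identical_distributions_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["MCI"] * 3 + ["HC"] * 3
        assert fisher_score(vals, labels) == 0.0

    def test_known_value(self, rng):
        # means 0 and 1, unit variances -> (0-1)^2/(1+1) = 0.5
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000) + 1.0
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1) + 1.0
        score = fisher_score(np.concatenate([a, b]),
                             ["MCI"] * 5000 + ["HC"] * 5000)
        assert score == pytest.approx(0.5, rel=1e-9)

    def test_shift_invariance(self, rng):
        vals = rng.standard_normal(20)
        labels = ["MCI"] * 10 + ["HC"] * 10
        assert fisher_score(vals, labels) == pytest.approx(
            fisher_score(vals + 100.0, labels), rel=1e-9)

    def test_flat_feature_scores_zero(self):
        vals = np.ones(8)
        assert fisher_score(vals, ["MCI"] * 4 + ["HC"] * 4) == 0.0

    def test_zero_denominator_unequal_means_is_inf(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.warns(RuntimeWarning):
            assert fisher_score(vals, ["MCI", "MCI", "HC", "HC"]) == np.inf

    def test_matrix_matches_scalar(self, rng):
        X = rng.standard_normal((12, 5))
        labels = ["MCI"] * 6 + ["HC"] * 6
        scores = fisher_scores(X, labels)
        for j in range(5):
            assert scores[j] == pytest.approx(fisher_score(X[:, j], labels))


class TestLpoFolds:
    def test_21x21_gives_441(self):
        assert len(lpo_folds(21, 21)) == 441

    def test_3x5_gives_15(self):
        assert len(lpo_folds(3, 5)) == 15

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            lpo_folds(1, 1)

    def test_training_excludes_test(self):
        for (ti, tj), train in lpo_folds(3, 4):
            assert ti not in train and tj not in train
            assert len(train) == 5

    def test_deterministic_order(self):
        a = [t for t, _ in lpo_folds(4, 4)]
        assert a == [t for t, _ in lpo_folds(4, 4)]


class TestZScore:
    def test_train_mean_zero_sd_one(self, rng):
        train = rng.standard_normal((30, 8)) * 5 + 2
        test = rng.standard_normal((2, 8))
        z_train, _ = _zscore_train_test(train, test)
        np.testing.assert_allclose(z_train.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z_train.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_test_uses_train_stats(self, rng):
        train = rng.standard_normal((30, 2))
        test = train[:2].copy()
        z_train, z_test = _zscore_train_test(train, test)
        np.testing.assert_allclose(z_test, z_train[:2], atol=1e-12)


class TestEvaluateConfiguration:
    def test_accuracy_identity(self):
        res = evaluate_configuration(random_table(), max_features=5)
        np.testing.assert_array_equal(
            res.per_n_accuracy,
            (res.per_n_sensitivity + res.per_n_specificity) / 2.0)
        assert res.accuracy == (res.sensitivity + res.specificity) / 2.0
        # the identity the published rates satisfy: 63.95/84.13 -> 74.04
        assert (63.95 + 84.13) / 2 == pytest.approx(74.04, abs=0.005)

    def test_best_accuracy_is_max_over_n(self):
        res = evaluate_configuration(random_table(seed=3), max_features=6)
        assert res.accuracy == res.per_n_accuracy.max()
        assert res.per_n_accuracy[res.best_n - 1] == res.accuracy

    def test_perfectly_separating_feature(self):
        X = np.zeros((12, 3))
        X[:, 0] = [1] * 6 + [-1] * 6
        rng = np.random.default_rng(0)
        X[:, 1:] = rng.standard_normal((12, 2))
        res = evaluate_configuration(make_table(X, 6, 6))
        assert res.best_n == 1
        assert res.accuracy == 100.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_max_features_capped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="capped"):
            res = evaluate_configuration(random_table(n_feat=3), max_features=15)
        assert res.max_features == 3

    def test_fold_count(self):
        res = evaluate_configuration(random_table(n_mci=3, n_hc=5), max_features=2)
        assert res.n_folds == 15

    def test_permutation_null_near_chance(self):
        accs = []
        for seed in range(15):
            res = evaluate_configuration(
                random_table(n_mci=6, n_hc=6, n_feat=8, seed=seed),
                max_features=2)
            accs.append(res.accuracy)
        assert 35.0 < np.mean(accs) < 65.0

    def test_changing_test_subject_changes_result(self):
        table = random_table(seed=11)
        res_a = evaluate_configuration(table, max_features=3)
        values = table.values.copy()
        values.iloc[0] = values.iloc[0] + 50.0  # move one MCI subject far away
        res_b = evaluate_configuration(FeatureTable(values, table.labels),
                                       max_features=3)
        assert not np.array_equal(res_a.per_n_accuracy, res_b.per_n_accuracy)

    def test_block_sd_manual(self):
        # 2 MCI x 2 HC: blocks are the two MCI rows of the fold grid
        X = np.array([[1.0, 0.0], [0.1, 0.0], [-1.0, 0.0], [-0.1, 0.0]])
        res = evaluate_configuration(make_table(X, 2, 2), max_features=1)
        assert res.n_folds == 4
        fold_acc = []
        # manual LPO with the same rules
        for i in (0, 1):
            for j in (2, 3):
                train = [t for t in range(4) if t not in (i, j)]
                mu = X[train, 0].mean()
                sd = X[train, 0].std(ddof=1)
                z = (X[:, 0] - mu) / sd
                # linear SVM on 1 feature, one subject per class: midpoint rule
                thr = (z[train[0]] + z[train[1]]) / 2
                sign = 1 if z[train[0]] > z[train[1]] else -1
                pred_i = sign * (z[i] - thr) > 0
                pred_j = sign * (z[j] - thr) <= 0
                fold_acc.append(50.0 * (pred_i + pred_j))
        blocks = np.array(fold_acc).reshape(2, 2).mean(axis=1)
        assert res.block_sd == pytest.approx(blocks.std(ddof=1))

    def test_rbf_kernel_runs(self):
        res = evaluate_configuration(random_table(), max_features=2, kernel="rbf")
        assert res.kernel == "rbf"
        assert 0.0 <= res.accuracy <= 100.0
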