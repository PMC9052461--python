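from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

from omicsel import (ClassLabels, DiscretizedMatrix, OmicsMatrix, cv_accuracy,
                     redundancy_rate, representation_entropy)
from omicsel.evaluation import CLASSIFIERS, confusion_counts

from conftest import labels_from_codes


def matrix_of(values):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(tuple(f"f{i}" for i in range(values.shape[0])),
                       tuple(f"s{j}" for j in range(values.shape[1])), values)


def separable_dataset(rng, n_per_class=30, d=6):
    y = np.repeat([0, 1], n_per_class)
    X = rng.normal(size=(d, 2 * n_per_class)) * 0.3
    X[0] += np.where(y == 1, 4.0, -4.0)
    X[1] += np.where(y == 1, 4.0, -4.0)
    return matrix_of(X), labels_from_codes(y)


class TestConfusionCounts:
    def test_multiclass_reductions_sum_correctly(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "c", "a"]
        cc = confusion_counts(y_true, y_pred)
        assert cc.n == 6
        assert cc.accuracy == pytest.approx(4 / 6)
        np.testing.assert_array_equal(cc.tp + cc.tn + cc.fp + cc.fn,
                                      [6, 6, 6])

    def test_binary_accuracy_equals_tp_tn_over_total(self):
        y_true = [0, 0, 1, 1, 1]
        y_pred = [0, 1, 1, 1, 0]
        cc = confusion_counts(y_true, y_pred)
        acc = (cc.tp[1] + cc.tn[1]) / cc.n
        assert cc.accuracy == pytest.approx(acc)


class TestCvAccuracy:
    @pytest.mark.parametrize("clf", CLASSIFIERS)
    def test_separable_clouds_near_perfect(self, clf):
        rng = np.random.default_rng(40)
        data, labels = separable_dataset(rng)
        est = cv_accuracy(data, labels, list(data.feature_ids), clf,
                          folds=5, repeats=2, seed=0)
        assert est.mean_pct >= 95.0

    def test_permuted_labels_give_chance_level(self):
        rng = np.random.default_rng(41)
        n = 120
        data = matrix_of(rng.normal(size=(8, n)))
        y = np.repeat([0, 1, 2], n // 3)
        labels = labels_from_codes(rng.permutation(y))
        est = cv_accuracy(data, labels, list(data.feature_ids), "KNN",
                          folds=10, repeats=10, seed=0)
        assert abs(est.mean_pct - 100 / 3) <= 5.0

    def test_identical_seed_gives_identical_estimate(self):
        rng = np.random.default_rng(42)
        data, labels = separable_dataset(rng, n_per_class=20)
        a = cv_accuracy(data, labels, list(data.feature_ids), "AdaBoost",
                        folds=4, repeats=2, seed=9)
        b = cv_accuracy(data, labels, list(data.feature_ids), "AdaBoost",
                        folds=4, repeats=2, seed=9)
        assert (a.mean_pct, a.std_pct) == (b.mean_pct, b.std_pct)

    def test_tuning_grid_reports_best_setting(self):
        rng = np.random.default_rng(43)
        data, labels = separable_dataset(rng, n_per_class=15)
        grid = [{"n_neighbors": k} for k in (1, 5, 9)]
        est = cv_accuracy(data, labels, list(data.feature_ids), "KNN",
                          folds=3, repeats=1, seed=0, tuning=grid)
        assert est.best_params["n_neighbors"] in (1, 5, 9)

    def test_infeasible_folds_rejected(self):
        rng = np.random.default_rng(44)
        data = matrix_of(rng.normal(size=(3, 8)))
        labels = labels_from_codes(np.array([0] * 6 + [1] * 2))
        with pytest.raises(ValueError, match="infeasible"):
            cv_accuracy(data, labels, list(data.feature_ids), "KNN", folds=5)

    def test_unknown_classifier_rejected(self):
        rng = np.random.default_rng(45)
        data, labels = separable_dataset(rng, n_per_class=10)
        with pytest.raises(ValueError, match="unknown classifier"):
            cv_accuracy(data, labels, list(data.feature_ids), "SVM", folds=2)


class TestRedundancyRate:
    def test_duplicated_features_give_rr_one_under_both_sims(self):
        rng = np.random.default_rng(50)
        row = rng.normal(size=40)
        data = matrix_of(np.vstack([row] * 4))
        assert redundancy_rate(data, sim="pearson") == pytest.approx(1.0)
        states = np.sign(np.vstack([row] * 4)).astype(int)
        disc = DiscretizedMatrix(data.feature_ids, data.sample_ids, states)
        assert redundancy_rate(disc, sim="nmi") == pytest.approx(1.0)

    def test_two_features_rr_equals_pairwise_similarity(self):
        rng = np.random.default_rng(51)
        a = rng.normal(size=50)
        b = 0.5 * a + rng.normal(size=50)
        data = matrix_of(np.vstack([a, b]))
        assert redundancy_rate(data, sim="pearson") == \
            pytest.approx(abs(np.corrcoef(a, b)[0, 1]))

    def test_independent_features_have_low_pearson_rr(self):
        rng = np.random.default_rng(52)
        data = matrix_of(rng.normal(size=(50, 200)))
        assert redundancy_rate(data, sim="pearson") < 0.1

    def test_rr_invariant_to_feature_order(self):
        rng = np.random.default_rng(53)
        vals = rng.normal(size=(6, 40))
        a = redundancy_rate(matrix_of(vals))
        b = redundancy_rate(matrix_of(vals[::-1]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            redundancy_rate(matrix_of(np.ones((1, 10))))


class TestRepresentationEntropy:
    def test_rank_one_covariance_gives_zero(self):
        rng = np.random.default_rng(60)
        row = rng.normal(size=30)
        data = matrix_of(np.vstack([row, 2 * row, -row]))
        assert representation_entropy(data).entropy_bits == \
            pytest.approx(0.0, abs=1e-9)

    def test_equal_eigenvalues_give_log2_d(self):
        # orthogonal zero-mean rows with equal norms -> covariance = c*I
        H = scipy.linalg.hadamard(8).astype(float)
        data = matrix_of(H[1:5])  # rows orthogonal, zero-mean
        assert representation_entropy(data).entropy_bits == \
            pytest.approx(np.log2(4), abs=1e-12)

    def test_eigenvalues_three_one_closed_form(self):
        # construct data whose covariance has eigenvalues {3, 1}:
        # normalized spectrum {0.75, 0.25} -> 0.811278 bits
        n = 8
        a = np.sqrt(3.0) * scipy.linalg.hadamard(n)[1].astype(float)
        b = scipy.linalg.hadamard(n)[2].astype(float)
        data = matrix_of(np.vstack([a, b]))
        summary = representation_entropy(data, ddof=0)
        np.testing.assert_allclose(sorted(summary.eigenvalues), [1.0, 3.0],
                                   atol=1e-9)
        assert summary.entropy_bits == pytest.approx(0.81128, abs=1e-5)

    def test_bounds_and_feature_order_invariance(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            d = int(rng.integers(2, 10))
            vals = rng.normal(size=(d, 25))
            re = representation_entropy(matrix_of(vals))
            assert 0.0 <= re.entropy_bits <= np.log2(d) + 1e-9
            assert re.normalized.sum() == pytest.approx(1.0, abs=1e-9)
            re_rev = representation_entropy(matrix_of(vals[::-1]))
            assert re.entropy_bits == pytest.approx(re_rev.entropy_bits,
                                                    abs=1e-9)

    def test_zero_covariance_rejected(self):
        data = matrix_of(np.ones((3, 10)))
        with pytest.raises(ValueError, match="zero covariance"):
            representation_entropy(data)
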