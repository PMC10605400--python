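"""Confusion metrics, Youden thresholding, and cross-validated models."""

import numpy as np
import pandas as pd
import pytest

from csprad.models import (CLASSIFIER_FAMILIES, ClassifierSpec, ConfusionCounts,
                           CVConfig, ThresholdedScoreClassifier,
                           YoudenThresholdClassifier, confusion_from_predictions,
                           evaluate_univariate, make_classifier,
                           metrics_from_confusion, multivariate_search,
                           youden_fit)
from csprad.selection import partition_stratified


class TestConfusionMetrics:
    def test_all_positive_prediction_ppv(self):
        # 111 lesions all predicted positive, 79 truly positive
        m = metrics_from_confusion(ConfusionCounts(tp=79, fp=32, tn=0, fn=0))
        assert round(100 * m["ppv"]) == 71
        assert m["sensitivity"] == 1.0
        assert np.isnan(m["npv"])

    def test_symmetric_counts_all_half(self):
        m = metrics_from_confusion(ConfusionCounts(5, 5, 5, 5))
        assert all(m[k] == 0.5 for k in m)

    def test_hand_arithmetic(self):
        m = metrics_from_confusion(ConfusionCounts(tp=8, fp=2, tn=6, fn=4))
        assert m["sensitivity"] == pytest.approx(0.667, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.750, abs=5e-4)
        assert m["ppv"] == pytest.approx(0.800, abs=5e-4)
        assert m["npv"] == pytest.approx(0.600, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.700, abs=5e-4)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics_from_confusion(ConfusionCounts(tp, fp, tn, fn))
            p, n = tp + fn, tn + fp
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n) / (p + n))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)


class TestYouden:
    def test_separable_classes(self):
        model = youden_fit([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert model.j == pytest.approx(1.0)
        assert 0.2 < model.threshold < 0.8
        assert model.orientation == 1
        np.testing.assert_array_equal(
            model.predict([0.05, 0.5, 0.95]), [False, True, True])

    def test_uninformative_flagged(self):
        model = youden_fit([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert model.j == pytest.approx(0.0)
        assert not model.informative

    def test_lower_values_predict_positive(self):
        model = youden_fit([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert model.orientation == -1
        assert model.predict([0.0])[0]

    def test_matches_bruteforce_scan(self):
        """Exhaustive candidate scan oracle on interleaved toy sets and
        random configurations."""

        def brute(values, labels):
            v = np.asarray(values, float)
            y = np.asarray(labels, bool)
            uniq = np.unique(v)
            cands = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2, np.inf]
            best = (-np.inf, None, None)
            for orient in (1, -1):
                for t in cands:
                    pred = (v >= t) if orient == 1 else (v < t)
                    sens = pred[y].mean()
                    spec = (~pred[~y]).mean()
                    j = sens + spec - 1
                    if j > best[0] + 1e-12:
                        best = (j, orient, t)
            return best

        cases = [([1, 4, 2, 5, 3, 6], [0, 1, 0, 1, 0, 1])]
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            cases.append((rng.integers(0, 6, n).astype(float),
                          rng.integers(0, 2, n)))
        for values, labels in cases:
            labels = np.asarray(labels)
            if labels.all() or not labels.any():
                continue
            model = youden_fit(values, labels)
            j_b, orient_b, t_b = brute(values, labels)
            assert model.j == pytest.approx(j_b, abs=1e-12)
            assert model.orientation == orient_b
            assert model.threshold == pytest.approx(t_b)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            youden_fit([1.0, 2.0], [1, 1])


class TestEvaluateUnivariate:
    def _table(self, rng, n=60, informative=True):
        y = np.r_[np.ones(40), np.zeros(20)].astype(bool)
        x = rng.standard_normal(n) + (3.0 * y if informative else 0.0)
        return pd.DataFrame({"f": x}), y

    def test_separable_feature_perfect(self):
        y = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        table = pd.DataFrame({"f": np.where(y, 10.0, 0.0)})
        s = evaluate_univariate(table, y, "f", CVConfig(n_repeats=3, seed=0))
        assert s.mean["sensitivity"] == 1.0 and s.sd["sensitivity"] == 0.0
        assert s.mean["specificity"] == 1.0 and s.sd["specificity"] == 0.0

    def test_noise_feature_near_chance(self):
        rng = np.random.default_rng(1)
        table, y = self._table(rng, informative=False)
        s = evaluate_univariate(table, y, "f", CVConfig(n_repeats=10, seed=0))
        # prevalence 2/3: accuracy should hover near max-class rate or below
        assert 0.3 < s.mean["accuracy"] < 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        table, y = self._table(rng)
        s1 = evaluate_univariate(table, y, "f", CVConfig(n_repeats=5, seed=4))
        s2 = evaluate_univariate(table, y, "f", CVConfig(n_repeats=5, seed=4))
        assert s1.mean == s2.mean and s1.sd == s2.sd

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            evaluate_univariate(pd.DataFrame({"f": [1.0, 2.0]}),
                                [0, 1], "g")


class TestMultivariateSearch:
    def _data(self, rng, n=60):
        y = np.r_[np.ones(40), np.zeros(20)].astype(bool)
        table = pd.DataFrame({
            "good": rng.standard_normal(n) + 2.5 * y,
            "weak": rng.standard_normal(n) + 0.5 * y,
            "noise": rng.standard_normal(n),
        })
        return table, y

    def test_spec_count_combinatorics(self):
        rng = np.random.default_rng(0)
        table, y = self._data(rng)
        res = multivariate_search(table, y, ["good", "weak"],
                                  CVConfig(n_repeats=2, seed=0),
                                  families=("lda", "knn"))
        assert len(res) == 3 * 2  # (2^2 - 1) subsets x 2 families

    def test_pool_of_four_gives_90_specs(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(30), np.zeros(15)].astype(bool)
        table = pd.DataFrame(rng.standard_normal((45, 4)),
                             columns=list("abcd"))
        res = multivariate_search(table, y, list("abcd"),
                                  CVConfig(n_repeats=1, seed=0))
        assert len(res) == 15 * 6

    def test_best_multivariate_not_worse_than_univariate(self):
        rng = np.random.default_rng(2)
        table, y = self._data(rng)
        cv = CVConfig(n_repeats=5, seed=3)
        uni = evaluate_univariate(table, y, "good", cv)
        multi = multivariate_search(table, y, ["good"], cv,
                                    families=("lda",))
        assert multi[0][1].mean["accuracy"] >= uni.mean["accuracy"] - 0.1

    def test_ranking_deterministic(self):
        rng = np.random.default_rng(4)
        table, y = self._data(rng)
        cv = CVConfig(n_repeats=2, seed=1)
        r1 = multivariate_search(table, y, ["good", "weak"], cv)
        r2 = multivariate_search(table, y, ["good", "weak"], cv)
        assert [(s.family, s.features) for s, _ in r1] == \
            [(s.family, s.features) for s, _ in r2]
        assert r1[0][1].mean == r2[0][1].mean

    def test_oversized_pool_rejected(self):
        with pytest.raises(ValueError):
            multivariate_search(pd.DataFrame(np.ones((10, 13))), np.ones(10),
                                [f"f{i}" for i in range(13)])

    def test_all_families_constructible(self):
        for fam in CLASSIFIER_FAMILIES:
            clf = make_classifier(fam)
            assert hasattr(clf, "fit")
        with pytest.raises(ValueError):
            make_classifier("forest")


class TestLeakageGuard:
    def test_threshold_uses_training_rows_only(self):
        """Poisoning the held-out fold with label-revealing values changes
        neither the fitted threshold nor the standardization."""
        rng = np.random.default_rng(7)
        n = 50
        y = np.r_[np.ones(30), np.zeros(20)].astype(bool)
        X = rng.standard_normal((n, 2)) + 1.5 * y[:, None]
        splits = partition_stratified(y, 5, seed=0)
        tr, te = splits[0].train_idx, splits[0].test_idx

        clean = ThresholdedScoreClassifier(make_classifier("svm_linear"))
        clean.fit(X[tr], y[tr])
        X_poison = X.copy()
        X_poison[te] = 1e6 * y[te][:, None]
        poisoned = ThresholdedScoreClassifier(make_classifier("svm_linear"))
        poisoned.fit(X_poison[tr], y[tr])

        assert clean.threshold_model_.threshold == \
            poisoned.threshold_model_.threshold
        np.testing.assert_array_equal(clean.scaler_.mean_,
                                      poisoned.scaler_.mean_)
        uni_clean = YoudenThresholdClassifier().fit(X[tr, :1], y[tr])
        uni_poison = YoudenThresholdClassifier().fit(X_poison[tr, :1], y[tr])
        assert uni_clean.model_.threshold == uni_poison.model_.threshold
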