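"""AUROC and the within / cross-study / LODO prediction harness."""

import numpy as np
import pandas as pd
import pytest

from virome_meta import (
    ClassifierSpec,
    auroc,
    cross_study,
    lodo,
    within_study_cv,
)


def _brute_force_auroc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class _CentroidScorer:
    """Tiny deterministic classifier honoring the fit/predict_proba contract."""

    def __init__(self, seed=0):
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        y = np.asarray(y)
        self.mu1 = X[y == 1].mean(axis=0)
        self.mu0 = X[y == 0].mean(axis=0)
        return self

    def predict_proba(self, X):
        d = np.linalg.norm(X - self.mu0, axis=1) - np.linalg.norm(X - self.mu1, axis=1)
        p = 1 / (1 + np.exp(-d))
        return np.column_stack([1 - p, p])


class _LeakageProbe(_CentroidScorer):
    """Records the exact rows seen at fit time (as tuples) for leakage checks."""

    seen: list = []

    def fit(self, X, y):
        _LeakageProbe.seen.append({tuple(np.round(row, 9)) for row in X})
        return super().fit(X, y)


CENTROID = ClassifierSpec(kind="mock", factory=lambda seed: _CentroidScorer(seed))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_enumerated_pairs(self):
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(0, 1, n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                _brute_force_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])


def _features(rng, n=60, p=10, signal=0.0):
    y = np.array([0, 1]).repeat(n // 2)
    X = rng.normal(0, 1, (n, p))
    X[:, 0] += signal * y
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                        columns=[f"f{j}" for j in range(p)]), y


class TestWithinStudyCv:
    def test_null_features_near_chance(self):
        rng = np.random.default_rng(2)
        X, y = _features(rng, n=100)
        rep = within_study_cv(X, y, CENTROID, n_folds=5, n_repeats=4, seed=0)
        assert abs(rep.mean_auroc - 0.5) < 0.08
        assert len(rep.aurocs) == 20

    def test_separable_feature_high_auroc(self):
        rng = np.random.default_rng(3)
        X, y = _features(rng, n=60, signal=4.0)
        rep = within_study_cv(X, y, CENTROID, n_folds=5, n_repeats=2, seed=0)
        assert rep.mean_auroc > 0.95

    def test_same_seed_identical_report(self):
        rng = np.random.default_rng(4)
        X, y = _features(rng, signal=1.0)
        clf = ClassifierSpec(n_estimators=20)
        r1 = within_study_cv(X, y, clf, n_folds=4, n_repeats=2, seed=9)
        r2 = within_study_cv(X, y, clf, n_folds=4, n_repeats=2, seed=9)
        assert r1 == r2

    def test_no_test_sample_used_in_training(self):
        rng = np.random.default_rng(5)
        X, y = _features(rng, n=40)
        _LeakageProbe.seen = []
        spec = ClassifierSpec(kind="probe", factory=lambda seed: _LeakageProbe(seed))
        within_study_cv(X, y, spec, n_folds=4, n_repeats=2, seed=0)
        all_rows = {tuple(np.round(r, 9)) for r in X.to_numpy()}
        for train_rows in _LeakageProbe.seen:
            test_rows = all_rows - train_rows
            assert train_rows.isdisjoint(test_rows)
            assert len(test_rows) > 0

    def test_too_few_per_class_rejected(self):
        rng = np.random.default_rng(6)
        X, y = _features(rng, n=10)
        with pytest.raises(ValueError):
            within_study_cv(X, y, CENTROID, n_folds=10, n_repeats=1, seed=0)


class TestCrossStudyAndLodo:
    def test_resubstitution_not_worse_than_cv(self):
        rng = np.random.default_rng(7)
        X, y = _features(rng, n=60, signal=1.0)
        within = within_study_cv(X, y, CENTROID, n_folds=5, n_repeats=2, seed=0)
        resub = cross_study((X, y), (X, y), CENTROID, n_repeats=1, seed=0)
        assert resub.mean_auroc >= within.mean_auroc - 1e-9

    def test_shared_signal_transfers(self):
        rng = np.random.default_rng(8)
        a = _features(rng, n=80, signal=3.0)
        b = _features(rng, n=80, signal=3.0)
        rep = cross_study(a, b, CENTROID, n_repeats=1, seed=0)
        assert rep.mean_auroc > 0.85

    def test_study_specific_signal_does_not_transfer(self):
        rng = np.random.default_rng(9)
        Xa, ya = _features(rng, n=80)
        Xb, yb = _features(rng, n=80)
        Xa["f0"] += 3.0 * ya  # signal in feature 0 only in study A
        Xb["f5"] += 3.0 * yb  # and feature 5 only in study B
        rep = cross_study((Xa, ya), (Xb, yb), CENTROID, n_repeats=1, seed=0)
        assert abs(rep.mean_auroc - 0.5) < 0.15

    def test_feature_intersection_required(self):
        rng = np.random.default_rng(10)
        Xa, ya = _features(rng)
        Xb, yb = _features(rng)
        Xb.columns = [f"g{j}" for j in range(Xb.shape[1])]
        with pytest.raises(ValueError, match="intersection"):
            cross_study((Xa, ya), (Xb, yb), CENTROID, n_repeats=1, seed=0)

    def test_lodo_pools_training_sets(self):
        rng = np.random.default_rng(11)
        datasets = {f"S{i}": _features(rng, n=50, signal=2.5) for i in range(4)}
        rep = lodo(datasets, "S0", CENTROID, n_repeats=1, seed=0)
        assert rep.setting == "lodo"
        assert rep.test_id == "S0"
        assert set(rep.train_ids) == {"S1", "S2", "S3"}
        assert rep.mean_auroc > 0.9

    def test_lodo_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        datasets = {f"S{i}": _features(rng, n=60, signal=2.5) for i in range(3)}
        X0, y0 = datasets["S0"]
        datasets["S0"] = (X0, rng.permutation(y0))
        rep = lodo(datasets, "S0", CENTROID, n_repeats=1, seed=0)
        assert abs(rep.mean_auroc - 0.5) < 0.2

    def test_lodo_unknown_id_rejected(self):
        rng = np.random.default_rng(13)
        datasets = {"S0": _features(rng), "S1": _features(rng)}
        with pytest.raises(ValueError, match="held-out"):
            lodo(datasets, "nope", CENTROID, n_repeats=1, seed=0)
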