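"""Disease-status prediction harness.

AUROC, within-study repeated stratified cross-validation, pairwise
cross-study transfer, and leave-one-dataset-out (LODO) pooling.  The
classifier is a contract — anything with sklearn's fit/predict_proba
surface works; the default is a random forest with 1000 trees, the
standard choice for microbial abundance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "auroc",
    "within_study_cv",
    "cross_study",
    "lodo",
    "make_classifier",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Pluggable classifier contract.

    ``kind="random-forest"`` builds a RandomForestClassifier with
    ``n_estimators`` trees; any other behaviour is injected through
    ``factory``, a callable mapping an integer seed to an object exposing
    ``fit(X, y)`` and ``predict_proba(X)``.
    """

    kind: str = "random-forest"
    n_estimators: int = 1000
    factory: Callable[[int], object] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


def make_classifier(spec: ClassifierSpec, seed: int):
    if spec.factory is not None:
        return spec.factory(seed)
    if spec.kind == "random-forest":
        return RandomForestClassifier(n_estimators=spec.n_estimators, random_state=seed)
    raise ValueError(f"unknown classifier kind {spec.kind!r} and no factory given")


@dataclass(frozen=True)
class EvaluationReport:
    setting: str                 # "within" | "cross" | "lodo"
    train_ids: tuple[str, ...]
    test_id: str
    mean_auroc: float
    aurocs: tuple[float, ...]


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Midrank (Mann-Whitney) construction:
    AUROC = (sum of positive midranks - n_pos (n_pos + 1) / 2) / (n_pos n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("feature rows and labels must align (samples x features)")
    return X, y


def _score(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    proba = np.asarray(proba)
    if proba.ndim == 2:
        classes = getattr(clf, "classes_", None)
        col = int(np.where(np.asarray(classes) == 1)[0][0]) if classes is not None else 1
        return proba[:, col]
    return proba


def within_study_cv(features: pd.DataFrame, labels, clf: ClassifierSpec,
                    n_folds: int = 10, n_repeats: int = 20, seed: int = 0,
                    study_id: str = "") -> EvaluationReport:
    """Repeated stratified k-fold cross-validation; mean of per-fold AUROCs.

    Folds are reshuffled each repeat from a seeded RNG; the report carries
    all n_folds * n_repeats fold-level AUROCs and their mean.
    """
    X, y = _as_xy(features, labels)
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError("each class needs at least n_folds samples for stratified CV")
    rng = np.random.default_rng(seed)
    aurocs: list[float] = []
    for _ in range(n_repeats):
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        for train_idx, test_idx in skf.split(X, y):
            model = make_classifier(clf, int(rng.integers(2**31 - 1)))
            model.fit(X[train_idx], y[train_idx])
            aurocs.append(auroc(_score(model, X[test_idx]), y[test_idx]))
    return EvaluationReport(
        setting="within",
        train_ids=(study_id,),
        test_id=study_id,
        mean_auroc=float(np.mean(aurocs)),
        aurocs=tuple(aurocs),
    )


def _intersect_features(frames: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    common = frames[0].columns
    for f in frames[1:]:
        common = common.intersection(f.columns)
    if len(common) == 0:
        raise ValueError("empty feature intersection between datasets")
    common = sorted(common)
    return [f[common] for f in frames]


def cross_study(train: tuple[pd.DataFrame, Sequence], test: tuple[pd.DataFrame, Sequence],
                clf: ClassifierSpec, n_repeats: int = 20, seed: int = 0,
                train_id: str = "train", test_id: str = "test") -> EvaluationReport:
    """Train on one full study, score another; mean AUROC over classifier seeds."""
    f_train, f_test = _intersect_features([train[0], test[0]])
    X_tr, y_tr = _as_xy(f_train, train[1])
    X_te, y_te = _as_xy(f_test, test[1])
    rng = np.random.default_rng(seed)
    aurocs = []
    for _ in range(n_repeats):
        model = make_classifier(clf, int(rng.integers(2**31 - 1)))
        model.fit(X_tr, y_tr)
        aurocs.append(auroc(_score(model, X_te), y_te))
    return EvaluationReport(
        setting="cross",
        train_ids=(train_id,),
        test_id=test_id,
        mean_auroc=float(np.mean(aurocs)),
        aurocs=tuple(aurocs),
    )


def lodo(datasets: dict[str, tuple[pd.DataFrame, Sequence]], held_out: str,
         clf: ClassifierSpec, n_repeats: int = 20, seed: int = 0) -> EvaluationReport:
    """Leave-one-dataset-out: pool all other studies, test on the held-out one."""
    if held_out not in datasets:
        raise ValueError(f"held-out id {held_out!r} not among datasets")
    if len(datasets) < 2:
        raise ValueError("LODO needs at least one training dataset besides the held-out")
    ids = sorted(datasets)
    frames = _intersect_features([datasets[i][0] for i in ids])
    by_id = dict(zip(ids, frames))
    train_ids = [i for i in ids if i != held_out]
    X_tr = np.vstack([np.asarray(by_id[i], dtype=float) for i in train_ids])
    y_tr = np.concatenate([np.asarray(datasets[i][1]).astype(int) for i in train_ids])
    X_te, y_te = _as_xy(by_id[held_out], datasets[held_out][1])
    rng = np.random.default_rng(seed)
    aurocs = []
    for _ in range(n_repeats):
        model = make_classifier(clf, int(rng.integers(2**31 - 1)))
        model.fit(X_tr, y_tr)
        aurocs.append(auroc(_score(model, X_te), y_te))
    return EvaluationReport(
        setting="lodo",
        train_ids=tuple(train_ids),
        test_id=held_out,
        mean_auroc=float(np.mean(aurocs)),
        aurocs=tuple(aurocs),
    )


def combine_features(frames: Sequence[pd.DataFrame], prefixes: Sequence[str]) -> pd.DataFrame:
    """Column-concatenate feature tables (e.g. bacterial + viral) on shared samples."""
    if len(frames) != len(prefixes):
        raise ValueError("one prefix per frame")
    shared = frames[0].index
    for f in frames[1:]:
        shared = shared.intersection(f.index)
    parts = [f.loc[shared].add_prefix(p + ":") for f, p in zip(frames, prefixes)]
    return pd.concat(parts, axis=1)
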