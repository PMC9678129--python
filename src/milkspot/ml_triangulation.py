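"""Triangulation of four ML classifiers against the chemometric selection.

A feature that only one model family considers important may be an
artefact of that family's inductive bias.  To flag such model-dependent
predictors, four supervised learners — random forest, elastic-net
logistic regression, PLS-DA and a linear SVM — are each evaluated by
leave-one-out cross-validation (one cow per fold) with recursive feature
elimination, and their top-k importance rankings are compared with the
OPLS-DA + t-test discriminative set.  A conventional-workflow feature
supported only by PLS-family models (PLS top-k and/or the OPLS-based
selection itself) is flagged ``model_dependent``; features supported by
several distinct model families are consensus predictors.

All standardisation (TIC then column z-scoring) and elimination ranking
is refitted inside each training fold, so the held-out cow never leaks
into feature selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import tic_normalize

__all__ = [
    "MlSpec",
    "RfeCurve",
    "standardize",
    "loocv_accuracy",
    "rfe",
    "importance_topk",
    "triangulate",
    "MODEL_KINDS",
    "PLS_FAMILY",
]

MODEL_KINDS = ("random_forest", "elastic_net", "pls_da", "svm")
PLS_FAMILY = ("pls_da",)
_STOCHASTIC = ("random_forest",)


@dataclass(frozen=True)
class MlSpec:
    """One classifier configuration.

    ``n_repeats`` controls the number of seeded repetitions averaged for
    stochastic learners (random forest); deterministic learners run once.
    Hyperparameters default to: RF 500 trees; elastic-net logistic with
    L1 ratio 0.5 and C chosen by inner 3-fold CV; PLS 2 components with
    a 0.5 decision cut; linear SVM with C = 1.
    """

    model_kind: str
    hyperparameters: dict = field(default_factory=dict)
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


class _PlsClassifier:
    """PLS regression on a 0/1 response with a 0.5 decision cut."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        from sklearn.cross_decomposition import PLSRegression

        n_comp = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self._pls = PLSRegression(n_components=n_comp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls.fit(X, y.astype(float))
        self.coef_ = self._pls.coef_.ravel()
        return self

    def predict(self, X):
        return (self._pls.predict(X).ravel() > 0.5).astype(int)


def _make_model(spec: MlSpec, seed: int):
    hp = spec.hyperparameters
    if spec.model_kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            random_state=seed,
            n_jobs=1,
        )
    if spec.model_kind == "elastic_net":
        from sklearn.linear_model import LogisticRegressionCV, LogisticRegression

        if "C" in hp:
            return LogisticRegression(
                solver="saga",
                l1_ratio=hp.get("l1_ratio", 0.5),
                C=hp["C"],
                max_iter=5000,
                random_state=seed,
            )
        return LogisticRegressionCV(
            solver="saga",
            l1_ratios=[hp.get("l1_ratio", 0.5)],
            Cs=hp.get("Cs", [0.1, 1.0, 10.0]),
            cv=hp.get("cv", 3),
            max_iter=5000,
            scoring="neg_log_loss",
            use_legacy_attributes=False,
            random_state=seed,
        )
    if spec.model_kind == "pls_da":
        return _PlsClassifier(n_components=hp.get("n_components", 2))
    if spec.model_kind == "svm":
        from sklearn.svm import SVC

        kernel = hp.get("kernel", "linear")
        return SVC(kernel=kernel, C=hp.get("C", 1.0), random_state=seed)
    raise ValueError(spec.model_kind)


def _importance(model, spec: MlSpec) -> np.ndarray:
    """Model-specific importance: impurity importance for RF, |coefficient|
    for the linear models."""
    if spec.model_kind == "random_forest":
        return np.asarray(model.feature_importances_, dtype=float)
    if spec.model_kind == "svm" and spec.hyperparameters.get("kernel", "linear") != "linear":
        raise ValueError("weight-based ranking requires a linear SVM kernel")
    coef = np.asarray(model.coef_, dtype=float)
    return np.abs(coef).reshape(-1)


def standardize(X: np.ndarray) -> np.ndarray:
    """TIC-normalise rows, then zero-mean unit-variance columns.

    Constant columns become zeros (with a warning).  When used inside
    cross-validation, the column statistics must come from the training
    fold only — see :func:`loocv_accuracy` and :func:`rfe`, which refit
    them per fold.
    """
    X = tic_normalize(np.asarray(X, dtype=float))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # constant up to floating-point noise relative to the column level
    nz = sd > 1e-10 * (np.abs(mu) + 1e-30)
    if not nz.all():
        warnings.warn("constant column(s) scaled to zeros", stacklevel=2)
    out = np.zeros_like(X)
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def _fold_scale(X_tr: np.ndarray, X_te: np.ndarray):
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_tr - mu) / sd, (X_te - mu) / sd


def _loo_folds(n: int, groups: Sequence | None):
    """One fold per cow: yields (train_mask, test_mask) boolean arrays."""
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        test = groups == g
        yield ~test, test


def loocv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    spec: MlSpec,
    feature_subset: Sequence[int] | None = None,
    groups: Sequence | None = None,
) -> float:
    """Leave-one-cow-out accuracy of one classifier.

    ``X`` holds raw (imputed) intensities; TIC normalisation is row-wise,
    and column standardisation is refitted on each training fold.
    Stochastic learners are averaged over ``spec.n_repeats`` seeded runs.
    """
    X = tic_normalize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=int)
        if feature_subset.size == 0:
            raise ValueError("feature subset is empty")
        X = X[:, feature_subset]
    repeats = spec.n_repeats if spec.model_kind in _STOCHASTIC else 1
    accs = []
    for r in range(repeats):
        correct = total = 0
        for tr, te in _loo_folds(len(y), groups):
            if np.unique(y[tr]).size < 2:
                raise ValueError("degenerate training fold (single class)")
            Xtr, Xte = _fold_scale(X[tr], X[te])
            model = _make_model(spec, spec.seed + r).fit(Xtr, y[tr])
            correct += int((model.predict(Xte) == y[te]).sum())
            total += int(te.sum())
        accs.append(correct / total)
    return float(np.mean(accs))


@dataclass
class RfeCurve:
    """Accuracy of a model as features are recursively eliminated."""

    sizes: np.ndarray          # descending subset sizes
    accuracy: np.ndarray       # LOOCV accuracy per size
    best_size: int             # smallest size attaining max accuracy
    best_subset: np.ndarray    # feature indices (full-data elimination)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "accuracy": self.accuracy})


def _rfe_sizes(p: int) -> list[int]:
    """Halve from p while >= 20 features, then step by 1 down to 1."""
    sizes = []
    s = p
    while s >= 20:
        sizes.append(s)
        s = s // 2
    sizes.extend(range(min(s, 19, p), 0, -1))
    # strictly decreasing, ends at 1
    out = []
    for v in sizes:
        if not out or v < out[-1]:
            out.append(v)
    return out


def _eliminate_to(X, y, spec: MlSpec, current: np.ndarray, size: int, seed: int):
    """Rank features on (X restricted to current) and keep the top
    ``size``; returns the reduced index array (original indexing)."""
    model = _make_model(spec, seed).fit(X[:, current], y)
    imp = _importance(model, spec)
    order = np.argsort(-imp, kind="stable")  # ties broken by feature order
    return current[np.sort(order[:size])]


def rfe(
    X: np.ndarray,
    y: np.ndarray,
    spec: MlSpec,
    groups: Sequence | None = None,
    rank_on_full_data: bool = False,
) -> RfeCurve:
    """Recursive feature elimination with LOOCV accuracy per subset size.

    By default elimination is nested inside each training fold (ranking
    refitted per fold, the held-out cow never influencing it).  With
    ``rank_on_full_data=True`` the ranking is computed once on all data
    — a faster but selection-biased variant kept for comparison.
    Among sizes tied for maximum accuracy the smallest wins; the reported
    ``best_subset`` comes from elimination on the full data truncated at
    the best size.
    """
    X = tic_normalize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features for RFE")
    sizes = _rfe_sizes(p)
    n_sizes = len(sizes)
    correct = np.zeros(n_sizes)
    total = np.zeros(n_sizes)

    full_subsets = None
    if rank_on_full_data:
        Xs = standardize_cols(X)
        full_subsets = []
        current = np.arange(p)
        for size in sizes:
            if size < current.size:
                current = _eliminate_to(Xs, y, spec, current, size, spec.seed)
            full_subsets.append(current.copy())

    for tr, te in _loo_folds(len(y), groups):
        if np.unique(y[tr]).size < 2:
            raise ValueError("degenerate training fold (single class)")
        Xtr, Xte = _fold_scale(X[tr], X[te])
        current = np.arange(p)
        for si, size in enumerate(sizes):
            if rank_on_full_data:
                current = full_subsets[si]
            elif size < current.size:
                current = _eliminate_to(Xtr, y[tr], spec, current, size, spec.seed)
            model = _make_model(spec, spec.seed).fit(Xtr[:, current], y[tr])
            correct[si] += int((model.predict(Xte[:, current]) == y[te]).sum())
            total[si] += int(te.sum())

    accuracy = correct / total
    best_acc = accuracy.max()
    # sizes are descending; the last index attaining the max has the
    # smallest size
    best_idx = int(np.nonzero(accuracy == best_acc)[0][-1])
    best_size = int(sizes[best_idx])

    Xs = standardize_cols(X)
    current = np.arange(p)
    for size in sizes:
        if size < current.size:
            current = _eliminate_to(Xs, y, spec, current, size, spec.seed)
        if size == best_size:
            break
    return RfeCurve(
        sizes=np.asarray(sizes),
        accuracy=accuracy,
        best_size=best_size,
        best_subset=current,
    )


def standardize_cols(X: np.ndarray) -> np.ndarray:
    """Column z-scoring only (rows assumed already TIC-normalised)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def importance_topk(
    X: np.ndarray, y: np.ndarray, spec: MlSpec, k: int = 10
) -> np.ndarray:
    """Top-k feature indices by full-data model importance (rank order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    Xs = standardize(X)
    y = np.asarray(y, dtype=int).ravel()
    model = _make_model(spec, spec.seed).fit(Xs, y)
    imp = _importance(model, spec)
    order = np.argsort(-imp, kind="stable")
    return order[: min(k, Xs.shape[1])]


def triangulate(
    conventional: Sequence[int],
    topk_per_model: dict[str, Sequence[int]],
) -> pd.DataFrame:
    """Compare the conventional (OPLS-DA + t-test) selection against the
    ML models' top-k lists.

    Returns one row per conventional feature with per-model membership
    and rank, the count of supporting ML models, and ``model_dependent``
    set when the only supporters are PLS-family methods (the OPLS-based
    conventional selection itself and/or PLS-DA).
    """
    rows = []
    for feat in conventional:
        row: dict = {"feature": int(feat), "in_conventional_set": True}
        supporters = []
        for kind, topk in topk_per_model.items():
            topk = list(map(int, topk))
            member = int(feat) in topk
            row[f"{kind}_topk"] = member
            row[f"{kind}_rank"] = topk.index(int(feat)) + 1 if member else np.nan
            if member:
                supporters.append(kind)
        row["consensus_count"] = len(supporters)
        row["model_dependent"] = all(s in PLS_FAMILY for s in supporters)
        rows.append(row)
    cols = ["feature", "in_conventional_set"]
    for kind in topk_per_model:
        cols += [f"{kind}_topk", f"{kind}_rank"]
    cols += ["consensus_count", "model_dependent"]
    return pd.DataFrame(rows, columns=cols)
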