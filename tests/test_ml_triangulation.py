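"""Four-classifier LOOCV, RFE, importance rankings and triangulation."""

import numpy as np
import pytest

from milkspot.ml_triangulation import (
    MODEL_KINDS,
    MlSpec,
    _loo_folds,
    importance_topk,
    loocv_accuracy,
    rfe,
    standardize,
    triangulate,
)

FAST_HP = {
    "random_forest": {"n_estimators": 200},
    "elastic_net": {"C": 1.0},
    "pls_da": {},
    "svm": {},
}


def _spec(kind, **kw):
    return MlSpec(kind, hyperparameters=dict(FAST_HP[kind]), **kw)


def _separable_toy(seed=0, n=20, p=30):
    """One dominant separating feature; moderate shift so TIC coupling
    does not make the remaining features strong inverse predictors."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = np.abs(rng.standard_normal((n, p))) + 1.0
    X[:, 4] += y * 8.0
    return X, y


# ---------------------------------------------------------------------------
# standardisation


def test_standardize_moments_and_constant_columns():
    rng = np.random.default_rng(2)
    X = np.abs(rng.standard_normal((15, 6))) + 0.5
    Z = standardize(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(Z.var(axis=0), 1.0, atol=1e-10)

    # make column 3 a fixed fraction of each row's total so it becomes
    # constant after TIC normalisation: x3 = S/3 gives x3/(S + x3) = 1/4
    X[:, 3] = 0.0
    X[:, 3] = X.sum(axis=1) / 3.0
    with pytest.warns(UserWarning, match="constant"):
        Z = standardize(X)
    np.testing.assert_array_equal(Z[:, 3], 0.0)


def test_fold_statistics_differ_from_global():
    """Leakage guard: column statistics fitted on a training fold and
    applied to the held-out sample must differ from whole-data
    statistics."""
    from milkspot.ml_triangulation import _fold_scale

    rng = np.random.default_rng(3)
    X = rng.standard_normal((10, 4))
    global_scaled = (X - X.mean(0)) / X.std(0)
    _, test_scaled = _fold_scale(X[1:], X[:1])
    assert not np.allclose(test_scaled, global_scaled[:1])


# ---------------------------------------------------------------------------
# LOOCV accuracy


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_loocv_accuracy_perfect_on_separable_data(kind):
    X, y = _separable_toy()
    assert loocv_accuracy(X, y, _spec(kind, seed=1)) == 1.0


def test_loocv_runs_one_fold_per_cow():
    masks = list(_loo_folds(5, None))
    assert len(masks) == 5
    grouped = list(_loo_folds(6, ["a", "a", "b", "b", "c", "c"]))
    assert len(grouped) == 3
    assert grouped[0][1].sum() == 2  # both samples of cow "a" held out


def test_loocv_accuracy_near_chance_on_shuffled_labels():
    rng = np.random.default_rng(4)
    X = np.abs(rng.standard_normal((20, 10))) + 1.0
    accs = [
        loocv_accuracy(X, rng.permutation([0, 1] * 10), _spec("svm"))
        for _ in range(10)
    ]
    assert 0.3 < np.mean(accs) < 0.7


def test_loocv_accuracy_errors():
    X, y = _separable_toy()
    with pytest.raises(ValueError, match="empty"):
        loocv_accuracy(X, y, _spec("svm"), feature_subset=[])
    y_one = np.zeros(20, dtype=int)
    y_one[0] = 1  # removing the only positive leaves a single-class fold
    with pytest.raises(ValueError, match="single class"):
        loocv_accuracy(X, y_one, _spec("svm"))


# ---------------------------------------------------------------------------
# RFE


def test_rfe_curve_contract_and_single_feature_limit():
    X, y = _separable_toy()
    curve = rfe(X, y, _spec("svm"))
    assert np.all(np.diff(curve.sizes) < 0)
    assert curve.sizes[-1] == 1
    assert curve.accuracy[curve.sizes.tolist().index(curve.best_size)] == (
        curve.accuracy.max()
    )
    # the single dominant feature keeps accuracy 1.0 down to size 1
    assert curve.accuracy[-1] == 1.0
    assert curve.best_size == 1  # smallest size among ties wins
    assert 4 in curve.best_subset


def test_rfe_recovers_planted_features():
    """With three moderately informative planted features among noise,
    maximum accuracy is reached by a subset built from planted features
    and the accuracy at the best size beats the all-features accuracy."""
    rng = np.random.default_rng(6)
    n, p = 20, 60
    y = np.array([0, 1] * 10)
    X = np.abs(rng.standard_normal((n, p))) + 1.0
    planted = [7, 23, 41]
    for j in planted:
        X[:, j] *= 1.0 + y * (0.8 + 0.4 * rng.uniform(size=n))
    curve = rfe(X, y, _spec("svm"))
    assert curve.accuracy.max() >= 0.85
    assert set(curve.best_subset) <= set(planted) or (
        len(set(curve.best_subset) & set(planted)) >= 2
    )
    assert curve.accuracy[curve.sizes.tolist().index(curve.best_size)] >= (
        curve.accuracy[0]
    )


def test_rfe_rejects_nonlinear_svm():
    X, y = _separable_toy()
    spec = MlSpec("svm", hyperparameters={"kernel": "rbf"})
    with pytest.raises(ValueError, match="linear"):
        rfe(X, y, spec)


# ---------------------------------------------------------------------------
# importance


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_importance_ranks_dominant_feature_first(kind):
    X, y = _separable_toy(seed=8)
    top = importance_topk(X, y, _spec(kind, seed=2), k=3)
    assert top[0] == 4


def test_importance_topk_truncation_and_ordering():
    X, y = _separable_toy()
    top = importance_topk(X, y, _spec("svm"), k=50)
    assert top.size == X.shape[1]  # k larger than feature count
    assert len(set(top.tolist())) == top.size


def test_rf_rank_one_stable_across_seeds():
    X, y = _separable_toy(seed=10)
    spec_hp = {"n_estimators": 300}
    firsts = {
        int(importance_topk(X, y, MlSpec("random_forest", hyperparameters=spec_hp, seed=s), k=1)[0])
        for s in range(5)
    }
    assert firsts == {4}


def test_models_jointly_recover_planted_effects(day8, study_small):
    """At the default planted effect size, the intersection of all four
    models' top-10 lists contains at least half of the 10 planted
    features."""
    fm, y = day8
    planted = set(int(j) for j in study_small["planted_cols"])
    tops = []
    for kind in MODEL_KINDS:
        hp = {"n_estimators": 200} if kind == "random_forest" else {}
        spec = MlSpec(kind, hyperparameters=hp, seed=3)
        tops.append(set(importance_topk(fm.values, y, spec, k=10).tolist()))
    intersection = set.intersection(*tops)
    assert len(intersection & planted) >= 5


# ---------------------------------------------------------------------------
# triangulation


def test_triangulate_consensus_and_model_dependence():
    topk = {
        "random_forest": [1, 2, 3],
        "elastic_net": [1, 2, 9],
        "pls_da": [1, 5, 2],
        "svm": [1, 2, 8],
    }
    report = triangulate([1, 5, 6], topk)
    by_feat = report.set_index("feature")
    assert by_feat.loc[1, "consensus_count"] == 4
    assert not by_feat.loc[1, "model_dependent"]
    assert by_feat.loc[1, "pls_da_rank"] == 1
    # feature 5: only PLS supports it -> model-dependent
    assert by_feat.loc[5, "consensus_count"] == 1
    assert by_feat.loc[5, "model_dependent"]
    # feature 6: supported by nobody -> only the OPLS-based conventional
    # selection itself backs it, which is PLS-family
    assert by_feat.loc[6, "consensus_count"] == 0
    assert by_feat.loc[6, "model_dependent"]
    # invariant: model_dependent <=> supporters subset of PLS family
    for feat in report["feature"]:
        supporters = {
            k for k in topk if by_feat.loc[feat, f"{k}_topk"]
        }
        assert by_feat.loc[feat, "model_dependent"] == (supporters <= {"pls_da"})


def test_triangulate_empty_conventional_set():
    assert len(triangulate([], {"svm": [1, 2]})) == 0
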