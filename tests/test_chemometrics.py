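"""Preprocessing, PCA, OPLS-DA/VIP/S-plot, validation, t-tests, ROC."""

import numpy as np
import pytest
from scipy import stats

from milkspot.chemometrics import (
    PreprocessSpec,
    fit_opls_da,
    loocv_q2,
    pareto_scale,
    pca,
    permutation_test,
    preprocess,
    select_discriminative,
    t_test_fdr,
    tic_normalize,
    univariate_roc,
)


@pytest.fixture(scope="module")
def opls_data(day8):
    fm, y = day8
    X = preprocess(fm)
    return X, y


# ---------------------------------------------------------------------------
# preprocessing


def test_tic_normalization_row_fractions():
    out = tic_normalize(np.array([[2.0, 2.0, 4.0]]))
    np.testing.assert_allclose(out, [[0.25, 0.25, 0.5]])
    with pytest.raises(ValueError, match="cow7"):
        tic_normalize(np.zeros((1, 3)), sample_ids=["cow7"])


def test_pareto_scaling_variance_identity():
    """Pareto scaling turns a column of variance 16 into variance 4 (the
    variance becomes the original standard deviation)."""
    rng = np.random.default_rng(0)
    col = rng.standard_normal(200)
    col = (col - col.mean()) / col.std(ddof=1) * 4.0  # sd exactly 4
    out = pareto_scale(col[:, None])
    assert out[:, 0].var(ddof=1) == pytest.approx(4.0)
    # constant column -> zeros
    np.testing.assert_array_equal(pareto_scale(np.full((5, 1), 3.0)), 0.0)


def test_tic_makes_statistics_scale_invariant(day8):
    """Multiplying one sample's raw intensities by a positive scalar must
    leave every post-TIC statistic unchanged."""
    fm, y = day8
    X1 = preprocess(fm)
    scaled = fm.values.copy()
    scaled[3] *= 7.3
    X2 = preprocess(scaled)
    np.testing.assert_allclose(X1, X2, atol=1e-10)


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_and_component_count(study_small):
    rank1 = np.outer(np.arange(1.0, 9), np.arange(1.0, 6))
    _, _, evr = pca(rank1, 3)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)

    X = preprocess(study_small["fm"])
    scores, loadings, evr6 = pca(X, 6)
    assert scores.shape == (48, 6)
    np.testing.assert_allclose(loadings.T @ loadings, np.eye(6), atol=1e-8)
    assert np.all(np.diff(evr6) <= 1e-12)


def test_pca_separates_extraction_days(study_small):
    """Day-16 attenuation dominates the first principal component, so the
    two extraction days separate along PC1."""
    fm, metadata = study_small["fm"], study_small["metadata"]
    X = preprocess(fm)
    scores, _, _ = pca(X, 2)
    day = metadata.set_index("sample_id").loc[fm.sample_ids, "day"].to_numpy()
    pc1_d8, pc1_d16 = scores[day == 8, 0], scores[day == 16, 0]
    lo, hi = sorted([pc1_d8.mean(), pc1_d16.mean()])
    assert max(pc1_d8.min(), pc1_d16.min()) > lo  # clouds do not interleave...
    gap = abs(pc1_d8.mean() - pc1_d16.mean())
    assert gap > 2 * max(pc1_d8.std(), pc1_d16.std())


# ---------------------------------------------------------------------------
# OPLS-DA


def test_opls_limiting_case_single_informative_column():
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 8)
    X = rng.standard_normal((16, 5)) * 0.01
    X[:, 2] = y * 2.0 + 0.001 * rng.standard_normal(16)
    model = fit_opls_da(X - X.mean(0), y, n_orthogonal=0)
    assert np.argmax(np.abs(model.w)) == 2
    assert model.R2Y > 0.99


def test_opls_equals_two_component_pls_predictions(opls_data):
    """With one predictive + one orthogonal component and a single
    response, OPLS-DA spans the same subspace as 2-component PLS: the
    fitted predictions must agree to 1e-8."""
    from sklearn.cross_decomposition import PLSRegression

    X, y = opls_data
    model = fit_opls_da(X, y, n_orthogonal=1)
    pls = PLSRegression(n_components=2, scale=False).fit(X, y.astype(float))
    np.testing.assert_allclose(
        model.predict_value(X), pls.predict(X).ravel(), atol=1e-8
    )


def test_opls_separates_classes_along_predictive_score(opls_data):
    X, y = opls_data
    model = fit_opls_da(X, y, n_orthogonal=1)
    assert model.t[y == 1].mean() * model.q > model.t[y == 0].mean() * model.q
    pred = model.predict_class(X)
    assert (pred == y).mean() >= 0.9


def test_vip_mean_square_is_one(opls_data):
    X, y = opls_data
    for n_orth in (0, 1, 2):
        model = fit_opls_da(X, y, n_orthogonal=n_orth)
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-6)
    model = fit_opls_da(X, y, 1, vip_include_orthogonal=True)
    assert np.all(model.vip >= 0)


def test_splot_sign_matches_class_difference(opls_data, study_small):
    X, y = opls_data
    model = fit_opls_da(X, y, n_orthogonal=1)
    assert np.all(np.abs(model.splot_corr) <= 1.0)
    sign_flip = np.sign(model.q)
    for j, effect in zip(study_small["planted_cols"], study_small["effects"]):
        diff = X[y == 1, j].mean() - X[y == 0, j].mean()
        assert np.sign(model.splot_cov[j] * sign_flip) == np.sign(diff)


def test_opls_scores_orthogonal_and_r2_monotone(opls_data):
    X, y = opls_data
    prev_r2x = prev_r2y = -np.inf
    for n_orth in (0, 1, 2):
        model = fit_opls_da(X, y, n_orthogonal=n_orth)
        for a in range(n_orth):
            cos = model.t @ model.t_o[:, a] / (
                np.linalg.norm(model.t) * np.linalg.norm(model.t_o[:, a])
            )
            assert abs(cos) < 1e-8
        assert model.R2X >= prev_r2x - 1e-12
        assert model.R2Y >= prev_r2y - 1e-12
        prev_r2x, prev_r2y = model.R2X, model.R2Y


def test_opls_errors():
    X = np.random.default_rng(0).standard_normal((8, 4))
    with pytest.raises(ValueError, match="class"):
        fit_opls_da(X, np.zeros(8))
    with pytest.raises(ValueError, match="0/1"):
        fit_opls_da(X, np.array([1, 2] * 4))
    y = np.array([0, 1] * 4)
    with pytest.raises(ValueError, match="rank|orthogonal"):
        fit_opls_da(X, y, n_orthogonal=10)


# ---------------------------------------------------------------------------
# cross-validation and permutation


def test_q2_high_for_separable_low_for_permuted(day8):
    fm, y = day8
    Xu = preprocess(fm, PreprocessSpec(pareto_scale=False))
    q2 = loocv_q2(Xu, y, 1, scale="pareto")
    assert q2 > 0.5
    rng = np.random.default_rng(7)
    q2_null = [
        loocv_q2(Xu, rng.permutation(y), 1, scale="pareto") for _ in range(5)
    ]
    assert np.median(q2_null) <= 0.1
    assert max(q2_null) < q2


def test_permutation_test_p_values(day8):
    fm, y = day8
    Xu = preprocess(fm, PreprocessSpec(pareto_scale=False))
    result = permutation_test(Xu, y, 1, n_perm=19, seed=3, scale="pareto")
    assert result.p_q2 == pytest.approx(1 / 20)  # no null reaches observed
    assert result.p_r2y >= 1 / 20
    assert result.null_q2.size == 19


# ---------------------------------------------------------------------------
# univariate


def test_t_test_matches_pooled_variance_formula():
    """{1,2,3} vs {7,8,9}: pooled sd = 1, se = sqrt(2/3), t = 6/se = 7.348
    with 4 df (sign follows class-1 minus class-0 means)."""
    X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    res = t_test_fdr(X, y)
    assert res.t_stat[0] == pytest.approx(7.348469, abs=1e-5)
    expected_p = 2 * stats.t.sf(7.348469, df=4)
    assert res.p_value[0] == pytest.approx(expected_p, rel=1e-4)


def test_t_test_degenerate_and_welch():
    X = np.column_stack([np.ones(6), [1, 2, 3, 1, 2, 3]])
    y = np.array([0, 0, 0, 1, 1, 1])
    res = t_test_fdr(X, y)
    assert res.p_value[0] == 1.0 and res.t_stat[0] == 0.0
    assert res.p_value[1] == pytest.approx(1.0)
    welch = t_test_fdr(X, y, equal_var=False)
    assert welch.p_value[1] == pytest.approx(1.0)


def _bh_oracle(p):
    """Independent BH step-up implementation."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_qvalues_match_step_up_oracle():
    p = np.array([0.01, 0.02, 0.03, 0.5])
    np.testing.assert_allclose(_bh_oracle(p), [0.04, 0.04, 0.04, 0.5])
    rng = np.random.default_rng(11)
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)


def test_select_discriminative_rule(opls_data):
    X, y = opls_data
    model = fit_opls_da(X, y, 1)
    uni = t_test_fdr(X, y)
    selected = select_discriminative(model, uni)
    for j in selected:
        assert model.vip[j] > 1 and uni.p_value[j] < 0.05 and uni.q_value[j] < 0.05
    # manual rule application on crafted values
    model.vip[:] = 0.9
    assert select_discriminative(model, uni).size == 0


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    r = univariate_roc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
    assert r.auc == pytest.approx(1.0)
    assert r.optimal_sensitivity == 1.0 and r.optimal_specificity == 1.0


def test_roc_auc_equals_concordant_pair_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(6, 20))
        x = rng.choice(np.arange(6).astype(float), size=n)  # with ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        r = univariate_roc(x, y)
        pos, neg = x[y == 1], x[y == 0]
        conc = sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
        )
        assert r.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


def test_roc_random_labels_centre_on_half():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(30)
    aucs = []
    for _ in range(40):
        y = rng.permutation([0, 1] * 15)
        aucs.append(univariate_roc(x, y).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)


def test_roc_constant_feature_warns():
    with pytest.warns(UserWarning, match="constant"):
        r = univariate_roc(np.ones(6), np.array([0, 1] * 3))
    assert r.auc == 0.5
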