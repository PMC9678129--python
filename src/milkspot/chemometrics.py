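"""Chemometric modelling: preprocessing, PCA, OPLS-DA, VIP/S-plot,
validation and univariate testing.

The modelling path mirrors standard DIMS metabolomics practice:

* intensities are normalised to total ion count (TIC), log-transformed and
  Pareto scaled (mean-centre, divide by the square root of the column
  standard deviation);
* unsupervised structure is inspected by PCA;
* class discrimination uses OPLS-DA with one predictive and (by default)
  one orthogonal component, fitted by the Trygg-Wold orthogonal-filtering
  NIPALS sequence for a single binary response coded 0/1;
* per-feature influence is summarised by VIP (scaled so the mean squared
  VIP is 1) and by the S-plot (covariance and correlation of each column
  with the predictive score);
* predictive power is assessed by leave-one-out Q2 and a label-permutation
  test; univariate screening uses Student's t-tests with Benjamini-
  Hochberg FDR; discriminative ions require VIP > 1, p < 0.05 and
  q < 0.05; single-ion diagnostic value is read off a ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_extraction import FeatureMatrix

__all__ = [
    "PreprocessSpec",
    "OplsModel",
    "UnivariateResult",
    "RocResult",
    "PermutationResult",
    "preprocess",
    "tic_normalize",
    "pareto_scale",
    "pca",
    "fit_opls_da",
    "loocv_q2",
    "permutation_test",
    "t_test_fdr",
    "select_discriminative",
    "univariate_roc",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing switches.

    ``counts_scale`` rescales TIC-normalised fractions (rows summing to 1)
    back onto a counts-like scale before the log, so that the ``offset``
    added for zeros is small relative to real signals; because it is a
    fixed constant it preserves invariance of all post-TIC statistics to
    per-sample rescaling.
    """

    tic_normalize: bool = True
    log_transform: bool = True
    pareto_scale: bool = True
    offset: float = 1.0
    counts_scale: float = 1e6

    def __post_init__(self) -> None:
        if self.log_transform and self.offset <= 0:
            raise ValueError("offset must be positive with log_transform")


def tic_normalize(X: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Divide each row by its total ion count (rows then sum to 1)."""
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        i = int(np.nonzero(totals == 0)[0][0])
        name = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise ValueError(f"zero total ion count for sample {name}")
    return X / totals[:, None]


def pareto_scale(X: np.ndarray) -> np.ndarray:
    """Mean-centre each column and divide by sqrt(column std); constant
    columns become all zeros."""
    X = np.asarray(X, dtype=float)
    centred = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.sqrt(sd)
    out = np.zeros_like(centred)
    nz = scale > 0
    out[:, nz] = centred[:, nz] / scale[nz]
    return out


def preprocess(
    fm: FeatureMatrix | np.ndarray,
    spec: PreprocessSpec = PreprocessSpec(),
) -> np.ndarray:
    """Apply TIC normalisation, log transform and Pareto scaling."""
    if isinstance(fm, FeatureMatrix):
        if fm.missing_mask.any():
            raise ValueError("impute before preprocessing")
        X, ids = fm.values, fm.sample_ids
    else:
        X, ids = np.asarray(fm, dtype=float), None
    if spec.tic_normalize:
        X = tic_normalize(X, ids) * (spec.counts_scale if spec.log_transform else 1.0)
    if spec.log_transform:
        X = np.log(X + spec.offset)
    if spec.pareto_scale:
        X = pareto_scale(X)
    return X


def pca(X: np.ndarray, n_components: int = 6):
    """PCA via SVD: returns (scores, loadings, explained variance
    fractions); loadings are orthonormal columns."""
    from sklearn.decomposition import PCA as _PCA

    X = np.asarray(X, dtype=float)
    n_components = int(min(n_components, X.shape[0] - 1, X.shape[1]))
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_.T, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (single binary response coded 0/1)."""

    n_predictive: int
    n_orthogonal: int
    w: np.ndarray           # predictive weights, unit norm
    t: np.ndarray           # predictive scores
    p: np.ndarray           # predictive loadings
    q: float                # y-loading of the predictive component
    w_o: np.ndarray         # orthogonal weights, columns
    t_o: np.ndarray         # orthogonal scores, columns
    p_o: np.ndarray         # orthogonal loadings, columns
    x_mean: np.ndarray
    y_mean: float
    R2X: float
    R2Y: float
    vip: np.ndarray
    splot_cov: np.ndarray
    splot_corr: np.ndarray

    def transform(self, X: np.ndarray):
        """Orthogonal-filter new rows; returns (t_pred, T_orth)."""
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        T_o = np.zeros((X.shape[0], self.n_orthogonal))
        for a in range(self.n_orthogonal):
            t_o = X @ self.w_o[:, a]
            X = X - np.outer(t_o, self.p_o[:, a])
            T_o[:, a] = t_o
        return X @ self.w, T_o

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X)
        return self.y_mean + self.q * t

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """0/1 class by a 0.5 cut; ties go to the control class (0)."""
        return (self.predict_value(X) > 0.5).astype(int)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return y


def fit_opls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    vip_include_orthogonal: bool = False,
) -> OplsModel:
    """Fit OPLS-DA by the orthogonal-filtering NIPALS sequence.

    The y-predictive weight vector ``w`` is fixed from the response; each
    orthogonal component captures X-variation orthogonal to ``w`` and is
    deflated from X; the single predictive component is then fitted on the
    filtered matrix.  VIP is computed from the predictive component only
    by default (mean squared VIP = 1); ``vip_include_orthogonal`` adds the
    orthogonal components weighted by their explained X-variance.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    y0 = y - y_mean
    ss_x = float((X0 ** 2).sum())
    ss_y = float((y0 ** 2).sum())
    if ss_x == 0:
        raise ValueError("X has no variance")

    w = X0.T @ y0
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("y is uncorrelated with every column of X")
    w = w / norm

    Xf = X0.copy()
    p_feat = X.shape[1]
    W_o = np.zeros((p_feat, n_orthogonal))
    T_o = np.zeros((X.shape[0], n_orthogonal))
    P_o = np.zeros((p_feat, n_orthogonal))
    for a in range(n_orthogonal):
        t = Xf @ w
        tt = float(t @ t)
        if tt <= 1e-12 * ss_x:
            raise ValueError(
                f"rank exhausted: cannot extract orthogonal component {a + 1}"
            )
        p_load = Xf.T @ t / tt
        w_o = p_load - float(w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo <= 1e-12:
            raise ValueError(
                f"no orthogonal variation left for component {a + 1}"
            )
        w_o = w_o / n_wo
        t_o = Xf @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o <= 1e-12 * ss_x:
            raise ValueError(
                f"rank exhausted: cannot extract orthogonal component {a + 1}"
            )
        p_o = Xf.T @ t_o / tt_o
        Xf = Xf - np.outer(t_o, p_o)
        W_o[:, a], T_o[:, a], P_o[:, a] = w_o, t_o, p_o

    t = Xf @ w
    tt = float(t @ t)
    if tt <= 0:
        raise ValueError("predictive component has zero variance")
    p_load = Xf.T @ t / tt
    q = float(y0 @ t / tt)

    # explained variation
    X_hat = np.outer(t, p_load) + T_o @ P_o.T
    R2X = float((X_hat ** 2).sum() / ss_x)
    resid_y = y0 - q * t
    R2Y = float(1.0 - (resid_y ** 2).sum() / ss_y)

    # VIP — predictive component(s) only by default
    ssy_pred = q * q * tt
    if vip_include_orthogonal and n_orthogonal > 0:
        ssx_o = np.array([(T_o[:, a] ** 2).sum() * (P_o[:, a] ** 2).sum()
                          for a in range(n_orthogonal)])
        comp_weight = np.concatenate([[ssy_pred], ssx_o])
        comp_w = np.column_stack(
            [w] + [W_o[:, a] for a in range(n_orthogonal)]
        )
        num = (comp_w ** 2) @ comp_weight
        vip = np.sqrt(p_feat * num / comp_weight.sum())
    else:
        vip = np.sqrt(p_feat) * np.abs(w)

    # S-plot against the predictive score
    n = X.shape[0]
    centred = X0
    cov = centred.T @ t / (n - 1)
    col_sd = centred.std(axis=0, ddof=1)
    t_sd = t.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(
            (col_sd > 0) & (t_sd > 0), cov / (col_sd * t_sd), 0.0
        )
    corr = np.clip(corr, -1.0, 1.0)

    return OplsModel(
        n_predictive=1,
        n_orthogonal=n_orthogonal,
        w=w,
        t=t,
        p=p_load,
        q=q,
        w_o=W_o,
        t_o=T_o,
        p_o=P_o,
        x_mean=x_mean,
        y_mean=y_mean,
        R2X=R2X,
        R2Y=R2Y,
        vip=vip,
        splot_cov=cov,
        splot_corr=corr,
    )


def loocv_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    scale: str = "none",
) -> float:
    """Leave-one-out Q2 = 1 - PRESS / SS.

    Each sample is predicted by a model fitted without it; preprocessing
    statistics (column means and, with ``scale='pareto'`` or ``'uv'``,
    column scales) are refitted inside each fold.  SS is the PRESS of the
    fold-wise training-mean predictor, so a constant predictor scores
    exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    n = y.size
    press = 0.0
    ss = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if np.unique(y_tr).size < 2:
            raise ValueError("training fold lost a class")
        mu = X_tr.mean(axis=0)
        if scale == "pareto":
            s = np.sqrt(X_tr.std(axis=0, ddof=1))
        elif scale == "uv":
            s = X_tr.std(axis=0, ddof=1)
        elif scale == "none":
            s = np.ones(X.shape[1])
        else:
            raise ValueError(f"unknown scale {scale!r}")
        s = np.where(s > 0, s, 1.0)
        model = fit_opls_da((X_tr - mu) / s, y_tr, n_orthogonal)
        pred = float(model.predict_value((X[i] - mu) / s)[0])
        press += (y[i] - pred) ** 2
        ss += (y[i] - y_tr.mean()) ** 2
    return float(1.0 - press / ss)


@dataclass(frozen=True)
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    null_r2y: np.ndarray
    null_q2: np.ndarray
    p_r2y: float
    p_q2: float


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    n_perm: int = 100,
    seed: int = 0,
    scale: str = "none",
) -> PermutationResult:
    """Label-permutation null for R2Y and Q2.

    Empirical p = (1 + #{null >= observed}) / (n_perm + 1), which never
    returns exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    obs_model = fit_opls_da(X, y, n_orthogonal)
    obs_q2 = loocv_q2(X, y, n_orthogonal, scale=scale)
    rng = np.random.default_rng(seed)
    null_r2y = np.empty(n_perm)
    null_q2 = np.empty(n_perm)
    for b in range(n_perm):
        while True:
            y_perm = rng.permutation(y)
            if np.unique(y_perm).size == 2:
                break
        null_r2y[b] = fit_opls_da(X, y_perm, n_orthogonal).R2Y
        null_q2[b] = loocv_q2(X, y_perm, n_orthogonal, scale=scale)
    p_r2y = (1 + np.sum(null_r2y >= obs_model.R2Y)) / (n_perm + 1)
    p_q2 = (1 + np.sum(null_q2 >= obs_q2)) / (n_perm + 1)
    return PermutationResult(
        observed_r2y=obs_model.R2Y,
        observed_q2=obs_q2,
        null_r2y=null_r2y,
        null_q2=null_q2,
        p_r2y=float(p_r2y),
        p_q2=float(p_q2),
    )


# ---------------------------------------------------------------------------
# Univariate testing


@dataclass(frozen=True)
class UnivariateResult:
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t_stat, "p": self.p_value, "q": self.q_value}
        )


def t_test_fdr(X: np.ndarray, y: np.ndarray, equal_var: bool = True) -> UnivariateResult:
    """Per-feature two-sample t-test (Student's pooled-variance by default,
    Welch with ``equal_var=False``) with Benjamini-Hochberg q-values.

    Degenerate features (zero variance in both groups, equal means) get
    t = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    g1, g0 = X[y == 1], X[y == 0]
    if min(len(g1), len(g0)) < 2:
        raise ValueError("need at least two samples per class")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(g1, g0, axis=0, equal_var=equal_var)
    t_stat = np.nan_to_num(np.asarray(t_stat, dtype=float), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p, dtype=float))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return UnivariateResult(t_stat=t_stat, p_value=p, q_value=q)


def select_discriminative(
    model: OplsModel,
    uni: UnivariateResult,
    vip_cut: float = 1.0,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> np.ndarray:
    """Indices of features with VIP > vip_cut AND p < p_cut AND q < q_cut."""
    if model.vip.size != uni.p_value.size:
        raise ValueError("model and univariate results disagree on features")
    keep = (
        (model.vip > vip_cut)
        & (uni.p_value < p_cut)
        & (uni.q_value < q_cut)
    )
    return np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_sensitivity: float
    optimal_specificity: float


def univariate_roc(x: np.ndarray, y: np.ndarray) -> RocResult:
    """ROC for a single feature, higher values taken to indicate class 1.

    Thresholds sweep the midpoints between consecutive distinct values
    (plus open ends); a sample is called positive when x >= threshold.
    AUC is the trapezoidal area, identical to the Mann-Whitney concordance
    probability with half-credit for ties.  The reported operating point
    maximises the Youden index (sensitivity + specificity - 1).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = _check_binary(y)
    uniq = np.unique(x)
    if uniq.size == 1:
        warnings.warn("constant feature: AUC is 0.5", stacklevel=2)
        return RocResult(
            thresholds=np.array([uniq[0]]),
            sensitivity=np.array([1.0]),
            specificity=np.array([0.0]),
            auc=0.5,
            optimal_threshold=float(uniq[0]),
            optimal_sensitivity=1.0,
            optimal_specificity=0.0,
        )
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n_pos = float((y == 1).sum())
    n_neg = float((y == 0).sum())
    sens = np.array([((x >= thr) & (y == 1)).sum() / n_pos for thr in thresholds])
    spec = np.array([((x < thr) & (y == 0)).sum() / n_neg for thr in thresholds])
    # thresholds ascend, so fpr and tpr descend together; reverse both to
    # integrate along the ROC curve from (0,0) to (1,1)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[best]),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
    )
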