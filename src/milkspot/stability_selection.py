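"""Bootstrap stability selection over penalised regression models.

Variable selection from n=21 cows and hundreds of features is unstable:
a single penalised fit can select different features on a slightly
different sample.  Stability selection quantifies this directly:

* fit a penalised model (elastic net, Lasso or MCP) on many stratified
  bootstrap resamples of the cows; a feature is "selected" in a resample
  iff its coefficient is non-zero;
* the stability score of a feature is the percentage of resamples in
  which it was selected (default 500 bootstraps);
* a null threshold is obtained by permuting the outcome (default 20
  permutations), repeating the bootstrap procedure on each permuted
  dataset (default 50 bootstraps each), and taking the highest stability
  score any feature reaches under any permutation;
* a sign-based bootstrap p-value per feature is the proportion of its
  non-zero coefficient estimates lying on the minority side of zero
  (e.g. 95 of 100 selections positive -> p = 5/100 = 0.05);
* stable features have a score strictly above the threshold and a low
  bootstrap p-value.

The penalised fits use an in-repo coordinate-descent solver (numba
compiled) covering all three penalties for both logistic (default, the
outcome is a class) and linear responses.  Per-bootstrap penalty strength
is chosen by inner cross-validation (deviance-minimising by default, 1-SE
optional) with folds grouped by original observation so that bootstrap
duplicates never straddle train and validation; a fixed-lambda mode is
available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PenalisedSpec",
    "StabilityResult",
    "fit_penalised",
    "stability_scores",
    "permutation_threshold",
    "bootstrap_p",
    "select_stable",
    "run_stability",
]

_PENALTIES = ("elastic_net", "lasso", "mcp")
_FAMILIES = ("logistic", "linear")


@dataclass(frozen=True)
class PenalisedSpec:
    """Configuration of one penalised model.

    ``alpha`` is the elastic-net L1 mixing proportion (1 = pure Lasso
    component); ``mcp_gamma`` the MCP concavity (> 1, larger = closer to
    Lasso).  ``lambda_`` fixes the penalty strength; when None it is
    chosen per fit by ``cv_folds``-fold cross-validation over a geometric
    path of ``n_lambda`` values down to ``lambda_min_ratio`` of the
    smallest fully-sparsifying lambda, with the 1-SE rule.
    """

    penalty: str = "elastic_net"
    alpha: float = 0.5
    mcp_gamma: float = 3.0
    family: str = "logistic"
    lambda_: float | None = None
    n_lambda: int = 8
    lambda_min_ratio: float = 0.05
    cv_folds: int = 7
    one_se: bool = False
    max_iter: int = 500
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.penalty not in _PENALTIES:
            raise ValueError(f"penalty must be one of {_PENALTIES}")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.mcp_gamma <= 1:
            raise ValueError("mcp_gamma must be > 1")

    @property
    def l1_fraction(self) -> float:
        """Fraction of lambda acting as L1 at the origin (for lambda_max)."""
        return self.alpha if self.penalty == "elastic_net" else 1.0


@njit(cache=True)
def _cd_solve(X, y, family, penalty, lam, alpha, gamma, max_outer, max_inner, tol):
    """Coordinate descent for penalised regression.

    family: 0 logistic, 1 linear.  penalty: 0 elastic net, 1 lasso, 2 MCP.
    Returns (intercept, beta, converged flag, last max coefficient change).
    Logistic uses IRLS with clipped weights; MCP uses the curvature-aware
    threshold operator (hard-threshold branch when gamma*v <= 1).
    """
    n, p = X.shape
    beta = np.zeros(p)
    b0 = 0.0
    if family == 1:
        w = np.ones(n)
        z = y.copy()
    else:
        w = np.full(n, 0.25)
        z = np.zeros(n)
    # precomputed weighted column curvatures, refreshed with the weights
    v = np.zeros(p)
    eta = np.zeros(n)
    converged = False
    last_delta = 0.0
    prev_obj = 1e300
    stable_pattern = 0
    sign_prev = np.zeros(p)
    n_outer = max_outer if family == 0 else 1
    beta_prev = np.zeros(p)
    b0_prev = 0.0
    for outer in range(n_outer):
        for j in range(p):
            beta_prev[j] = beta[j]
        b0_prev = b0
        # working response
        for i in range(n):
            s = b0
            for j in range(p):
                if beta[j] != 0.0:
                    s += X[i, j] * beta[j]
            eta[i] = s
        if family == 0:
            # For the nonconvex MCP the quadratic approximation uses the
            # constant curvature bound 1/4 (an MM majorizer of the logistic
            # loss), which keeps the outer iteration monotone; the convex
            # penalties use true IRLS weights (faster, same fixed point).
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    mu = 1.0
                elif e < -30.0:
                    mu = 0.0
                else:
                    mu = 1.0 / (1.0 + math.exp(-e))
                if penalty == 2:
                    wi = 0.25
                else:
                    wi = mu * (1.0 - mu)
                    if wi < 1e-4:
                        wi = 1e-4
                w[i] = wi
                z[i] = e + (y[i] - mu) / wi
        sum_w = 0.0
        for i in range(n):
            sum_w += w[i]
        for j in range(p):
            acc = 0.0
            for i in range(n):
                acc += w[i] * X[i, j] * X[i, j]
            v[j] = acc / n
        # residual r = z - eta
        r = np.empty(n)
        for i in range(n):
            r[i] = z[i] - eta[i]
        outer_delta = 0.0
        for inner in range(max_inner):
            delta = 0.0
            # intercept
            num0 = 0.0
            for i in range(n):
                num0 += w[i] * r[i]
            d0 = num0 / sum_w
            if d0 != 0.0:
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > delta:
                    delta = abs(d0)
            for j in range(p):
                vj = v[j]
                if vj <= 0.0:
                    continue
                num = 0.0
                for i in range(n):
                    num += w[i] * X[i, j] * r[i]
                num = num / n + vj * beta[j]
                if penalty == 2:
                    # MCP threshold operator with curvature vj
                    zj = num / vj
                    az = abs(zj)
                    if gamma * vj > 1.0 + 1e-9:
                        if az >= gamma * lam:
                            new = zj
                        else:
                            s = az - lam / vj
                            if s < 0.0:
                                s = 0.0
                            new = (1.0 if zj > 0 else -1.0) * s / (1.0 - 1.0 / (gamma * vj))
                    else:
                        # nonconvex coordinate: hard threshold
                        if az > lam * math.sqrt(gamma / vj):
                            new = zj
                        else:
                            new = 0.0
                else:
                    l1 = lam * alpha if penalty == 0 else lam
                    l2 = lam * (1.0 - alpha) if penalty == 0 else 0.0
                    a = abs(num) - l1
                    if a < 0.0:
                        new = 0.0
                    else:
                        new = (1.0 if num > 0 else -1.0) * a / (vj + l2)
                d = new - beta[j]
                if d != 0.0:
                    beta[j] = new
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    if abs(d) > delta:
                        delta = abs(d)
            if delta < tol:
                break
        # outer progress = total coefficient movement this IRLS step
        outer_delta = abs(b0 - b0_prev)
        for j in range(p):
            d = abs(beta[j] - beta_prev[j])
            if d > outer_delta:
                outer_delta = d
        last_delta = outer_delta
        if family == 1:
            converged = delta < tol
            break
        if outer_delta < tol:
            converged = True
            break
        # objective-based stop: the penalised deviance is monotone under
        # the majorized update, so a stalled objective means the iterate
        # is cycling on a flat (nonconvex) ridge — accept it.  A saturated
        # loss (perfect separation, where the MCP flat region lets the
        # coefficients drift without bound) also stops the iteration: the
        # active set no longer changes.
        obj = 0.0
        for i in range(n):
            e = b0
            for j in range(p):
                if beta[j] != 0.0:
                    e += X[i, j] * beta[j]
            if e > 30.0:
                obj += e - y[i] * e
            elif e < -30.0:
                obj += -y[i] * e
            else:
                obj += math.log(1.0 + math.exp(e)) - y[i] * e
        obj /= n
        if obj < 1e-8:
            converged = True
            break
        for j in range(p):
            ab = abs(beta[j])
            if ab == 0.0:
                continue
            if penalty == 2:
                if ab <= gamma * lam:
                    obj += lam * ab - ab * ab / (2.0 * gamma)
                else:
                    obj += gamma * lam * lam / 2.0
            elif penalty == 0:
                obj += lam * (alpha * ab + (1.0 - alpha) * ab * ab / 2.0)
            else:
                obj += lam * ab
        if outer > 0 and abs(prev_obj - obj) <= 1e-9 * (abs(obj) + 1.0):
            converged = True
            break
        prev_obj = obj
        # under separation the MCP flat region lets magnitudes drift
        # without bound while the selection pattern is frozen; a pattern
        # unchanged for many small-step iterations counts as converged
        same = True
        for j in range(p):
            s = 0.0
            if beta[j] > 1e-8:
                s = 1.0
            elif beta[j] < -1e-8:
                s = -1.0
            if s != sign_prev[j]:
                same = False
            sign_prev[j] = s
        max_b = 0.0
        for j in range(p):
            if abs(beta[j]) > max_b:
                max_b = abs(beta[j])
        if same and outer_delta < 1e-2 * (1.0 + max_b):
            stable_pattern += 1
            if stable_pattern >= 25:
                converged = True
                break
        else:
            stable_pattern = 0
    return b0, beta, converged, last_delta


def _lambda_max(X: np.ndarray, y: np.ndarray, spec: PenalisedSpec) -> float:
    if spec.family == "logistic":
        resid = y - y.mean()
    else:
        resid = y - y.mean()
    grad = np.abs(X.T @ resid) / X.shape[0]
    lam = float(grad.max()) / spec.l1_fraction
    if spec.family == "logistic":
        lam *= 4.0  # weights bounded by 1/4 in the quadratic approximation
    return max(lam, 1e-6)


def fit_penalised(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenalisedSpec = PenalisedSpec(),
    lambda_: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fit one penalised model and return its coefficient vector.

    ``X`` should be standardised; ``y`` is 0/1 for the logistic family.
    With neither ``lambda_`` nor ``spec.lambda_`` given, the penalty
    strength is chosen by inner cross-validation (see
    :class:`PenalisedSpec`).  Raises on non-convergence.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    lam = lambda_ if lambda_ is not None else spec.lambda_
    if lam is None:
        lam = _cv_lambda(X, y, spec, rng or np.random.default_rng(0))
    return _fit_at(X, y, spec, lam)


def _fit_at(X, y, spec: PenalisedSpec, lam: float) -> np.ndarray:
    fam = 0 if spec.family == "logistic" else 1
    pen = _PENALTIES.index(spec.penalty)
    b0, beta, ok, delta = _cd_solve(
        X, y, fam, pen, lam, spec.alpha, spec.mcp_gamma,
        spec.max_iter, 1000, spec.tol,
    )
    if not ok:
        raise RuntimeError(
            f"coordinate descent did not converge: penalty={spec.penalty} "
            f"family={spec.family} lambda={lam:.4g} last_delta={delta:.3g} "
            f"after {spec.max_iter} outer iterations"
        )
    return beta


def _deviance(X, y, b0, beta, family: str) -> float:
    eta = b0 + X @ beta
    if family == "logistic":
        eta = np.clip(eta, -30, 30)
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta)) * 2
    return float(np.sum((y - eta) ** 2))


def _cv_lambda(
    X,
    y,
    spec: PenalisedSpec,
    rng: np.random.Generator,
    groups: np.ndarray | None = None,
) -> float:
    """Cross-validated penalty strength.

    ``groups`` identifies rows that are resampled copies of the same
    original observation (as in a bootstrap): all copies are assigned to
    the same fold, otherwise duplicates leak across folds and CV
    systematically overfits on resampled data.
    """
    n = X.shape[0]
    lam_max = _lambda_max(X, y, spec)
    path = np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)
    # stratified fold assignment over unique groups
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    group_fold: dict = {}
    group_class = {g: y[np.nonzero(groups == g)[0][0]] for g in np.unique(groups)}
    for cls in np.unique(y):
        gs = rng.permutation([g for g, c in group_class.items() if c == cls])
        for i, g in enumerate(gs):
            group_fold[g] = i % spec.cv_folds
    folds = np.array([group_fold[g] for g in groups])
    fam = 0 if spec.family == "logistic" else 1
    pen = _PENALTIES.index(spec.penalty)
    losses = np.full((spec.cv_folds, path.size), np.nan)
    for f in range(spec.cv_folds):
        tr, va = folds != f, folds == f
        if np.unique(y[tr]).size < 2 or va.sum() == 0:
            continue
        Xtr = np.ascontiguousarray(X[tr])
        for li, lam in enumerate(path):
            b0, beta, ok, _ = _cd_solve(
                Xtr, y[tr], fam, pen, lam, spec.alpha, spec.mcp_gamma,
                spec.max_iter, 1000, spec.tol,
            )
            losses[f, li] = _deviance(X[va], y[va], b0, beta, spec.family) / va.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_loss = np.nanmean(losses, axis=0)
        se_loss = np.nanstd(losses, axis=0, ddof=1) / math.sqrt(spec.cv_folds)
    if np.all(np.isnan(mean_loss)):
        return float(path[0])
    best = int(np.nanargmin(mean_loss))
    if spec.one_se:
        cutoff = mean_loss[best] + (se_loss[best] if np.isfinite(se_loss[best]) else 0.0)
        for li in range(path.size):  # path is descending in lambda
            if np.isfinite(mean_loss[li]) and mean_loss[li] <= cutoff:
                return float(path[li])
    return float(path[best])


# ---------------------------------------------------------------------------
# Stability machinery


@dataclass
class StabilityResult:
    """Outcome of bootstrap stability selection for one penalised model."""

    feature_names: list[str]
    selection_count: np.ndarray     # per feature
    stability_score: np.ndarray     # per feature, percent of bootstraps
    sign_records: np.ndarray        # n_bootstraps x p, int8 in {-1, 0, +1}
    n_bootstraps: int
    threshold: float | None = None  # percent
    bootstrap_p: np.ndarray | None = None
    n_permutations: int | None = None
    n_permutation_bootstraps: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "selection_count": self.selection_count,
                "stability_score": self.stability_score,
            }
        )
        if self.bootstrap_p is not None:
            df["bootstrap_p"] = self.bootstrap_p
        if self.threshold is not None:
            df["threshold"] = self.threshold
            if self.bootstrap_p is not None:
                df["selected"] = (self.stability_score > self.threshold) & (
                    np.nan_to_num(self.bootstrap_p, nan=1.0) < 0.05
                )
        return df


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices of a class-stratified bootstrap resample."""
    idx = []
    for cls in np.unique(y):
        members = np.nonzero(y == cls)[0]
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def stability_scores(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenalisedSpec = PenalisedSpec(),
    n_boot: int = 500,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> StabilityResult:
    """Selection frequency of every feature across stratified bootstraps.

    Each resample keeps the per-class sample counts (so both classes are
    always present), refits the penalised model (penalty strength by
    inner CV on the resample unless fixed), and records the sign of each
    non-zero coefficient.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    signs = np.zeros((n_boot, p), dtype=np.int8)
    for b in range(n_boot):
        rows = _stratified_bootstrap(y, rng)
        Xb, yb = np.ascontiguousarray(X[rows]), y[rows]
        lam = spec.lambda_
        if lam is None:
            # per-bootstrap CV with folds grouped by original row, so
            # resampled duplicates never straddle train and validation
            lam = _cv_lambda(Xb, yb, spec, rng, groups=rows)
        beta = _fit_at(Xb, yb, spec, lam)
        signs[b] = np.sign(np.where(np.abs(beta) > 1e-8, beta, 0.0)).astype(np.int8)
    count = (signs != 0).sum(axis=0)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{j}" for j in range(p)]
    )
    return StabilityResult(
        feature_names=names,
        selection_count=count,
        stability_score=100.0 * count / n_boot,
        sign_records=signs,
        n_bootstraps=n_boot,
    )


def permutation_threshold(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenalisedSpec = PenalisedSpec(),
    n_perm: int = 20,
    n_perm_boot: int = 50,
    seed: int = 0,
    quantile: float = 1.0,
) -> float:
    """Null stability threshold (percent).

    The outcome is permuted ``n_perm`` times; each permuted dataset is
    run through ``n_perm_boot`` bootstrap refits; the threshold is the
    highest stability score any feature attains in any permuted dataset
    (``quantile=1``; a lower quantile of the per-permutation maxima is
    available as a softer alternative).
    """
    if n_perm < 1 or n_perm_boot < 1:
        raise ValueError("n_perm and n_perm_boot must be >= 1")
    rng = np.random.default_rng(seed)
    per_perm_max = np.empty(n_perm)
    for k in range(n_perm):
        while True:
            y_perm = rng.permutation(y)
            if np.unique(y_perm).size == 2:
                break
        res = stability_scores(
            X, y_perm, spec, n_boot=n_perm_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        per_perm_max[k] = res.stability_score.max() if res.stability_score.size else 0.0
    return float(np.quantile(per_perm_max, quantile))


def bootstrap_p(sign_records: np.ndarray) -> np.ndarray:
    """Sign-based bootstrap p-values from a (bootstraps x features) sign
    record.

    For each feature, p = (# selections on the minority side of zero) /
    (# selections); zero coefficients count as unselected.  Features never
    selected get NaN (undefined).
    """
    signs = np.asarray(sign_records)
    pos = (signs > 0).sum(axis=0).astype(float)
    neg = (signs < 0).sum(axis=0).astype(float)
    total = pos + neg
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, np.minimum(pos, neg) / total, np.nan)
    return p


def select_stable(result: StabilityResult, p_cut: float = 0.05) -> np.ndarray:
    """Indices of features with stability score strictly above the
    threshold AND bootstrap p-value below ``p_cut``."""
    if result.threshold is None:
        raise ValueError("threshold has not been computed")
    p = (
        result.bootstrap_p
        if result.bootstrap_p is not None
        else bootstrap_p(result.sign_records)
    )
    keep = (result.stability_score > result.threshold) & (
        np.nan_to_num(p, nan=1.0) < p_cut
    )
    return np.nonzero(keep)[0]


def run_stability(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenalisedSpec = PenalisedSpec(),
    n_boot: int = 500,
    n_perm: int = 20,
    n_perm_boot: int = 50,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> StabilityResult:
    """Full stability-selection run: scores, permutation threshold and
    bootstrap p-values in one result."""
    result = stability_scores(X, y, spec, n_boot=n_boot, seed=seed,
                              feature_names=feature_names)
    result.threshold = permutation_threshold(
        X, y, spec, n_perm=n_perm, n_perm_boot=n_perm_boot, seed=seed + 1
    )
    result.bootstrap_p = bootstrap_p(result.sign_records)
    result.n_permutations = n_perm
    result.n_permutation_bootstraps = n_perm_boot
    return result


def plot_stability(result: StabilityResult, ax=None, min_score: float = 5.0):
    """Lollipop plot of stability scores (features below ``min_score``
    omitted), with the permutation threshold as a horizontal line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    keep = result.stability_score >= min_score
    names = [n for n, k in zip(result.feature_names, keep) if k]
    scores = result.stability_score[keep]
    order = np.argsort(scores)[::-1]
    xs = np.arange(order.size)
    ax.stem(xs, scores[order])
    ax.set_xticks(xs, [names[i] for i in order])
    if result.threshold is not None:
        ax.axhline(result.threshold, color="red", ls="--", label="threshold")
        ax.legend()
    ax.set_ylabel("stability score (%)")
    ax.tick_params(axis="x", rotation=90)
    return ax
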