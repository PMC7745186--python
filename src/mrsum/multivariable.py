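"""Multivariable MR: several risk factors analysed jointly.

With K risk factors sharing genetic predictors, the causal effect of each
risk factor (conditional on the others) is estimated by regressing the
per-variant outcome associations on the J x K matrix of risk-factor
associations, assuming every causal path from a variant to the outcome
passes through one of the K risk factors.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .core import (
    HeterogeneityResult,
    InterceptResult,
    MRMVInput,
    ValidationError,
    confidence_interval,
    outcome_covariance,
)
from .univariable import _gls, _robust_fit, _wls

logger = logging.getLogger("mrsum")

__all__ = ["MVEstimate", "mvivw", "mvegger", "mvmedian", "mvlasso",
           "predicted_outcome_associations"]

from dataclasses import dataclass, field


@dataclass
class MVEstimate:
    """Result of a multivariable estimator: one coefficient per risk factor,
    ordered as in the input's ``exposure_names``."""

    method: str
    exposure_names: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    alpha: float
    n_variants: int
    outcome_name: str = "outcome"
    heterogeneity: HeterogeneityResult | None = None
    intercept: InterceptResult | None = None
    valid_variants: tuple[str, ...] | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"method": self.method, "alpha": self.alpha,
               "n_variants": self.n_variants, "outcome": self.outcome_name,
               "exposures": []}
        for k, name in enumerate(self.exposure_names):
            out["exposures"].append({
                "exposure": name,
                "estimate": float(self.estimates[k]),
                "std_error": float(self.std_errors[k]),
                "ci_lower": float(self.ci_lower[k]),
                "ci_upper": float(self.ci_upper[k]),
                "p_value": float(self.p_values[k]),
            })
        if self.heterogeneity is not None:
            out["heterogeneity_stat"] = self.heterogeneity.statistic
            out["heterogeneity_df"] = self.heterogeneity.df
            out["heterogeneity_p"] = self.heterogeneity.p_value
        if self.intercept is not None:
            out["intercept"] = self.intercept.estimate
            out["intercept_se"] = self.intercept.std_error
            out["intercept_p"] = self.intercept.p_value
        if self.valid_variants is not None:
            out["valid_variants"] = list(self.valid_variants)
        for key, val in self.extra.items():
            if isinstance(val, (int, float, str, bool)) or val is None:
                out[key] = val
        return out


def _check_rank(X: np.ndarray, w: np.ndarray, names):
    Xw = X * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # identify dependent columns via the R factor of a pivoted-free QR
        _, R = np.linalg.qr(Xw)
        diag = np.abs(np.diag(R))
        dep = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValidationError(
            f"risk-factor association matrix is rank deficient "
            f"(rank {rank} < {X.shape[1]}); collinear columns: {dep or names}")


def _mv_ci(beta, ses, alpha, distribution, df):
    dist = {"t-dist": "t"}.get(distribution, distribution)
    los, his, ps = [], [], []
    for b, s in zip(beta, ses):
        lo, hi, p = confidence_interval(float(b), float(s), alpha, dist,
                                        df if dist == "t" else None)
        los.append(lo)
        his.append(hi)
        ps.append(p)
    return np.array(los), np.array(his), np.array(ps)


def mvivw(data: MRMVInput, *, model: str = "default", robust: bool = False,
          correl: bool = False, distribution: str = "normal",
          alpha: float = 0.05) -> MVEstimate:
    """Multivariable IVW: zero-intercept weighted regression of by on all
    risk-factor association columns, weights byse^-2 (GLS with the LD-based
    outcome covariance when ``correl=True``).

    ``model="default"`` uses a fixed-effect fit when J <= K + 2 and a
    multiplicative random-effects fit otherwise; the random-effects SEs
    multiply the fixed-effect SEs by max(1, sqrt(Q/(J-K))).
    """
    J, K = data.n_variants, data.n_exposures
    if model not in ("default", "fixed", "random"):
        raise ValidationError(f"unknown model {model!r}")
    if correl and data.correlation is None:
        raise ValidationError("correl=True requires a correlation matrix")
    if correl and robust:
        raise ValidationError("robust is incompatible with correl=True")
    if model == "default":
        model = "fixed" if J <= K + 2 else "random"
    X = data.bx
    w = data.byse ** -2.0
    # a risk factor with no instrument signal at all is dropped from the fit
    # (its effect is undetermined, reported NaN) rather than treated as
    # collinear; genuine collinearity among informative columns still errors
    zero_cols = np.flatnonzero(np.all(X == 0.0, axis=0))
    if len(zero_cols):
        names = [data.exposure_names[k] for k in zero_cols]
        logger.warning("risk factor(s) %s have all-zero associations; "
                       "their effects are undetermined (NaN)", names)
        keep_cols = np.setdiff1d(np.arange(K), zero_cols)
        sub = MRMVInput(snps=data.snps, bx=X[:, keep_cols],
                        bxse=data.bxse[:, keep_cols], by=data.by,
                        byse=data.byse, correlation=data.correlation,
                        exposure_names=tuple(data.exposure_names[k]
                                             for k in keep_cols),
                        outcome_name=data.outcome_name)
        inner = mvivw(sub, model=model, robust=robust, correl=correl,
                      distribution=distribution, alpha=alpha)
        nan = np.full(K, np.nan)
        est, ses_, lo_, hi_, p_ = (nan.copy() for _ in range(5))
        cov = np.full((K, K), np.nan)
        for i, k in enumerate(keep_cols):
            est[k] = inner.estimates[i]
            ses_[k] = inner.std_errors[i]
            lo_[k], hi_[k], p_[k] = (inner.ci_lower[i], inner.ci_upper[i],
                                     inner.p_values[i])
            cov[np.ix_([k], keep_cols)] = inner.extra["cov"][i]
        return MVEstimate(method="mvivw", exposure_names=data.exposure_names,
                          estimates=est, std_errors=ses_, ci_lower=lo_,
                          ci_upper=hi_, p_values=p_, alpha=alpha,
                          n_variants=J, outcome_name=data.outcome_name,
                          heterogeneity=inner.heterogeneity,
                          extra={**inner.extra, "cov": cov,
                                 "undetermined": names})
    _check_rank(X, w, list(data.exposure_names))
    if correl:
        omega = outcome_covariance(data.byse, data.correlation)
        beta, cov, Q = _gls(X, data.by, omega)
    elif robust:
        params, bse = _robust_fit(X, data.by, data.byse)
        beta = params
        cov = np.diag(bse ** 2)
        Q = float(np.sum(w * (data.by - X @ beta) ** 2))
    else:
        beta, cov, Q = _wls(X, data.by, w)
    ses = np.sqrt(np.diag(cov))
    phi = 1.0
    if model == "random" and J > K:
        phi = max(1.0, np.sqrt(Q / (J - K)))
    ses = ses * phi
    het = HeterogeneityResult(Q, J - K, float(stats.chi2.sf(Q, J - K)))
    lo, hi, p = _mv_ci(beta, ses, alpha, distribution, J - K)
    return MVEstimate(method="mvivw", exposure_names=data.exposure_names,
                      estimates=np.asarray(beta, float), std_errors=ses,
                      ci_lower=lo, ci_upper=hi, p_values=p, alpha=alpha,
                      n_variants=J, outcome_name=data.outcome_name,
                      heterogeneity=het,
                      extra={"model": model, "robust": robust, "correl": correl,
                             "cov": cov * phi ** 2})


def _orient_rows(data: MRMVInput, orientate: int):
    """Sign-flip each variant's row (all bx columns and by) so that the
    orientate-th (1-based) risk-factor association is non-negative."""
    col = data.bx[:, orientate - 1]
    sign = np.where(col < 0, -1.0, 1.0)
    bx = data.bx * sign[:, None]
    by = data.by * sign
    corr = None
    if data.correlation is not None:
        corr = sign[:, None] * data.correlation * sign[None, :]
        np.fill_diagonal(corr, 1.0)
    return bx, by, corr


def mvegger(data: MRMVInput, *, orientate: int = 1, correl: bool = False,
            distribution: str = "normal", alpha: float = 0.05) -> MVEstimate:
    """Multivariable MR-Egger: weighted multivariable regression with an
    intercept, rows oriented so the ``orientate``-th risk-factor association
    is non-negative.  The intercept estimates average directional
    pleiotropy.  Dispersion max(1, sqrt(Q/(J-K-1))) scales the SEs.
    """
    J, K = data.n_variants, data.n_exposures
    if J <= K + 1:
        raise ValidationError(
            f"multivariable Egger requires J > K + 1 (J={J}, K={K})")
    if not 1 <= orientate <= K:
        raise ValidationError(f"orientate must be in 1..{K}")
    if correl and data.correlation is None:
        raise ValidationError("correl=True requires a correlation matrix")
    bx, by, corr = _orient_rows(data, orientate)
    X = np.column_stack([np.ones(J), bx])
    w = data.byse ** -2.0
    _check_rank(X, w, ["intercept"] + list(data.exposure_names))
    if correl:
        omega = outcome_covariance(data.byse, corr)
        beta, cov, Q = _gls(X, by, omega)
    else:
        beta, cov, Q = _wls(X, by, w)
    df = J - K - 1
    phi = max(1.0, np.sqrt(Q / df))
    ses = np.sqrt(np.diag(cov)) * phi
    het = HeterogeneityResult(Q, df, float(stats.chi2.sf(Q, df)))
    lo, hi, p = _mv_ci(beta[1:], ses[1:], alpha, distribution, df)
    ilo, ihi, ip = confidence_interval(float(beta[0]), float(ses[0]), alpha,
                                       *( ("t", df) if distribution in ("t", "t-dist")
                                          else ("normal", None)))
    return MVEstimate(method="mvegger", exposure_names=data.exposure_names,
                      estimates=np.asarray(beta[1:], float),
                      std_errors=ses[1:], ci_lower=lo, ci_upper=hi,
                      p_values=p, alpha=alpha, n_variants=J,
                      outcome_name=data.outcome_name, heterogeneity=het,
                      intercept=InterceptResult(float(beta[0]), float(ses[0]),
                                                ilo, ihi, ip),
                      extra={"orientate": orientate, "correl": correl,
                             "dispersion": float(phi)})


def _weighted_l1_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted L1 (median) regression without intercept via linear
    programming: min sum_j w_j |y_j - x_j' theta|.

    Multiplying each row by its (positive) weight reduces the problem to an
    unweighted L1 fit, solved with the HiGHS LP solver.
    """
    from scipy.optimize import linprog

    J, K = X.shape
    Xw = X * w[:, None]
    yw = y * w
    # variables: theta (K, free), u (J), v (J) with residual = u - v, u,v >= 0
    c = np.concatenate([np.zeros(K), np.ones(J), np.ones(J)])
    A_eq = np.hstack([Xw, np.eye(J), -np.eye(J)])
    bounds = [(None, None)] * K + [(0, None)] * (2 * J)
    res = linprog(c, A_eq=A_eq, b_eq=yw, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"weighted L1 regression failed: {res.message}")
    return res.x[:K]


def mvmedian(data: MRMVInput, *, iterations: int = 10000,
             seed: int | None = None, distribution: str = "normal",
             alpha: float = 0.05) -> MVEstimate:
    """Multivariable median-based estimate: weighted L1 regression of by on
    the risk-factor associations (no intercept), weights byse^-2, robust to
    a minority of outlying variants.  SEs come from a parametric bootstrap
    (bx and by both resampled); ``seed`` is required.
    """
    J, K = data.n_variants, data.n_exposures
    if seed is None:
        raise ValidationError("mvmedian requires an explicit seed for the bootstrap SE")
    w = data.byse ** -2.0
    _check_rank(data.bx, w, list(data.exposure_names))
    beta = _weighted_l1_fit(data.bx, data.by, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((iterations, K))
    for b in range(iterations):
        bxs = rng.normal(data.bx, data.bxse)
        bys = rng.normal(data.by, data.byse)
        boots[b] = _weighted_l1_fit(bxs, bys, w)
    ses = np.std(boots, axis=0, ddof=1)
    lo, hi, p = _mv_ci(beta, ses, alpha, distribution, J - K)
    return MVEstimate(method="mvmedian", exposure_names=data.exposure_names,
                      estimates=beta, std_errors=ses, ci_lower=lo,
                      ci_upper=hi, p_values=p, alpha=alpha, n_variants=J,
                      outcome_name=data.outcome_name,
                      extra={"iterations": iterations, "seed": seed})


def _mvlasso_fit(X, y, w, lam, a_start=None, tol=1e-12, maxiter=20000):
    """Coordinate descent for per-variant intercepts with an L1 penalty:
    min_theta,a sum_j w_j (y_j - a_j - x_j' theta)^2 + lam sum_j |a_j|."""
    J, K = X.shape
    a = np.zeros(J) if a_start is None else a_start.copy()
    XtW = X.T * w
    xtwx = XtW @ X
    theta = np.linalg.solve(xtwx, XtW @ (y - a))
    for _ in range(maxiter):
        resid = y - X @ theta
        thresh = lam / (2 * w)
        a_new = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0)
        theta_new = np.linalg.solve(xtwx, XtW @ (y - a_new))
        if np.max(np.abs(a_new - a)) < tol and np.max(np.abs(theta_new - theta)) < tol:
            a, theta = a_new, theta_new
            break
        a, theta = a_new, theta_new
    return theta, a


def mvlasso(data: MRMVInput, *, lam: float = 0.0, distribution: str = "normal",
            alpha: float = 0.05) -> MVEstimate:
    """Multivariable lasso: per-variant intercepts with an L1 penalty;
    variants whose intercept is shrunk to zero form the valid set and the
    reported coefficients are the multivariable IVW fit on that set.
    ``lam=0`` selects lambda by the same heterogeneity stopping rule as the
    univariable lasso, with Q on |S| - K degrees of freedom.
    """
    J, K = data.n_variants, data.n_exposures
    if J <= K + 2:
        raise ValidationError(
            f"multivariable lasso requires J > K + 2 (J={J}, K={K})")
    if data.correlation is not None:
        raise ValidationError("mvlasso does not support correlated variants")
    w = data.byse ** -2.0
    X, y = data.bx, data.by
    _check_rank(X, w, list(data.exposure_names))

    def q_subset(keep):
        Xs, ys, ws = X[keep], y[keep], w[keep]
        beta, _, q = _wls(Xs, ys, ws)
        return q

    if lam > 0:
        _, a = _mvlasso_fit(X, y, w, lam)
        keep = a == 0.0
        lam_used = lam
    else:
        theta0, _, _ = _wls(X, y, w)
        lam_max = 2.0 * np.max(w * np.abs(y - X @ theta0)) * (1 + 1e-10)
        keep = np.ones(J, dtype=bool)
        lam_used = lam_max
        a_start = None
        found = lam_max == 0.0  # perfect fit: nothing to penalize
        path = [] if found else np.geomspace(lam_max, lam_max * 1e-3, 100)
        for lam_val in path:
            _, a_start = _mvlasso_fit(X, y, w, lam_val, a_start)
            keep_i = a_start == 0.0
            if keep_i.sum() <= K:
                break
            if q_subset(keep_i) <= stats.chi2.ppf(0.95, int(keep_i.sum()) - K):
                keep, lam_used, found = keep_i, float(lam_val), True
                break
        if not found:
            raise ValidationError(
                "no lambda on the path yields a homogeneous valid set of more "
                "than K variants; supply a larger lambda explicitly")
    if keep.sum() < K + 1:
        raise ValidationError(
            f"only {int(keep.sum())} variants retained at lambda={lam_used:g}; "
            "supply a larger lambda")
    from .core import make_mvinput
    sub = make_mvinput(X[keep], data.bxse[keep], y[keep], data.byse[keep],
                       snps=[s for s, k in zip(data.snps, keep) if k],
                       exposure_names=data.exposure_names,
                       outcome_name=data.outcome_name)
    post = mvivw(sub, distribution=distribution, alpha=alpha)
    post.method = "mvlasso"
    post.n_variants = J
    post.valid_variants = sub.snps
    post.extra = {"lambda": float(lam_used), "n_valid": int(keep.sum())}
    return post


def predicted_outcome_associations(data: MRMVInput, result: MVEstimate,
                                   alpha: float = 0.05):
    """Fitted outcome associations from a multivariable IVW fit.

    Per variant: predicted by = x_j' theta-hat, with CI from the variance
    x_j' Cov(theta-hat) x_j only — uncertainty in the coefficient estimates,
    not in the risk-factor associations, which are treated as fixed.
    Returns a DataFrame with the observed by/byse alongside, for the
    predicted-versus-observed scatter plot.
    """
    import pandas as pd

    if len(result.estimates) != data.n_exposures:
        raise ValidationError("result and input have different numbers of "
                              "risk factors")
    cov = result.extra.get("cov")
    if cov is None:
        raise ValidationError("result lacks a coefficient covariance matrix; "
                              "use an mvivw() result")
    pred = data.bx @ result.estimates
    var = np.einsum("jk,kl,jl->j", data.bx, cov, data.bx)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "snp": list(data.snps),
        "predicted": pred,
        "predicted_se": se,
        "predicted_lower": pred - z * se,
        "predicted_upper": pred + z * se,
        "observed": data.by,
        "observed_se": data.byse,
    })
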