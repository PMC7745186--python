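"""Univariable causal-effect estimators for summarized-data MR.

Each estimator regresses, pools, or models the per-variant association
estimates (bx, by) to produce one causal effect of the risk factor on the
outcome, under different assumptions about which variants are valid
instruments:

* ``ivw`` — inverse-variance weighted: zero-intercept weighted regression
  of by on bx; most efficient, biased if the average pleiotropic effect is
  nonzero.  ``robust=True`` switches to robust (Tukey bisquare) regression;
  ``penalized=True`` down-weights variants with outlying heterogeneity
  contributions; ``correl=True`` uses generalized least squares with the
  supplied LD matrix.
* ``egger`` — weighted regression with an intercept; the intercept
  estimates the average directional pleiotropy (valid under the InSIDE
  assumption).
* ``median`` — simple/weighted/penalized median of the per-variant ratio
  estimates; consistent when at least half the weight is on valid variants.
* ``maxlik`` — maximum likelihood accounting for uncertainty in bx.
* ``mbe`` — mode-based estimate: the mode of a kernel-smoothed density of
  the ratio estimates.
* ``hetpen`` — heterogeneity-penalized model averaging over variant subsets.
* ``conmix`` — contamination-mixture profile likelihood classifying each
  variant as valid or invalid.
* ``lasso`` — per-variant intercepts with an L1 penalty; variants whose
  intercept is shrunk to zero form the valid set for a post-selection IVW.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
from scipy import stats

from .core import (
    HeterogeneityResult,
    InterceptResult,
    MREstimate,
    MRInput,
    ValidationError,
    confidence_interval,
    outcome_covariance,
    ratio_estimates,
    solve_spd,
)

logger = logging.getLogger("mrsum")

__all__ = ["ivw", "egger", "median", "maxlik", "mbe", "hetpen", "conmix",
           "lasso", "heterogeneity", "run_all", "METHOD_TOKENS"]

_PENALTY_CONSTANT = 20.0  # scale on the chi-square tail probability in penalized weights


# --------------------------------------------------------------------------
# shared fitting machinery
# --------------------------------------------------------------------------


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via normal equations.

    Returns (beta, cov_unit, rss) where cov_unit = (X'WX)^-1 and
    rss = weighted residual sum of squares (the heterogeneity Q when the
    weights are inverse variances).
    """
    XtW = X.T * w
    xtwx = XtW @ X
    beta = np.linalg.solve(xtwx, XtW @ y)
    resid = y - X @ beta
    rss = float(np.sum(w * resid ** 2))
    return beta, np.linalg.inv(xtwx), rss


def _gls(X: np.ndarray, y: np.ndarray, omega: np.ndarray):
    """Generalized least squares with outcome covariance omega."""
    oinv_X = solve_spd(omega, X)
    oinv_y = solve_spd(omega, y)
    xtox = X.T @ oinv_X
    beta = np.linalg.solve(xtox, X.T @ oinv_y)
    resid = y - X @ beta
    rss = float(resid @ solve_spd(omega, resid))
    return beta, np.linalg.inv(np.atleast_2d(xtox)), rss


def _robust_fit(X: np.ndarray, y: np.ndarray, byse: np.ndarray):
    """Robust regression on inverse-SE-standardized data.

    Tukey bisquare (c = 4.685) iteratively reweighted least squares,
    started from a high-breakdown median-regression fit with the residual
    scale fixed at the MAD of the initial residuals.
    """
    import statsmodels.api as sm
    from statsmodels.regression.quantile_regression import QuantReg

    Xs = X / byse[:, None]
    ys = y / byse
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rlm = sm.RLM(ys, Xs, M=sm.robust.norms.TukeyBiweight(c=4.685))
        if X.shape[1] > 1:
            start = QuantReg(ys, Xs).fit(q=0.5).params
            res = rlm.fit(start_params=start, scale_est="mad", maxiter=200)
        else:  # statsmodels rejects a length-1 start vector; OLS init is fine
            res = rlm.fit(scale_est="mad", maxiter=200)
    return np.atleast_1d(res.params), np.atleast_1d(res.bse)


def _penalized_weights(bx, by, w):
    """Down-weight variants by their heterogeneity contribution p-value.

    Each variant's contribution q_j = w_j (by_j - theta0 bx_j)^2 at the
    plain IVW estimate theta0 is referred to a chi-square(1); the weight is
    multiplied by min(1, 20 p_j), so only clearly outlying variants lose
    weight.
    """
    theta0 = np.sum(w * bx * by) / np.sum(w * bx ** 2)
    q = w * (by - theta0 * bx) ** 2
    p = stats.chi2.sf(q, df=1)
    return w * np.minimum(1.0, _PENALTY_CONSTANT * p)


def _ci_df(distribution: str, df: int):
    dist = {"t-dist": "t"}.get(distribution, distribution)
    return dist, (df if dist == "t" else None)


# --------------------------------------------------------------------------
# IVW
# --------------------------------------------------------------------------


def ivw(data: MRInput, *, model: str = "default", robust: bool = False,
        penalized: bool = False, correl: bool = False,
        distribution: str = "normal", alpha: float = 0.05) -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model`` is ``"fixed"``, ``"random"`` (multiplicative random effects),
    or ``"default"`` (fixed when J <= 3, random otherwise).  The
    random-effects SE multiplies the fixed-effect SE by
    max(1, sqrt(Q/(J-1))).
    """
    J = data.n_variants
    if model not in ("default", "fixed", "random"):
        raise ValidationError(f"unknown model {model!r}")
    if model == "random" and J < 2:
        raise ValidationError("random-effects model requires at least 2 variants")
    if correl and data.correlation is None:
        raise ValidationError("correl=True requires a correlation matrix")
    if correl and (robust or penalized):
        raise ValidationError("robust/penalized are incompatible with correl=True")
    if model == "default":
        model = "fixed" if J <= 3 else "random"

    X = data.bx[:, None]
    extra: dict = {"model": model, "robust": robust, "penalized": penalized,
                   "correl": correl}
    if correl:
        omega = outcome_covariance(data.byse, data.correlation)
        beta, cov, Q = _gls(X, data.by, omega)
        theta, se_fixed = float(beta[0]), float(np.sqrt(cov[0, 0]))
    else:
        w = data.byse ** -2.0
        if penalized:
            w = _penalized_weights(data.bx, data.by, w)
        if robust:
            params, bse = _robust_fit(X, data.by, data.byse)
            theta, se_fixed = float(params[0]), float(bse[0])
            _, _, Q = _wls(X, data.by, data.byse ** -2.0)
            # Q reported on unpenalized weights about the robust fit
            Q = float(np.sum(data.byse ** -2.0 * (data.by - theta * data.bx) ** 2))
        else:
            beta, cov, Q = _wls(X, data.by, w)
            theta, se_fixed = float(beta[0]), float(np.sqrt(cov[0, 0]))

    het = None
    if J >= 2:
        het = HeterogeneityResult(Q, J - 1, float(stats.chi2.sf(Q, J - 1)))
    se = se_fixed
    if model == "random" and J >= 2:
        se = se_fixed * max(1.0, np.sqrt(Q / (J - 1)))
    dist, df = _ci_df(distribution, J - 1 if J > 1 else 1)
    lo, hi, p = confidence_interval(theta, se, alpha, dist, df)
    return MREstimate(method="ivw", estimate=theta, std_error=se, ci_lower=lo,
                      ci_upper=hi, p_value=p, alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      heterogeneity=het, extra=extra)


# --------------------------------------------------------------------------
# MR-Egger
# --------------------------------------------------------------------------


def _orient(data: MRInput):
    """Flip each variant's (bx, by) so bx >= 0; flip the LD matrix to match."""
    sign = np.where(data.bx < 0, -1.0, 1.0)
    bx = data.bx * sign
    by = data.by * sign
    corr = None
    if data.correlation is not None:
        corr = sign[:, None] * data.correlation * sign[None, :]
        np.fill_diagonal(corr, 1.0)
    return bx, by, corr


def egger(data: MRInput, *, robust: bool = False, correl: bool = False,
          distribution: str = "normal", alpha: float = 0.05) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with an intercept.

    The slope is the causal estimate and the intercept the average
    pleiotropic (direct) effect; variants are first oriented so all bx >= 0.
    Standard errors use multiplicative random effects with dispersion
    max(1, sqrt(Q_Ruecker/(J-2))).
    """
    J = data.n_variants
    if J < 3:
        raise ValidationError("MR-Egger requires at least 3 variants")
    if correl and data.correlation is None:
        raise ValidationError("correl=True requires a correlation matrix")
    if correl and robust:
        raise ValidationError("robust is incompatible with correl=True")
    bx, by, corr = _orient(data)
    X = np.column_stack([np.ones(J), bx])
    if correl:
        omega = outcome_covariance(data.byse, corr)
        beta, cov, Q = _gls(X, by, omega)
        ses = np.sqrt(np.diag(cov))
    elif robust:
        params, bse = _robust_fit(X, by, data.byse)
        beta, ses = params, bse
        Q = float(np.sum(data.byse ** -2.0 * (by - X @ beta) ** 2))
    else:
        beta, cov, Q = _wls(X, by, data.byse ** -2.0)
        ses = np.sqrt(np.diag(cov))
    phi = max(1.0, np.sqrt(Q / (J - 2)))
    ses = ses * phi
    dist, df = _ci_df(distribution, J - 2)
    slope, slope_se = float(beta[1]), float(ses[1])
    inter, inter_se = float(beta[0]), float(ses[0])
    lo, hi, p = confidence_interval(slope, slope_se, alpha, dist, df)
    ilo, ihi, ip = confidence_interval(inter, inter_se, alpha, dist, df)
    het = HeterogeneityResult(Q, J - 2, float(stats.chi2.sf(Q, J - 2)))
    return MREstimate(method="egger", estimate=slope, std_error=slope_se,
                      ci_lower=lo, ci_upper=hi, p_value=p, alpha=alpha,
                      n_variants=J, exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name, heterogeneity=het,
                      intercept=InterceptResult(inter, inter_se, ilo, ihi, ip),
                      extra={"robust": robust, "correl": correl,
                             "dispersion": float(phi)})


# --------------------------------------------------------------------------
# median methods
# --------------------------------------------------------------------------


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with linear interpolation.

    For each row, sort values ascending and find the 50% point of the
    cumulative weight distribution (cumsum minus half the current weight,
    normalized), interpolating linearly between adjacent values.  With
    equal weights this reproduces the ordinary sample median.
    """
    values = np.atleast_2d(values)
    weights = np.atleast_2d(np.broadcast_to(weights, values.shape))
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    csum = np.cumsum(w, axis=1) - 0.5 * w
    csum = csum / np.sum(w, axis=1, keepdims=True)
    # index of last point strictly below 0.5 (clipped into range)
    below = np.clip(np.sum(csum < 0.5, axis=1) - 1, 0, values.shape[1] - 2)
    idx = np.arange(values.shape[0])
    c0, c1 = csum[idx, below], csum[idx, below + 1]
    v0, v1 = v[idx, below], v[idx, below + 1]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.5)
    frac = np.clip(frac, 0.0, 1.0)
    return v0 + frac * (v1 - v0)


def _median_weights(bx, by, byse, method: str) -> np.ndarray:
    if method == "simple":
        return np.ones_like(bx)
    w = bx ** 2 / byse ** 2  # inverse first-order variance of the ratio
    if method == "penalized":
        # penalize each variant's heterogeneity contribution about the IVW fit
        r = by / bx
        wr = byse ** -2.0
        theta0 = np.sum(wr * bx * by) / np.sum(wr * bx ** 2)
        q = w * (r - theta0) ** 2
        p = stats.chi2.sf(q, df=1)
        w = w * np.minimum(1.0, _PENALTY_CONSTANT * p)
    return w


def median(data: MRInput, *, method: str = "weighted", iterations: int = 10000,
           seed: int | None = None, distribution: str = "normal",
           alpha: float = 0.05) -> MREstimate:
    """Simple, weighted, or penalized-weighted median of the ratio estimates.

    The point estimate is the (weighted) median of by_j/bx_j; the standard
    error is the SD of the estimate over ``iterations`` parametric-bootstrap
    resamples (bx*, by* drawn from Normal(bx, bxse), Normal(by, byse)),
    with the weights held fixed at their observed values across resamples.
    ``seed`` is required for a reproducible SE.
    """
    J = data.n_variants
    if J < 3:
        raise ValidationError("median methods require at least 3 variants")
    if method not in ("simple", "weighted", "penalized"):
        raise ValidationError(f"unknown median method {method!r}")
    if seed is None:
        raise ValidationError("median requires an explicit seed for the bootstrap SE")
    w = _median_weights(data.bx, data.by, data.byse, method)
    theta = float(_weighted_median_rows(data.by / data.bx, w)[0])

    rng = np.random.default_rng(seed)
    bxs = rng.normal(data.bx, data.bxse, size=(iterations, J))
    bys = rng.normal(data.by, data.byse, size=(iterations, J))
    bxs = np.where(bxs == 0, 1e-300, bxs)
    ratios = bys / bxs
    if method == "simple":
        boots = np.median(ratios, axis=1)
    else:
        boots = _weighted_median_rows(ratios, np.broadcast_to(w, ratios.shape))
    se = float(np.std(boots, ddof=1))
    dist, df = _ci_df(distribution, J - 1)
    lo, hi, p = confidence_interval(theta, se, alpha, dist, df)
    name = {"simple": "median", "weighted": "wmedian", "penalized": "pmedian"}[method]
    return MREstimate(method=name, estimate=theta, std_error=se, ci_lower=lo,
                      ci_upper=hi, p_value=p, alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      extra={"iterations": iterations, "seed": seed})


# --------------------------------------------------------------------------
# maximum likelihood
# --------------------------------------------------------------------------


def _profile_loglik_factory(data: MRInput, correl: bool):
    """Profile log-likelihood of theta with the per-variant true effects
    xi_j profiled out in closed form.

    Model: bx_j ~ N(xi_j, bxse_j^2), by_j ~ N(theta xi_j, byse_j^2),
    independent across variants (or correlated through the LD matrix when
    ``correl``)."""
    bx, by = data.bx, data.by
    if not correl:
        vx, vy = data.bxse ** 2, data.byse ** 2

        def loglik(theta: float) -> float:
            xi = (bx / vx + theta * by / vy) / (1.0 / vx + theta ** 2 / vy)
            return float(-0.5 * np.sum((bx - xi) ** 2 / vx)
                         - 0.5 * np.sum((by - theta * xi) ** 2 / vy))
        return loglik

    sx = outcome_covariance(data.bxse, data.correlation)
    sy = outcome_covariance(data.byse, data.correlation)
    sx_inv = np.linalg.inv(sx)
    sy_inv = np.linalg.inv(sy)

    def loglik(theta: float) -> float:
        A = sx_inv + theta ** 2 * sy_inv
        rhs = sx_inv @ bx + theta * (sy_inv @ by)
        xi = np.linalg.solve(A, rhs)
        rx, ry = bx - xi, by - theta * xi
        return float(-0.5 * rx @ sx_inv @ rx - 0.5 * ry @ sy_inv @ ry)
    return loglik


def maxlik(data: MRInput, *, correl: bool = False, distribution: str = "normal",
           alpha: float = 0.05) -> MREstimate:
    """Maximum-likelihood estimate accounting for uncertainty in bx.

    The per-variant true effects are profiled out in closed form and the
    1-D profile log-likelihood is maximized numerically; the SE comes from
    the curvature (observed information) at the maximum.
    """
    from scipy.optimize import minimize_scalar

    if correl and data.correlation is None:
        raise ValidationError("correl=True requires a correlation matrix")
    J = data.n_variants
    loglik = _profile_loglik_factory(data, correl)
    start = ivw(data, model="fixed", correl=correl,
                distribution="normal").estimate
    res = minimize_scalar(lambda t: -loglik(t),
                          bracket=(start - 0.5, start + 0.5))
    if not res.success:  # pragma: no cover - brent rarely fails here
        raise RuntimeError(f"maximum-likelihood optimizer failed: {res.message}")
    theta = float(res.x)
    h = max(1e-6, 1e-5 * abs(theta))
    d2 = (loglik(theta + h) - 2 * loglik(theta) + loglik(theta - h)) / h ** 2
    if d2 >= 0:
        raise RuntimeError("maximum-likelihood curvature is not negative; "
                           "the likelihood may be flat (weak instruments)")
    se = float(np.sqrt(-1.0 / d2))
    dist, df = _ci_df(distribution, J - 1 if J > 1 else 1)
    lo, hi, p = confidence_interval(theta, se, alpha, dist, df)
    return MREstimate(method="maxlik", estimate=theta, std_error=se,
                      ci_lower=lo, ci_upper=hi, p_value=p, alpha=alpha,
                      n_variants=J, exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      extra={"correl": correl, "loglik": float(-res.fun)})


# --------------------------------------------------------------------------
# mode-based estimate
# --------------------------------------------------------------------------


def _mbe_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: phi * 0.9 * min(SD, MAD/0.6745) * J^(-1/5)."""
    sd = np.std(r, ddof=1) if len(r) > 1 else 0.0
    mad = np.median(np.abs(r - np.median(r))) / 0.6745
    s = min(sd, mad) if mad > 0 else sd
    return float(phi * 0.9 * s * len(r) ** (-0.2))


def _kde_mode(r: np.ndarray, w: np.ndarray, h: float, n_grid: int = 2001) -> float:
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = np.zeros_like(grid)
    for rj, wj in zip(r, w):
        dens += wj * np.exp(-0.5 * ((grid - rj) / h) ** 2)
    return float(grid[np.argmax(dens)])


def mbe(data: MRInput, *, weighting: str = "weighted", stderror: str = "simple",
        phi: float = 1.0, iterations: int = 10000, seed: int | None = None,
        distribution: str = "normal", alpha: float = 0.05) -> MREstimate:
    """Mode-based estimate: the mode of a kernel-smoothed density of the
    per-variant ratio estimates.

    ``weighting="weighted"`` weights each ratio by its inverse variance;
    ``stderror`` selects first-order (``"simple"``) or second-order
    (``"delta"``) ratio SEs for those weights.  The bandwidth is ``phi``
    times a modified Silverman rule, and the mode is located by dense-grid
    search.  The SE is a parametric bootstrap over ``iterations`` draws.
    """
    J = data.n_variants
    if J < 3:
        raise ValidationError("mode-based estimation requires at least 3 variants")
    if weighting not in ("weighted", "simple"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    if stderror not in ("simple", "delta"):
        raise ValidationError(f"unknown stderror {stderror!r}")
    if seed is None:
        raise ValidationError("mbe requires an explicit seed for the bootstrap SE")

    def ratio_se(bx, bxse, by, byse):
        if stderror == "simple":
            return byse / np.abs(bx)
        return np.sqrt(byse ** 2 / bx ** 2 + by ** 2 * bxse ** 2 / bx ** 4)

    def point_estimate(bx, bxse, by, byse):
        r = by / bx
        se = ratio_se(bx, bxse, by, byse)
        w = np.ones_like(r) if weighting == "simple" else se ** -2.0
        w = w / w.sum()
        h = _mbe_bandwidth(r, phi)
        if h == 0 or np.ptp(r) < 1e-12 * max(1.0, np.max(np.abs(r))):
            logger.info("all ratio estimates coincide; mode equals the common value")
            return float(np.mean(r)), 0.0
        return _kde_mode(r, w, h), h

    theta, bandwidth = point_estimate(data.bx, data.bxse, data.by, data.byse)

    rng = np.random.default_rng(seed)
    boots = np.empty(iterations)
    # chunked bootstrap: vectorize the grid KDE over replicates
    chunk = max(1, int(2_000_000 / (2001))) if J else iterations
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        bxs = rng.normal(data.bx, data.bxse, size=(b, J))
        bys = rng.normal(data.by, data.byse, size=(b, J))
        bxs = np.where(bxs == 0, 1e-300, bxs)
        rs = bys / bxs
        ses = (data.byse / np.abs(bxs) if stderror == "simple"
               else np.sqrt(data.byse ** 2 / bxs ** 2
                            + bys ** 2 * data.bxse ** 2 / bxs ** 4))
        ws = np.ones_like(rs) if weighting == "simple" else ses ** -2.0
        ws = ws / ws.sum(axis=1, keepdims=True)
        sd = np.std(rs, axis=1, ddof=1)
        madv = np.median(np.abs(rs - np.median(rs, axis=1, keepdims=True)),
                         axis=1) / 0.6745
        hs = phi * 0.9 * np.minimum(sd, np.where(madv > 0, madv, sd)) * J ** (-0.2)
        hs = np.where(hs > 0, hs, 1e-12)
        lo = rs.min(axis=1) - 3 * hs
        hi = rs.max(axis=1) + 3 * hs
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, 501)[None, :]
        dens = np.zeros_like(grid)
        for j in range(J):
            dens += ws[:, j:j + 1] * np.exp(
                -0.5 * ((grid - rs[:, j:j + 1]) / hs[:, None]) ** 2)
        boots[done:done + b] = grid[np.arange(b), np.argmax(dens, axis=1)]
        done += b
    se = float(np.std(boots, ddof=1))
    dist, df = _ci_df(distribution, J - 1)
    lo_, hi_, p = confidence_interval(theta, se, alpha, dist, df)
    return MREstimate(method="mbe", estimate=theta, std_error=se, ci_lower=lo_,
                      ci_upper=hi_, p_value=p, alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      extra={"weighting": weighting, "stderror": stderror,
                             "phi": phi, "bandwidth": bandwidth,
                             "iterations": iterations, "seed": seed})


# --------------------------------------------------------------------------
# heterogeneity-penalized model averaging
# --------------------------------------------------------------------------


def _default_grid(r: np.ndarray, se: np.ndarray, ci_min, ci_max, ci_step):
    if ci_min is None:
        ci_min = float(r.min() - 5 * se.max())
    if ci_max is None:
        ci_max = float(r.max() + 5 * se.max())
    if ci_max <= ci_min:
        ci_min, ci_max = ci_min - 1.0, ci_max + 1.0
    if ci_step is None:
        ci_step = 0.001 * (ci_max - ci_min)
    if ci_step <= 0:
        raise ValidationError("ci_step must be positive")
    n = int(np.floor((ci_max - ci_min) / ci_step)) + 1
    return ci_min + ci_step * np.arange(n), float(ci_step)


def _grid_intervals(grid: np.ndarray, mask: np.ndarray):
    """Contiguous runs of True grid points as (lower, upper) intervals."""
    intervals = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return intervals
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((float(grid[start]), float(grid[prev])))
            start = i
        prev = i
    intervals.append((float(grid[start]), float(grid[prev])))
    return intervals


def _subset_sums(w: np.ndarray, wr: np.ndarray, wr2: np.ndarray):
    """Per-bitmask sums of w, w*r, w*r^2 over all 2^J variant subsets."""
    J = len(w)
    size = 1 << J
    sw = np.zeros(size)
    swr = np.zeros(size)
    swr2 = np.zeros(size)
    popcount = np.zeros(size, dtype=np.int64)
    for j in range(J):
        bit = 1 << j
        half = np.arange(size) & bit > 0
        sw[half] = sw[~half] + w[j]
        swr[half] = swr[~half] + wr[j]
        swr2[half] = swr2[~half] + wr2[j]
        popcount[half] = popcount[~half] + 1
    return sw, swr, swr2, popcount


def hetpen(data: MRInput, *, prior: float = 0.5, ci_min: float | None = None,
           ci_max: float | None = None, ci_step: float | None = None,
           alpha: float = 0.05, max_variants: int = 20,
           keep_components: bool = False) -> MREstimate:
    """Heterogeneity-penalized model averaging over variant subsets.

    Every subset S of >= 2 variants contributes a normal component centred
    at the subset IVW estimate with the subset IVW standard error, weighted
    by prior^|S| (1-prior)^(J-|S|) exp(-Q_S/2) where Q_S is the subset's
    heterogeneity statistic.  The averaged distribution is evaluated on a
    grid; the confidence set is the smallest set of grid points holding
    1-alpha of the normalized mass (possibly disjoint intervals), and the
    point estimate is the grid mode.

    Enumeration is 2^J, so J is capped (default 20).  ``keep_components``
    attaches the per-subset mixture components and the grid density to
    ``extra`` (for inspection; only sensible at small J).
    """
    J = data.n_variants
    if not 0 < prior < 1:
        raise ValidationError("prior must lie strictly between 0 and 1")
    if J < 3:
        raise ValidationError("hetpen requires at least 3 variants")
    if J > max_variants:
        raise ValidationError(
            f"hetpen enumerates 2^J subsets and is computationally infeasible "
            f"for J={J} > {max_variants}; consider conmix instead")
    rt = ratio_estimates(data, alpha)
    if not rt["defined"].all():
        raise ValidationError("hetpen requires bx != 0 for every variant")
    r = rt["ratio"].to_numpy()
    se = rt["se_second"].to_numpy()
    grid, step = _default_grid(r, se, ci_min, ci_max, ci_step)

    w = se ** -2.0
    sw, swr, swr2, pop = _subset_sums(w, w * r, w * r ** 2)
    keep = pop >= 2
    sw, swr, swr2, pop = sw[keep], swr[keep], swr2[keep], pop[keep]
    theta_s = swr / sw
    var_s = 1.0 / sw
    q_s = swr2 - swr ** 2 / sw
    logw = (pop * np.log(prior) + (J - pop) * np.log1p(-prior) - 0.5 * q_s)
    logw -= logw.max()
    weight = np.exp(logw)
    weight /= weight.sum()

    # mixture density on the grid, chunked over components
    dens = np.zeros_like(grid)
    order = np.argsort(weight)[::-1]
    cum = np.cumsum(weight[order])
    ncomp = int(np.searchsorted(cum, 1.0 - 1e-12) + 1)
    sel = order[:ncomp]
    for s0 in range(0, ncomp, 4096):
        idx = sel[s0:s0 + 4096]
        z = (grid[None, :] - theta_s[idx, None]) / np.sqrt(var_s[idx, None])
        dens += weight[idx] @ (np.exp(-0.5 * z ** 2)
                               / np.sqrt(2 * np.pi * var_s[idx, None]))
    mass = dens / dens.sum()
    if mass[0] > alpha / 2 or mass[-1] > alpha / 2:
        warnings.warn("substantial probability mass at the grid edge; "
                      "widen ci_min/ci_max")
    # highest-density grid set holding 1 - alpha of the mass
    dorder = np.argsort(dens)[::-1]
    cmass = np.cumsum(mass[dorder])
    ncover = int(np.searchsorted(cmass, 1.0 - alpha) + 1)
    mask = np.zeros_like(mass, dtype=bool)
    mask[dorder[:ncover]] = True
    intervals = _grid_intervals(grid, mask)
    theta = float(grid[np.argmax(dens)])
    mean = float(np.sum(mass * grid))
    sd = float(np.sqrt(np.sum(mass * (grid - mean) ** 2)))
    lo = min(i[0] for i in intervals)
    hi = max(i[1] for i in intervals)
    p_tail = 2 * min(float(np.sum(mass[grid <= 0])), float(np.sum(mass[grid >= 0])))
    extra = {"prior": prior, "ci_intervals": intervals, "ci_step": step,
             "n_components": ncomp}
    if keep_components:
        extra["component_means"] = theta_s
        extra["component_vars"] = var_s
        extra["component_sizes"] = pop
        extra["component_weights"] = weight
        extra["grid"] = grid
        extra["grid_mass"] = mass
    return MREstimate(method="hetpen", estimate=theta, std_error=sd,
                      ci_lower=lo, ci_upper=hi, p_value=min(1.0, p_tail),
                      alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name, extra=extra)


# --------------------------------------------------------------------------
# contamination mixture
# --------------------------------------------------------------------------


def _conmix_loglik(r, se, psi, thetas):
    """Profile log-likelihood over the grid plus per-variant valid/invalid
    log-densities (ties break to valid)."""
    thetas = np.atleast_1d(thetas)
    valid = stats.norm.logpdf(r[None, :], loc=thetas[:, None], scale=se[None, :])
    invalid = stats.norm.logpdf(r, loc=0.0, scale=np.sqrt(se ** 2 + psi ** 2))
    contrib = np.maximum(valid, invalid[None, :])
    return contrib.sum(axis=1), valid, invalid


def conmix(data: MRInput, *, psi: float = 0.0, ci_min: float | None = None,
           ci_max: float | None = None, ci_step: float | None = None,
           alpha: float = 0.05) -> MREstimate:
    """Contamination-mixture estimate.

    Each variant's ratio estimate is modelled as either valid (centred at
    the causal effect theta with its ratio SE) or invalid (centred at zero
    with SD sqrt(SE^2 + psi^2), psi the spread of invalid estimands).  The
    profile log-likelihood over theta takes the better classification per
    variant; the estimate is the grid argmax and the confidence set is the
    likelihood-ratio region against chi-square(1).  ``psi=0`` selects
    1.5 x SD of the ratio estimates.
    """
    J = data.n_variants
    if J < 3:
        raise ValidationError("conmix requires at least 3 variants")
    rt = ratio_estimates(data, alpha)
    if not rt["defined"].all():
        raise ValidationError("conmix requires bx != 0 for every variant")
    r = rt["ratio"].to_numpy()
    se = rt["se_first"].to_numpy()
    spread = float(np.std(r, ddof=1))
    if psi <= 0:
        psi = 1.5 * spread
    if psi <= 0 or np.ptp(r) < 1e-12 * max(1.0, np.max(np.abs(r))):
        logger.info("all ratio estimates coincide; conmix returns the common value")
        theta = float(np.mean(r))
        se_pool = float(1.0 / np.sqrt(np.sum(se ** -2.0)))
        lo, hi, p = confidence_interval(theta, se_pool, alpha, "normal")
        return MREstimate(method="conmix", estimate=theta, std_error=se_pool,
                          ci_lower=lo, ci_upper=hi, p_value=p, alpha=alpha,
                          n_variants=J, exposure_name=data.exposure_name,
                          outcome_name=data.outcome_name,
                          valid_variants=data.snps,
                          extra={"psi": psi, "ci_intervals": [(lo, hi)]})
    grid, step = _default_grid(r, se, ci_min, ci_max, ci_step)
    ll, valid, invalid = _conmix_loglik(r, se, psi, grid)
    imax = int(np.argmax(ll))
    theta = float(grid[imax])
    crit = stats.chi2.ppf(1 - alpha, 1)
    mask = 2 * (ll[imax] - ll) <= crit
    intervals = _grid_intervals(grid, mask)
    is_valid = valid[imax] >= invalid
    valid_snps = tuple(s for s, v in zip(data.snps, is_valid) if v)
    ll0 = _conmix_loglik(r, se, psi, np.array([0.0]))[0][0]
    p = float(stats.chi2.sf(2 * (ll[imax] - ll0), 1))
    hull_lo = min(i[0] for i in intervals)
    hull_hi = max(i[1] for i in intervals)
    # report a symmetric-interval-equivalent SE for the interval holding theta
    own = next((i for i in intervals if i[0] <= theta <= i[1]), intervals[0])
    z = stats.norm.ppf(1 - alpha / 2)
    se_eq = float((own[1] - own[0]) / (2 * z)) or step
    return MREstimate(method="conmix", estimate=theta, std_error=se_eq,
                      ci_lower=hull_lo, ci_upper=hull_hi, p_value=p,
                      alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      valid_variants=valid_snps,
                      extra={"psi": float(psi), "ci_intervals": intervals,
                             "ci_step": step,
                             "n_valid": int(is_valid.sum())})


# --------------------------------------------------------------------------
# lasso
# --------------------------------------------------------------------------


def _lasso_fit(bx, by, w, lam, alpha_start=None, theta_start=None,
               tol=1e-12, maxiter=20000):
    """Coordinate descent for min_theta,a sum_j w_j (by_j - a_j - theta bx_j)^2
    + lam sum_j |a_j|.  Closed-form updates: soft-thresholding for each a_j
    and weighted regression through the origin for theta."""
    a = np.zeros_like(by) if alpha_start is None else alpha_start.copy()
    theta = (np.sum(w * bx * by) / np.sum(w * bx ** 2)
             if theta_start is None else theta_start)
    denom = np.sum(w * bx ** 2)
    for _ in range(maxiter):
        resid = by - theta * bx
        thresh = lam / (2 * w)
        a_new = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0)
        theta_new = np.sum(w * bx * (by - a_new)) / denom
        if (np.max(np.abs(a_new - a)) < tol and abs(theta_new - theta) < tol):
            a, theta = a_new, theta_new
            break
        a, theta = a_new, theta_new
    return theta, a


def _fixed_ivw_q(bx, by, byse):
    w = byse ** -2.0
    theta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
    return float(np.sum(w * (by - theta * bx) ** 2))


def lasso(data: MRInput, *, lam: float = 0.0, distribution: str = "normal",
          alpha: float = 0.05) -> MREstimate:
    """L1-penalized per-variant intercepts with post-selection IVW.

    Minimizes sum_j w_j (by_j - a_j - theta bx_j)^2 + lambda sum_j |a_j|
    with w_j = byse_j^-2.  Variants with a_j shrunk exactly to zero form the
    valid set; the reported estimate is the IVW estimate on that set.
    ``lam=0`` selects lambda automatically by a heterogeneity stopping rule:
    descending a log-spaced path from the smallest lambda retaining all
    variants, stop at the first lambda whose valid set S is homogeneous
    (Q_S <= chi-square 95th percentile on |S|-1 df).
    """
    J = data.n_variants
    if J < 3:
        raise ValidationError("lasso requires at least 3 variants")
    w = data.byse ** -2.0
    bx, by = data.bx, data.by

    def valid_set(lam_val, a_start=None, t_start=None):
        theta, a = _lasso_fit(bx, by, w, lam_val, a_start, t_start)
        return a == 0.0, a, theta

    if lam > 0:
        keep, a, _ = valid_set(lam)
        lam_used = lam
    else:
        theta0 = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        lam_max = 2.0 * np.max(w * np.abs(by - theta0 * bx)) * (1 + 1e-10)
        keep = np.ones(J, dtype=bool)
        lam_used = lam_max
        a_start, t_start = None, None
        found = lam_max == 0.0  # perfect fit: nothing to penalize
        path = [] if found else np.geomspace(lam_max, lam_max * 1e-3, 100)
        for lam_val in path:
            keep_i, a_start, t_start = valid_set(lam_val, a_start, t_start)
            if keep_i.sum() < 2:
                break
            q = _fixed_ivw_q(bx[keep_i], by[keep_i], data.byse[keep_i])
            if q <= stats.chi2.ppf(0.95, int(keep_i.sum()) - 1):
                keep, lam_used, found = keep_i, float(lam_val), True
                break
        if not found:
            raise ValidationError(
                "no lambda on the path yields a homogeneous valid set of >= 2 "
                "variants; supply a larger lambda explicitly")
    if keep.sum() < 2:
        raise ValidationError(
            f"only {int(keep.sum())} variants retained at lambda={lam_used:g}; "
            "supply a larger lambda")
    from .core import make_input
    sub = make_input(bx[keep], data.bxse[keep], by[keep], data.byse[keep],
                     snps=[s for s, k in zip(data.snps, keep) if k],
                     exposure_name=data.exposure_name,
                     outcome_name=data.outcome_name)
    post = ivw(sub, distribution=distribution, alpha=alpha)
    return MREstimate(method="lasso", estimate=post.estimate,
                      std_error=post.std_error, ci_lower=post.ci_lower,
                      ci_upper=post.ci_upper, p_value=post.p_value,
                      alpha=alpha, n_variants=J,
                      exposure_name=data.exposure_name,
                      outcome_name=data.outcome_name,
                      heterogeneity=post.heterogeneity,
                      valid_variants=sub.snps,
                      extra={"lambda": float(lam_used),
                             "n_valid": int(keep.sum())})


# --------------------------------------------------------------------------
# heterogeneity statistics and run-all
# --------------------------------------------------------------------------


def heterogeneity(data: MRInput, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q (about the fixed-effect IVW fit, J-1 df) or Ruecker's Q
    (about the MR-Egger fit, J-2 df) with its upper chi-square tail p-value."""
    J = data.n_variants
    w = data.byse ** -2.0
    if method == "ivw":
        if J < 2:
            raise ValidationError("Cochran's Q requires at least 2 variants")
        theta = np.sum(w * data.bx * data.by) / np.sum(w * data.bx ** 2)
        q = float(np.sum(w * (data.by - theta * data.bx) ** 2))
        df = J - 1
    elif method == "egger":
        if J < 3:
            raise ValidationError("Ruecker's Q requires at least 3 variants")
        bx, by, _ = _orient(data)
        X = np.column_stack([np.ones(J), bx])
        beta, _, q = _wls(X, by, w)
        df = J - 2
    else:
        raise ValidationError(f"unknown heterogeneity method {method!r}")
    return HeterogeneityResult(float(q), df, float(stats.chi2.sf(q, df)))


METHOD_TOKENS = ("ivw", "median", "wmedian", "pmedian", "egger", "maxlik",
                 "mbe", "conmix")


def run_all(data: MRInput, methods=None, *, seed: int = 12345,
            iterations: int = 10000, alpha: float = 0.05,
            distribution: str = "normal") -> list[MREstimate]:
    """Run a panel of univariable estimators with default options.

    ``methods`` is a list of tokens from ``METHOD_TOKENS`` (default: all).
    Methods whose preconditions fail on this dataset are skipped with a
    logged reason.
    """
    if methods is None:
        methods = list(METHOD_TOKENS)
    if not methods:
        raise ValidationError("methods list must not be empty")
    unknown = [m for m in methods if m not in METHOD_TOKENS]
    if unknown:
        raise ValidationError(
            f"unknown method token(s) {unknown}; valid tokens: {METHOD_TOKENS}")
    runners = {
        "ivw": lambda: ivw(data, distribution=distribution, alpha=alpha),
        "median": lambda: median(data, method="simple", iterations=iterations,
                                 seed=seed, distribution=distribution, alpha=alpha),
        "wmedian": lambda: median(data, method="weighted", iterations=iterations,
                                  seed=seed, distribution=distribution, alpha=alpha),
        "pmedian": lambda: median(data, method="penalized", iterations=iterations,
                                  seed=seed, distribution=distribution, alpha=alpha),
        "egger": lambda: egger(data, distribution=distribution, alpha=alpha),
        "maxlik": lambda: maxlik(data, distribution=distribution, alpha=alpha),
        "mbe": lambda: mbe(data, iterations=iterations, seed=seed,
                           distribution=distribution, alpha=alpha),
        "conmix": lambda: conmix(data, alpha=alpha),
    }
    out = []
    for token in methods:
        try:
            out.append(runners[token]())
        except ValidationError as exc:
            logger.warning("skipping %s: %s", token, exc)
    return out
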