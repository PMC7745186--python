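"""Data containers, validation, and shared numerics for summarized-data MR.

Summarized data are per-variant beta-coefficients and standard errors from
univariate regressions of a risk factor (``bx``, ``bxse``) and an outcome
(``by``, ``byse``) on each genetic variant in turn, as reported by GWAS
consortia.  All estimators in this package consume an :class:`MRInput`
(one risk factor) or :class:`MRMVInput` (several risk factors) built from
such data, optionally together with a variant-variant correlation (LD)
matrix estimated from reference data.

Association estimates are assumed to be pre-harmonized to common effect
alleles.  The one harmonization helper provided is
:func:`flip_correlation`, which flips the sign of rows/columns of an LD
matrix computed with effect and reference alleles reversed for some
variants.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrsum")

__all__ = [
    "ValidationError",
    "DimensionError",
    "IdentifiabilityError",
    "MRInput",
    "MRMVInput",
    "HeterogeneityResult",
    "InterceptResult",
    "MREstimate",
    "make_input",
    "make_mvinput",
    "flip_correlation",
    "ratio_estimates",
    "confidence_interval",
    "read_summary_csv",
    "read_mv_summary_csv",
    "read_correlation_csv",
    "write_summary_csv",
    "write_estimate",
]


class ValidationError(ValueError):
    """Input fails a validity requirement (non-positive SE, bad matrix, ...)."""


class DimensionError(ValidationError):
    """Fields have inconsistent lengths or shapes."""


class IdentifiabilityError(ValidationError):
    """The model cannot be identified from the data provided (e.g. J <= K)."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MRInput:
    """Univariable summarized dataset: J variants, one risk factor.

    Build with :func:`make_input` (which validates) rather than directly.
    """

    snps: tuple[str, ...]
    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    correlation: np.ndarray | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    @property
    def n_variants(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class MRMVInput:
    """Multivariable summarized dataset: J variants, K risk factors.

    ``bx`` and ``bxse`` are J x K; a causal effect is estimated per
    risk factor, assuming every causal path from variant to outcome
    passes through one of the K risk factors.
    """

    snps: tuple[str, ...]
    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    correlation: np.ndarray | None = None
    exposure_names: tuple[str, ...] = ()
    outcome_name: str = "outcome"

    @property
    def n_variants(self) -> int:
        return len(self.snps)

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's (IVW) or Ruecker's (Egger) heterogeneity statistic."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class InterceptResult:
    """Intercept term of an Egger-type fit: the average pleiotropic effect."""

    estimate: float
    std_error: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class MREstimate:
    """Result of a univariable estimator.

    ``ci_lower``/``ci_upper`` always hold a single interval; methods whose
    confidence set may consist of several disjoint intervals (contamination
    mixture, heterogeneity-penalized) store the full list under
    ``extra["ci_intervals"]`` and report the hull here.
    """

    method: str
    estimate: float
    std_error: float
    ci_lower: float
    ci_upper: float
    p_value: float
    alpha: float
    n_variants: int
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    heterogeneity: HeterogeneityResult | None = None
    intercept: InterceptResult | None = None
    valid_variants: tuple[str, ...] | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "estimate": self.estimate,
            "std_error": self.std_error,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "n_variants": self.n_variants,
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
        }
        if self.heterogeneity is not None:
            out["heterogeneity_stat"] = self.heterogeneity.statistic
            out["heterogeneity_df"] = self.heterogeneity.df
            out["heterogeneity_p"] = self.heterogeneity.p_value
        if self.intercept is not None:
            out["intercept"] = self.intercept.estimate
            out["intercept_se"] = self.intercept.std_error
            out["intercept_ci_lower"] = self.intercept.ci_lower
            out["intercept_ci_upper"] = self.intercept.ci_upper
            out["intercept_p"] = self.intercept.p_value
        if self.valid_variants is not None:
            out["valid_variants"] = list(self.valid_variants)
        for key, val in self.extra.items():
            if isinstance(val, (int, float, str, bool)) or val is None:
                out[key] = val
            elif isinstance(val, (list, tuple)):
                out[key] = [list(v) if isinstance(v, (list, tuple)) else v for v in val]
        return out


# --------------------------------------------------------------------------
# construction and validation
# --------------------------------------------------------------------------


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values (NaN/inf); "
                              "remove or impute these rows before analysis")
    return arr


def _validate_correlation(correlation, n: int) -> np.ndarray:
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (n, n):
        raise DimensionError(
            f"correlation must be {n}x{n} to match the {n} variants, got {corr.shape}")
    if not np.all(np.isfinite(corr)):
        raise ValidationError("correlation contains non-finite values")
    if np.max(np.abs(corr - corr.T)) > 1e-8:
        raise ValidationError("correlation matrix is not symmetric (tolerance 1e-8)")
    if not np.all(np.diag(corr) == 1.0):
        raise ValidationError("correlation matrix diagonal entries must all equal 1")
    if np.any(np.abs(corr) > 1.0 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    return 0.5 * (corr + corr.T)


def make_input(bx, bxse, by, byse, snps: Sequence[str] | None = None,
               correlation=None, exposure_name: str = "exposure",
               outcome_name: str = "outcome") -> MRInput:
    """Validate and assemble a univariable summarized dataset.

    Parameters
    ----------
    bx, bxse
        Per-variant associations with the risk factor and their standard
        errors (all SEs strictly positive).
    by, byse
        Per-variant associations with the outcome (beta or log odds ratio)
        and their standard errors.
    snps
        Variant identifiers; auto-labelled ``snp_1 ... snp_J`` if omitted.
    correlation
        Optional J x J variant correlation (LD) matrix, aligned and
        allele-harmonized to the association estimates.
    """
    bx = _as_vector(bx, "bx")
    bxse = _as_vector(bxse, "bxse")
    by = _as_vector(by, "by")
    byse = _as_vector(byse, "byse")
    n = len(bx)
    if n < 1:
        raise ValidationError("at least one variant is required")
    for name, arr in (("bxse", bxse), ("by", by), ("byse", byse)):
        if len(arr) != n:
            raise DimensionError(
                f"{name} has length {len(arr)} but bx has length {n}")
    if np.any(bxse <= 0):
        raise ValidationError("all bxse must be strictly positive")
    if np.any(byse <= 0):
        raise ValidationError("all byse must be strictly positive")
    if snps is None:
        snps = tuple(f"snp_{i + 1}" for i in range(n))
    else:
        snps = tuple(str(s) for s in snps)
        if len(snps) != n:
            raise DimensionError(f"snps has length {len(snps)} but bx has length {n}")
    corr = None if correlation is None else _validate_correlation(correlation, n)
    return MRInput(snps=snps, bx=bx, bxse=bxse, by=by, byse=byse,
                   correlation=corr, exposure_name=exposure_name,
                   outcome_name=outcome_name)


def make_mvinput(bx, bxse, by, byse, snps: Sequence[str] | None = None,
                 correlation=None, exposure_names: Sequence[str] | None = None,
                 outcome_name: str = "outcome") -> MRMVInput:
    """Validate and assemble a multivariable summarized dataset (J x K)."""
    bx = np.asarray(bx, dtype=float)
    bxse = np.asarray(bxse, dtype=float)
    if bx.ndim != 2:
        raise DimensionError(f"bx must be a J x K matrix, got shape {bx.shape}")
    if bxse.shape != bx.shape:
        raise DimensionError(
            f"bxse shape {bxse.shape} does not match bx shape {bx.shape}")
    if not (np.all(np.isfinite(bx)) and np.all(np.isfinite(bxse))):
        raise ValidationError("bx/bxse contain non-finite values")
    n, k = bx.shape
    if n <= k:
        raise IdentifiabilityError(
            f"need more variants than risk factors (J={n}, K={k})")
    by = _as_vector(by, "by")
    byse = _as_vector(byse, "byse")
    if len(by) != n or len(byse) != n:
        raise DimensionError("by/byse lengths must match the number of bx rows")
    if np.any(bxse <= 0) or np.any(byse <= 0):
        raise ValidationError("all standard errors must be strictly positive")
    if snps is None:
        snps = tuple(f"snp_{i + 1}" for i in range(n))
    else:
        snps = tuple(str(s) for s in snps)
        if len(snps) != n:
            raise DimensionError("snps length must match the number of bx rows")
    if exposure_names is None:
        exposure_names = tuple(f"exposure_{j + 1}" for j in range(k))
    else:
        exposure_names = tuple(str(s) for s in exposure_names)
        if len(exposure_names) != k:
            raise DimensionError("exposure_names length must equal K")
    corr = None if correlation is None else _validate_correlation(correlation, n)
    return MRMVInput(snps=snps, bx=bx, bxse=bxse, by=by, byse=byse,
                     correlation=corr, exposure_names=exposure_names,
                     outcome_name=outcome_name)


def flip_correlation(correlation, flip_indices: Sequence[int]) -> np.ndarray:
    """Flip the sign of rows/columns of an LD matrix for re-oriented variants.

    When a correlation matrix was computed with effect and reference alleles
    reversed for some variants, the signs of the corresponding row and
    column must be flipped, keeping the diagonal at +1.  Applying the same
    flip twice restores the original matrix.

    Indices are zero-based.
    """
    corr = np.asarray(correlation, dtype=float)
    corr = _validate_correlation(corr, corr.shape[0])
    n = corr.shape[0]
    sign = np.ones(n)
    for i in flip_indices:
        i = int(i)
        if not 0 <= i < n:
            raise IndexError(f"flip index {i} out of range for {n} variants")
        sign[i] = -sign[i]
    out = sign[:, None] * corr * sign[None, :]
    np.fill_diagonal(out, 1.0)
    return out


# --------------------------------------------------------------------------
# per-variant ratio estimates and CI machinery
# --------------------------------------------------------------------------


def ratio_estimates(data: MRInput, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variant causal (Wald ratio) estimates by/bx with delta-method SEs.

    Returns a DataFrame with columns ``snp, ratio, se_first, se_second,
    ci_lower, ci_upper, defined``.  The first-order SE is byse/|bx|; the
    second-order SE additionally propagates the uncertainty in bx:
    sqrt(byse^2/bx^2 + by^2 bxse^2 / bx^4).  Variants with bx = 0 have an
    undefined ratio and are flagged (``defined=False``) rather than raising;
    plotting functions drop them with a warning.  Confidence intervals use
    the first-order SE and normal quantiles.
    """
    bx, by = data.bx, data.by
    defined = bx != 0
    if not np.all(defined):
        bad = [s for s, d in zip(data.snps, defined) if not d]
        warnings.warn(f"ratio undefined for variants with bx=0: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, by / np.where(defined, bx, 1.0), np.nan)
        se1 = np.where(defined, data.byse / np.abs(np.where(defined, bx, 1.0)), np.nan)
        se2 = np.where(
            defined,
            np.sqrt(data.byse ** 2 / np.where(defined, bx, 1.0) ** 2
                    + by ** 2 * data.bxse ** 2 / np.where(defined, bx, 1.0) ** 4),
            np.nan)
    z = stats.norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "snp": list(data.snps),
        "ratio": ratio,
        "se_first": se1,
        "se_second": se2,
        "ci_lower": ratio - z * se1,
        "ci_upper": ratio + z * se1,
        "defined": defined,
    })


def confidence_interval(estimate: float, se: float, alpha: float = 0.05,
                        distribution: str = "normal",
                        df: int | None = None) -> tuple[float, float, float]:
    """Two-sided CI at level 1-alpha and two-sided p-value against zero.

    ``distribution`` is ``"normal"`` or ``"t"`` (alias ``"t-dist"``); the
    t-distribution requires ``df`` > 0.
    """
    if se <= 0:
        raise ValidationError("standard error must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    dist = {"t-dist": "t"}.get(distribution, distribution)
    if dist == "normal":
        q = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(estimate) / se)
    elif dist == "t":
        if df is None or df <= 0:
            raise ValidationError("t-distribution requires df > 0")
        q = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(estimate) / se, df)
    else:
        raise ValidationError(f"unknown distribution {distribution!r}; "
                              "use 'normal' or 't-dist'")
    return estimate - q * se, estimate + q * se, float(p)


# --------------------------------------------------------------------------
# generalized least squares support for correlated variants
# --------------------------------------------------------------------------


def outcome_covariance(byse: np.ndarray, correlation: np.ndarray) -> np.ndarray:
    """Covariance of outcome association estimates under the assumption that
    correlations between association estimates equal the variant (LD)
    correlations: Omega_ij = byse_i byse_j rho_ij."""
    return np.outer(byse, byse) * correlation


def solve_spd(omega: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve omega @ x = b for a (near) positive-definite covariance.

    A 1e-8 ridge is added if the Cholesky factorization fails (near-singular
    LD), with a logged warning.
    """
    from scipy.linalg import cho_factor, cho_solve

    try:
        factor = cho_factor(omega)
    except np.linalg.LinAlgError:
        logger.warning("covariance matrix is near-singular; adding 1e-8 ridge")
        factor = cho_factor(omega + 1e-8 * np.eye(omega.shape[0]))
    return cho_solve(factor, b)


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------

_REQUIRED_COLS = ("snp", "bx", "bxse", "by", "byse")


def _coerce_numeric(frame: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValidationError(f"{path}: missing value in column {col!r} at data row {row}")
        frame[col] = coerced
    return frame


def read_summary_csv(path, column_map: Mapping[str, str] | None = None,
                     exposure_name: str = "exposure",
                     outcome_name: str = "outcome") -> MRInput:
    """Read a univariable summarized dataset from delimited text.

    Expects a header with columns ``snp, bx, bxse, by, byse``; arbitrary
    GWAS export headers can be adapted via ``column_map`` mapping canonical
    names to the file's column names, e.g. ``{"bx": "beta_exposure"}``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    frame = _coerce_numeric(frame, ["bx", "bxse", "by", "byse"], path)
    return make_input(frame["bx"], frame["bxse"], frame["by"], frame["byse"],
                      snps=frame["snp"].astype(str).tolist(),
                      exposure_name=exposure_name, outcome_name=outcome_name)


def read_mv_summary_csv(path, exposure_names: Sequence[str] | None = None,
                        outcome_name: str = "outcome") -> MRMVInput:
    """Read a multivariable summarized dataset from delimited text.

    Expects columns ``snp, by, byse`` plus numbered pairs ``bx1, bxse1,
    bx2, bxse2, ...`` (one pair per risk factor, in order).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("snp", "by", "byse"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    ks = sorted(int(m.group(1)) for c in frame.columns
                if (m := re.fullmatch(r"bx(\d+)", c)))
    if not ks or ks != list(range(1, len(ks) + 1)):
        raise ValidationError(
            f"{path}: expected consecutive bx1, bx2, ... columns, found {ks}")
    bx_cols = [f"bx{k}" for k in ks]
    bxse_cols = [f"bxse{k}" for k in ks]
    missing = [c for c in bxse_cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    frame = _coerce_numeric(frame, bx_cols + bxse_cols + ["by", "byse"], path)
    return make_mvinput(frame[bx_cols].to_numpy(), frame[bxse_cols].to_numpy(),
                        frame["by"], frame["byse"],
                        snps=frame["snp"].astype(str).tolist(),
                        exposure_names=exposure_names, outcome_name=outcome_name)


def read_correlation_csv(path, snp_order: Sequence[str]) -> np.ndarray:
    """Read a labelled square correlation matrix, reordered to ``snp_order``.

    The file must have an identifier header row and first column; its
    identifiers must be a superset of ``snp_order``.
    """
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    missing = [s for s in snp_order if s not in frame.index or s not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: correlation matrix lacks identifiers {missing}")
    reordered = frame.loc[list(snp_order), list(snp_order)].to_numpy(dtype=float)
    return _validate_correlation(reordered, len(snp_order))


def write_summary_csv(data: MRInput | MRMVInput, path) -> None:
    """Write a summarized dataset in the schema read_*_summary_csv expects."""
    if isinstance(data, MRMVInput):
        cols = {"snp": list(data.snps)}
        for k in range(data.n_exposures):
            cols[f"bx{k + 1}"] = data.bx[:, k]
            cols[f"bxse{k + 1}"] = data.bxse[:, k]
        cols["by"] = data.by
        cols["byse"] = data.byse
    else:
        cols = {"snp": list(data.snps), "bx": data.bx, "bxse": data.bxse,
                "by": data.by, "byse": data.byse}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_correlation_csv(correlation: np.ndarray, snps: Sequence[str], path) -> None:
    pd.DataFrame(correlation, index=list(snps), columns=list(snps)).to_csv(
        path, float_format="%.17g")


def write_estimate(estimate, path, fmt: str | None = None) -> None:
    """Serialize one estimate (or a list) as JSON or CSV by extension."""
    records = estimate if isinstance(estimate, (list, tuple)) else [estimate]
    rows = [r.to_dict() for r in records]
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "json"
    if fmt == "json":
        payload = rows[0] if not isinstance(estimate, (list, tuple)) else rows
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
    elif fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown output format {fmt!r}")
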