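"""Synthetic summarized-data generator and benchmarking harness.

The generator emulates the data regime of a typical two-sample MR analysis
of tens of independent variants (e.g. a lipid-fraction panel of ~28
variants): instrument effects of order 0.1-0.5, association SEs of order
0.01-0.1, an optional exchangeable cross-variant correlation, and four
pleiotropy regimes:

* ``none`` — every variant is a valid instrument;
* ``balanced`` — direct effects with mean zero;
* ``directional`` — direct effects of one sign (biases IVW, leaves the
  MR-Egger intercept with the planted sign);
* ``inside_violating`` — direct effects correlated with instrument
  strength, breaking the InSIDE assumption that MR-Egger requires.

Outcome associations are drawn as by_j ~ N(theta bx_j + alpha_j, byse_j),
with the realized bx_j playing the role of the true instrument effect, so
estimates based on the reported associations are exactly unbiased under
no pleiotropy.  Reported bxse are of the same scale as byse so estimators
that model uncertainty in bx are exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import MRInput, MRMVInput, ValidationError, make_input, make_mvinput

__all__ = ["SimScenario", "simulate_summary_data", "benchmark"]

_PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")


@dataclass
class SimScenario:
    """Generative parameters for a synthetic summarized dataset.

    ``theta`` may be a scalar (univariable) or a length-K sequence
    (multivariable).  ``prop_invalid`` is the fraction of variants given a
    direct (pleiotropic) effect on the outcome; ``pleiotropy_sd`` is the
    spread of those effects.  ``bx_mean``/``bx_sd`` set the instrument
    strength distribution (|Normal| by default; ``signed_bx`` disables the
    folding).  ``se_scale`` sets the magnitude of both association SEs
    (each jittered uniformly by +-20%).  ``correlation`` adds an
    exchangeable cross-variant correlation to the outcome noise and
    attaches the matrix to the dataset.
    """

    J: int = 28
    theta: float | tuple = 0.5
    prop_invalid: float = 0.0
    pleiotropy: str = "none"
    pleiotropy_sd: float = 0.1
    bx_mean: float = 0.3
    bx_sd: float = 0.1
    se_scale: float = 0.05
    correlation: float | None = None
    signed_bx: bool = False
    seed: int = 0
    exposure_names: tuple = ()

    def validate(self) -> None:
        if self.J < 1:
            raise ValidationError("J must be at least 1")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValidationError("prop_invalid must lie in [0, 1]")
        if self.pleiotropy not in _PLEIOTROPY_REGIMES:
            raise ValidationError(
                f"unknown pleiotropy regime {self.pleiotropy!r}; "
                f"choose from {_PLEIOTROPY_REGIMES}")
        if self.se_scale <= 0:
            raise ValidationError("se_scale must be positive")
        if self.correlation is not None and not -1.0 < self.correlation < 1.0:
            raise ValidationError("exchangeable correlation must lie in (-1, 1)")

    @classmethod
    def from_config(cls, path) -> "SimScenario":
        """Load a scenario from a JSON or YAML config file."""
        text = open(path).read()
        try:
            payload = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            payload = yaml.safe_load(text)
        if isinstance(payload.get("theta"), list):
            payload["theta"] = tuple(payload["theta"])
        return cls(**payload)


def _direct_effects(rng, scenario: SimScenario, bx_ref: np.ndarray) -> np.ndarray:
    J = scenario.J
    n_invalid = int(round(scenario.prop_invalid * J))
    alpha = np.zeros(J)
    if scenario.pleiotropy == "none" or n_invalid == 0:
        return alpha
    which = rng.choice(J, size=n_invalid, replace=False)
    sd = scenario.pleiotropy_sd
    if scenario.pleiotropy == "balanced":
        alpha[which] = rng.normal(0.0, sd, size=n_invalid)
    elif scenario.pleiotropy == "directional":
        alpha[which] = np.abs(rng.normal(0.0, sd, size=n_invalid))
    else:  # inside_violating: direct effect tracks instrument strength
        alpha[which] = (0.5 * sd * bx_ref[which] / scenario.bx_mean
                        + rng.normal(0.0, 0.25 * sd, size=n_invalid))
    return alpha


def _correlated_noise(rng, byse: np.ndarray, rho: float) -> np.ndarray:
    J = len(byse)
    corr = np.full((J, J), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    return byse * (chol @ rng.standard_normal(J))


def simulate_summary_data(scenario: SimScenario) -> MRInput | MRMVInput:
    """Generate one synthetic summarized dataset, reproducible under
    ``scenario.seed``."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    J = scenario.J
    theta = scenario.theta
    multivariable = isinstance(theta, (tuple, list, np.ndarray))

    def draw_bx(size):
        raw = rng.normal(scenario.bx_mean, scenario.bx_sd, size=size)
        return raw if scenario.signed_bx else np.abs(raw)

    def draw_se(size):
        return scenario.se_scale * rng.uniform(0.8, 1.2, size=size)

    if multivariable:
        theta = np.asarray(theta, dtype=float)
        K = len(theta)
        if J <= K:
            raise ValidationError("J must exceed the number of risk factors")
        bx = draw_bx((J, K))
        bxse = draw_se((J, K))
        mean_by = bx @ theta
    else:
        bx = draw_bx(J)
        bxse = draw_se(J)
        mean_by = theta * bx

    bx_ref = bx[:, 0] if multivariable else bx
    alpha = _direct_effects(rng, scenario, bx_ref)
    byse = draw_se(J)
    if scenario.correlation is not None:
        noise = _correlated_noise(rng, byse, scenario.correlation)
        corr = np.full((J, J), float(scenario.correlation))
        np.fill_diagonal(corr, 1.0)
    else:
        noise = byse * rng.standard_normal(J)
        corr = None
    by = mean_by + alpha + noise

    if multivariable:
        names = scenario.exposure_names or None
        return make_mvinput(bx, bxse, by, byse, correlation=corr,
                            exposure_names=names)
    return make_input(bx, bxse, by, byse, correlation=corr)


# --------------------------------------------------------------------------
# benchmark harness
# --------------------------------------------------------------------------


def _method_runner(token: str, iterations: int):
    from . import univariable as uv

    def run(data, seed, alpha):
        if token == "ivw":
            return uv.ivw(data, alpha=alpha)
        if token == "egger":
            return uv.egger(data, alpha=alpha)
        if token == "median":
            return uv.median(data, method="simple", iterations=iterations,
                             seed=seed, alpha=alpha)
        if token == "wmedian":
            return uv.median(data, method="weighted", iterations=iterations,
                             seed=seed, alpha=alpha)
        if token == "pmedian":
            return uv.median(data, method="penalized", iterations=iterations,
                             seed=seed, alpha=alpha)
        if token == "maxlik":
            return uv.maxlik(data, alpha=alpha)
        if token == "mbe":
            return uv.mbe(data, iterations=iterations, seed=seed, alpha=alpha)
        if token == "conmix":
            return uv.conmix(data, alpha=alpha)
        if token == "lasso":
            return uv.lasso(data, alpha=alpha)
        raise ValidationError(f"unknown benchmark method {token!r}")
    return run


def benchmark(methods, scenario: SimScenario, n_reps: int,
              alpha: float = 0.05, iterations: int = 1000) -> pd.DataFrame:
    """Monte-Carlo comparison of estimators under one scenario.

    For each method: mean estimate, empirical SD, mean reported SE, bias,
    RMSE, CI coverage of the true effect, and the rejection rate of the
    theta=0 test at ``alpha``.  Replicates draw fresh datasets from
    independent streams spawned from ``scenario.seed``; method
    precondition failures are counted, not fatal.  ``iterations`` is the
    bootstrap size used by bootstrap-based methods (kept moderate here
    because it is repeated n_reps times).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    scenario.validate()
    theta = scenario.theta
    if isinstance(theta, (tuple, list, np.ndarray)):
        raise ValidationError("benchmark supports univariable scenarios only")
    seeds = np.random.SeedSequence(scenario.seed).spawn(n_reps)
    runners = {m: _method_runner(m, iterations) for m in methods}
    results = {m: {"est": [], "se": [], "cover": [], "reject": [], "fail": 0}
               for m in methods}
    for rep, seq in enumerate(seeds):
        child = np.random.default_rng(seq)
        rep_scenario = SimScenario(**{**asdict(scenario),
                                      "seed": int(child.integers(2 ** 31))})
        data = simulate_summary_data(rep_scenario)
        boot_seed = int(child.integers(2 ** 31))
        for m in methods:
            try:
                est = runners[m](data, boot_seed, alpha)
            except (ValidationError, RuntimeError):
                results[m]["fail"] += 1
                continue
            results[m]["est"].append(est.estimate)
            results[m]["se"].append(est.std_error)
            intervals = est.extra.get("ci_intervals",
                                      [(est.ci_lower, est.ci_upper)])
            results[m]["cover"].append(
                any(lo <= theta <= hi for lo, hi in intervals))
            results[m]["reject"].append(est.p_value < alpha)
    rows = []
    for m in methods:
        res = results[m]
        est = np.asarray(res["est"], dtype=float)
        n_ok = len(est)
        row = {"method": m, "n_reps": n_reps, "n_success": n_ok,
               "n_failed": res["fail"]}
        if n_ok:
            row.update({
                "mean_estimate": float(est.mean()),
                "sd_estimate": float(est.std(ddof=1)) if n_ok > 1 else 0.0,
                "mean_se": float(np.mean(res["se"])),
                "bias": float(est.mean() - theta),
                "rmse": float(np.sqrt(np.mean((est - theta) ** 2))),
                "coverage": float(np.mean(res["cover"])),
                "rejection_rate": float(np.mean(res["reject"])),
            })
        rows.append(row)
    return pd.DataFrame(rows)
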