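"""Univariable estimators against independent oracles and known limits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mrsum as mr
from mrsum.core import ValidationError
from tests.conftest import random_dataset


# --------------------------------------------------------------------------
# independent oracles (direct arithmetic, no shared code with the package)
# --------------------------------------------------------------------------


def ivw_oracle(bx, by, byse):
    """Closed-form weighted ratio of sums for the zero-intercept fit."""
    w = 1.0 / byse ** 2
    theta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
    se = 1.0 / np.sqrt(np.sum(w * bx ** 2))
    q = np.sum(w * (by - theta * bx) ** 2)
    return theta, se, q


def egger_oracle(bx, by, byse):
    """Normal equations for the weighted fit with intercept, solved directly,
    after orienting each variant so bx >= 0."""
    s = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * s, by * s
    w = 1.0 / byse ** 2
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx ** 2
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    q = np.sum(w * (y - intercept - slope * x) ** 2)
    cov = np.array([[swx2, -swx], [-swx, sw]]) / det
    return intercept, slope, np.sqrt(np.diag(cov)), q


def weighted_quantile_oracle(values, weights, q=0.5):
    """Interpolated weighted quantile evaluated directly."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    csum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(q, csum, v))


# --------------------------------------------------------------------------
# IVW
# --------------------------------------------------------------------------


class TestIVW:
    def test_exact_proportionality(self, exact_data):
        est = mr.ivw(exact_data)
        assert est.estimate == pytest.approx(0.5, abs=1e-12)
        assert est.heterogeneity.statistic == pytest.approx(0.0, abs=1e-18)

    def test_single_variant_equals_ratio(self):
        d = mr.make_input([2.0], [0.1], [1.0], [0.2])
        assert mr.ivw(d).estimate == pytest.approx(0.5)

    def test_weighted_ratio_of_sums(self):
        d = mr.make_input([0.4, 0.6, 0.5], [0.01] * 3, [0.2, 0.4, 0.2],
                          [0.1, 0.1, 0.1])
        assert mr.ivw(d).estimate == pytest.approx(0.42 / 0.77, abs=1e-12)

    def test_identity_correlation_reduces_to_wls(self, clean_data):
        d = mr.make_input(clean_data.bx, clean_data.bxse, clean_data.by,
                          clean_data.byse, correlation=np.eye(10))
        plain = mr.ivw(clean_data)
        gls = mr.ivw(d, correl=True)
        assert gls.estimate == pytest.approx(plain.estimate, abs=1e-12)
        assert gls.std_error == pytest.approx(plain.std_error, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equation_oracle(self, seed):
        d = random_dataset(seed, J=int(5 + seed % 20))
        est = mr.ivw(d, model="fixed")
        theta, se, q = ivw_oracle(d.bx, d.by, d.byse)
        assert est.estimate == pytest.approx(theta, abs=1e-10)
        assert est.std_error == pytest.approx(se, abs=1e-10)
        assert est.heterogeneity.statistic == pytest.approx(q, abs=1e-8)

    def test_random_effects_inflates_se_only_when_overdispersed(self):
        d = random_dataset(3, J=12)
        fixed = mr.ivw(d, model="fixed")
        random_ = mr.ivw(d, model="random")
        q = fixed.heterogeneity.statistic
        factor = max(1.0, np.sqrt(q / 11))
        assert random_.std_error == pytest.approx(fixed.std_error * factor)
        assert random_.estimate == fixed.estimate

    def test_gls_with_correlated_variants_matches_direct_solve(self):
        rng = np.random.default_rng(11)
        J = 8
        corr = np.full((J, J), 0.4)
        np.fill_diagonal(corr, 1.0)
        d = random_dataset(11, J=J)
        d = mr.make_input(d.bx, d.bxse, d.by, d.byse, correlation=corr)
        est = mr.ivw(d, model="fixed", correl=True)
        omega = np.outer(d.byse, d.byse) * corr
        oinv = np.linalg.inv(omega)
        theta = (d.bx @ oinv @ d.by) / (d.bx @ oinv @ d.bx)
        se = 1.0 / np.sqrt(d.bx @ oinv @ d.bx)
        assert est.estimate == pytest.approx(theta, abs=1e-10)
        assert est.std_error == pytest.approx(se, abs=1e-10)

    def test_robust_and_correl_mutually_exclusive(self, clean_data):
        d = mr.make_input(clean_data.bx, clean_data.bxse, clean_data.by,
                          clean_data.byse, correlation=np.eye(10))
        with pytest.raises(ValidationError):
            mr.ivw(d, robust=True, correl=True)
        with pytest.raises(ValidationError):
            mr.ivw(d, penalized=True, correl=True)

    def test_robust_downweights_gross_outlier(self):
        d = random_dataset(5, J=12)
        by = d.by.copy()
        by[0] += 3.0  # gross outlier
        dd = mr.make_input(d.bx, d.bxse, by, d.byse)
        plain = mr.ivw(dd).estimate
        rob = mr.ivw(dd, robust=True).estimate
        clean = mr.ivw(d).estimate
        assert abs(rob - clean) < abs(plain - clean)

    def test_penalized_weights_recover_from_outlier(self):
        d = random_dataset(6, J=12)
        by = d.by.copy()
        by[0] += 2.0
        dd = mr.make_input(d.bx, d.bxse, by, d.byse)
        plain = mr.ivw(dd).estimate
        pen = mr.ivw(dd, penalized=True).estimate
        clean = mr.ivw(d).estimate
        assert abs(pen - clean) < abs(plain - clean)


# --------------------------------------------------------------------------
# MR-Egger
# --------------------------------------------------------------------------


class TestEgger:
    def test_exact_affine_data(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        d = mr.make_input(bx, [0.01] * 4, 0.1 + 0.5 * bx, [0.02] * 4)
        est = mr.egger(d)
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
        assert est.intercept.estimate == pytest.approx(0.1, abs=1e-10)
        assert est.heterogeneity.statistic == pytest.approx(0.0, abs=1e-16)

    def test_orientation_invariance(self, clean_data):
        flip = np.ones(10)
        flip[[1, 4, 7]] = -1.0
        d2 = mr.make_input(clean_data.bx * flip, clean_data.bxse,
                           clean_data.by * flip, clean_data.byse)
        a, b = mr.egger(clean_data), mr.egger(d2)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.intercept.estimate == pytest.approx(b.intercept.estimate,
                                                     abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equation_oracle(self, seed):
        d = random_dataset(100 + seed, J=10)
        est = mr.egger(d)
        intercept, slope, ses, q = egger_oracle(d.bx, d.by, d.byse)
        phi = max(1.0, np.sqrt(q / 8))
        assert est.estimate == pytest.approx(slope, abs=1e-10)
        assert est.intercept.estimate == pytest.approx(intercept, abs=1e-10)
        assert est.std_error == pytest.approx(ses[1] * phi, abs=1e-10)
        assert est.heterogeneity.statistic == pytest.approx(q, abs=1e-8)

    def test_underidentified(self):
        d = mr.make_input([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValidationError):
            mr.egger(d)


# --------------------------------------------------------------------------
# median methods
# --------------------------------------------------------------------------


class TestMedian:
    def test_equal_weights_reduce_to_simple_median(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.4, 0.5, 0.6])
        d = mr.make_input(bx, [0.01] * 3, by, [0.1] * 3)
        simple = mr.median(d, method="simple", seed=1, iterations=100)
        weighted = mr.median(d, method="weighted", seed=1, iterations=100)
        assert simple.estimate == pytest.approx(0.5)
        assert weighted.estimate == pytest.approx(0.5)

    def test_identical_ratios_small_positive_se(self):
        bx = np.array([0.2, 0.3, 0.4])
        d = mr.make_input(bx, [1e-4] * 3, 0.7 * bx, [1e-4] * 3)
        est = mr.median(d, method="weighted", seed=2, iterations=500)
        assert est.estimate == pytest.approx(0.7, abs=1e-10)
        assert 0 < est.std_error < 0.01

    def test_concentrated_weight_pulls_to_that_variant(self):
        # ~90% of the weight on the third variant
        bx = np.array([0.1, 0.1, 1.0, 0.1, 0.1])
        byse = np.array([0.1, 0.1, 0.06, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.8, 0.11, 0.12])
        d = mr.make_input(bx, [0.01] * 5, by, byse)
        w = bx ** 2 / byse ** 2
        oracle = weighted_quantile_oracle(by / bx, w)
        est = mr.median(d, method="weighted", seed=3, iterations=100)
        assert est.estimate == pytest.approx(oracle, abs=1e-12)
        assert abs(est.estimate - 0.8) < 0.05

    def test_penalized_downweights_heavily_weighted_outlier(self):
        # the outlying variant carries most of the inverse-variance weight,
        # so the weighted median is dragged towards it; penalization should
        # recover an estimate close to the clean weighted median
        bx = np.array([0.3, 0.32, 0.28, 0.31, 0.29, 0.55])
        byse = np.array([0.05, 0.05, 0.05, 0.05, 0.05, 0.045])
        by_clean = 0.5 * bx
        by = by_clean.copy()
        by[-1] = 1.5 * bx[-1]  # ratio 1.5 carrying ~45% of the weight
        d_clean = mr.make_input(bx, np.full(6, 0.01), by_clean, byse)
        d = mr.make_input(bx, np.full(6, 0.01), by, byse)
        pen = mr.median(d, method="penalized", seed=4, iterations=200)
        wgt = mr.median(d, method="weighted", seed=4, iterations=200)
        clean = mr.median(d_clean, method="weighted", seed=4, iterations=200)
        assert abs(pen.estimate - clean.estimate) < abs(
            wgt.estimate - clean.estimate)

    def test_bootstrap_se_deterministic_under_seed(self, clean_data):
        a = mr.median(clean_data, seed=42, iterations=500)
        b = mr.median(clean_data, seed=42, iterations=500)
        assert a.std_error == b.std_error

    def test_bootstrap_se_stable_across_seeds_at_large_iterations(self,
                                                                  clean_data):
        a = mr.median(clean_data, seed=1, iterations=10000)
        b = mr.median(clean_data, seed=2, iterations=10000)
        assert abs(a.std_error - b.std_error) / a.std_error < 0.1

    def test_seed_required(self, clean_data):
        with pytest.raises(ValidationError):
            mr.median(clean_data)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_estimate_within_ratio_range(self, seed):
        d = random_dataset(seed, J=7)
        est = mr.median(d, method="weighted", seed=0, iterations=50)
        r = d.by / d.bx
        assert r.min() - 1e-12 <= est.estimate <= r.max() + 1e-12


# --------------------------------------------------------------------------
# maximum likelihood
# --------------------------------------------------------------------------


class TestMaxlik:
    def test_no_measurement_error_limit_equals_fixed_ivw(self, clean_data):
        d = mr.make_input(clean_data.bx, np.full(10, 1e-10), clean_data.by,
                          clean_data.byse)
        ml = mr.maxlik(d)
        fixed = mr.ivw(clean_data, model="fixed")
        assert ml.estimate == pytest.approx(fixed.estimate, abs=1e-4)
        assert ml.std_error == pytest.approx(fixed.std_error, rel=1e-3)

    def test_exact_proportionality(self):
        bx = np.array([0.2, 0.3, 0.4])
        d = mr.make_input(bx, [1e-6] * 3, 0.5 * bx, [1e-6] * 3)
        assert mr.maxlik(d).estimate == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_profile_oracle(self):
        d = random_dataset(17, J=4)
        est = mr.maxlik(d)
        # brute-force profile likelihood on a fine grid, closed-form xi
        vx, vy = d.bxse ** 2, d.byse ** 2
        grid = np.arange(est.estimate - 0.2, est.estimate + 0.2, 1e-4)

        def ll(t):
            xi = (d.bx / vx + t * d.by / vy) / (1 / vx + t ** 2 / vy)
            return (-0.5 * np.sum((d.bx - xi) ** 2 / vx)
                    - 0.5 * np.sum((d.by - t * xi) ** 2 / vy))

        best = grid[np.argmax([ll(t) for t in grid])]
        assert est.estimate == pytest.approx(best, abs=2e-4)


# --------------------------------------------------------------------------
# mode-based estimation
# --------------------------------------------------------------------------


class TestMbe:
    def test_degenerate_common_ratio(self):
        bx = np.array([0.2, 0.3, 0.4])
        d = mr.make_input(bx, [0.01] * 3, 0.7 * bx, [0.02] * 3)
        est = mr.mbe(d, seed=1, iterations=200)
        assert est.estimate == pytest.approx(0.7, abs=1e-10)
        assert est.std_error > 0

    def test_mode_resists_outliers_against_kde_oracle(self):
        bx = np.concatenate([np.full(7, 0.4), np.full(2, 0.4)])
        by = np.concatenate([0.4 * np.array([0.48, 0.49, 0.5, 0.5, 0.51,
                                             0.52, 0.5]),
                             0.4 * np.array([3.0, 3.0])])
        d = mr.make_input(bx, np.full(9, 0.01), by, np.full(9, 0.04))
        est = mr.mbe(d, seed=2, iterations=200)
        assert abs(est.estimate - 0.5) < 0.1
        assert abs(est.estimate - np.mean(by / bx)) > 0.3
        # independent dense-grid argmax of the weighted KDE
        r = by / bx
        se = d.byse / np.abs(bx)
        w = se ** -2.0
        w = w / w.sum()
        h = est.extra["bandwidth"]
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 200001)
        dens = sum(wj * stats.norm.pdf(grid, rj, h) for rj, wj in zip(r, w))
        assert est.estimate == pytest.approx(grid[np.argmax(dens)], abs=1e-2)

    def test_bandwidth_scales_with_phi(self, clean_data):
        a = mr.mbe(clean_data, phi=1.0, seed=1, iterations=50)
        b = mr.mbe(clean_data, phi=2.0, seed=1, iterations=50)
        assert b.extra["bandwidth"] == pytest.approx(2 * a.extra["bandwidth"])

    def test_deterministic_under_seed(self, clean_data):
        a = mr.mbe(clean_data, seed=9, iterations=300)
        b = mr.mbe(clean_data, seed=9, iterations=300)
        assert a.std_error == b.std_error


# --------------------------------------------------------------------------
# heterogeneity-penalized model averaging
# --------------------------------------------------------------------------


def hetpen_oracle(data, prior, grid):
    """Literal subset enumeration, written independently of the package."""
    rt = mr.ratio_estimates(data)
    r = rt["ratio"].to_numpy()
    se = rt["se_second"].to_numpy()
    J = len(r)
    comps = []
    for size in range(2, J + 1):
        for subset in itertools.combinations(range(J), size):
            idx = list(subset)
            w = 1.0 / se[idx] ** 2
            theta = np.sum(w * r[idx]) / np.sum(w)
            var = 1.0 / np.sum(w)
            q = np.sum(w * (r[idx] - theta) ** 2)
            weight = prior ** size * (1 - prior) ** (J - size) * np.exp(-q / 2)
            comps.append((weight, theta, var))
    weights = np.array([c[0] for c in comps])
    weights = weights / weights.sum()
    dens = np.zeros_like(grid)
    for wgt, theta, var in zip(weights, (c[1] for c in comps),
                               (c[2] for c in comps)):
        dens += wgt * stats.norm.pdf(grid, theta, np.sqrt(var))
    return dens / dens.sum()


class TestHetpen:
    def test_identical_ratios_tight_interval(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        d = mr.make_input(bx, [0.005] * 4, 0.5 * bx, [0.002] * 4)
        est = mr.hetpen(d)
        assert est.ci_lower < 0.5 < est.ci_upper
        assert est.ci_upper - est.ci_lower < 0.05

    def test_matches_brute_force_enumeration(self):
        d = random_dataset(23, J=6)
        est = mr.hetpen(d, ci_step=0.005)
        grid = np.arange(*_hetpen_grid(d, 0.005))
        oracle_mass = hetpen_oracle(d, 0.5, grid)
        assert est.estimate == pytest.approx(grid[np.argmax(oracle_mass)],
                                             abs=1e-9)
        # mode and hull agree with an HPD set computed from the oracle mass
        order = np.argsort(oracle_mass)[::-1]
        ncover = int(np.searchsorted(np.cumsum(oracle_mass[order]), 0.95) + 1)
        mask = np.zeros(len(grid), bool)
        mask[order[:ncover]] = True
        assert est.ci_lower == pytest.approx(grid[mask].min(), abs=1e-9)
        assert est.ci_upper == pytest.approx(grid[mask].max(), abs=1e-9)

    def test_prior_near_one_approaches_ivw(self, clean_data):
        est = mr.hetpen(clean_data, prior=1 - 1e-9, max_variants=10)
        ivw_est = mr.ivw(clean_data, model="fixed")
        # with prior ~1 nearly all weight is on the full subset
        assert abs(est.estimate - ivw_est.estimate) < 2 * est.extra["ci_step"] \
            + 0.05 * abs(ivw_est.estimate)

    def test_infeasible_j_rejected(self):
        d = random_dataset(1, J=25)
        with pytest.raises(ValidationError, match="conmix"):
            mr.hetpen(d)


def _hetpen_grid(data, step):
    rt = mr.ratio_estimates(data)
    r = rt["ratio"].to_numpy()
    se = rt["se_second"].to_numpy()
    lo = r.min() - 5 * se.max()
    hi = r.max() + 5 * se.max()
    n = int(np.floor((hi - lo) / step)) + 1
    return lo, lo + step * n - 1e-12, step


# --------------------------------------------------------------------------
# contamination mixture
# --------------------------------------------------------------------------


class TestConmix:
    def test_homogeneous_all_valid(self):
        bx = np.array([0.2, 0.3, 0.4])
        d = mr.make_input(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        est = mr.conmix(d, psi=1.0)
        assert est.estimate == pytest.approx(0.5, abs=1e-6)
        assert est.valid_variants == d.snps

    def test_outlier_classification(self):
        rng = np.random.default_rng(5)
        bx = np.abs(rng.normal(0.4, 0.05, 12))
        ratios = np.array([0.5] * 8 + [2.5] * 4)
        by = ratios * bx + rng.normal(0, 0.01, 12)
        d = mr.make_input(bx, np.full(12, 0.01), by, np.full(12, 0.05))
        est = mr.conmix(d, psi=2.5)
        assert abs(est.estimate - 0.5) < 0.05
        assert set(est.valid_variants) == set(d.snps[:8])

    def test_matches_dense_grid_profile_oracle(self):
        d = random_dataset(31, J=9)
        est = mr.conmix(d, psi=0.7, ci_step=0.001)
        rt = mr.ratio_estimates(d)
        r, se = rt["ratio"].to_numpy(), rt["se_first"].to_numpy()
        grid = np.arange(r.min() - 5 * se.max(), r.max() + 5 * se.max(), 1e-4)
        ll = np.array([
            np.sum(np.maximum(stats.norm.logpdf(r, t, se),
                              stats.norm.logpdf(r, 0, np.sqrt(se ** 2 + 0.49))))
            for t in grid])
        assert est.estimate == pytest.approx(grid[np.argmax(ll)], abs=2e-3)

    def test_confidence_set_monotone_in_coverage(self, clean_data):
        wide = mr.conmix(clean_data, alpha=0.01)
        narrow = mr.conmix(clean_data, alpha=0.05)
        assert wide.ci_lower <= narrow.ci_lower + 1e-12
        assert wide.ci_upper >= narrow.ci_upper - 1e-12

    def test_auto_psi_recorded(self, clean_data):
        est = mr.conmix(clean_data)
        r = clean_data.by / clean_data.bx
        assert est.extra["psi"] == pytest.approx(1.5 * np.std(r, ddof=1))


# --------------------------------------------------------------------------
# lasso
# --------------------------------------------------------------------------


class TestLasso:
    def test_homogeneous_data_retains_all(self, exact_data):
        est = mr.lasso(exact_data)
        assert est.valid_variants == exact_data.snps
        assert est.estimate == pytest.approx(mr.ivw(exact_data).estimate,
                                             abs=1e-12)

    def test_large_lambda_keeps_everything(self, clean_data):
        est = mr.lasso(clean_data, lam=1e9)
        assert len(est.valid_variants) == 10
        assert est.estimate == pytest.approx(mr.ivw(clean_data).estimate,
                                             abs=1e-10)

    def test_gross_outlier_removed_at_auto_lambda(self):
        rng = np.random.default_rng(13)
        bx = np.abs(rng.normal(0.4, 0.05, 10))
        by = 0.5 * bx + rng.normal(0, 0.005, 10)
        by[-1] += 1.0  # gross outlier
        d = mr.make_input(bx, np.full(10, 0.01), by, np.full(10, 0.02))
        est = mr.lasso(d)
        assert est.valid_variants == d.snps[:9]
        clean = mr.make_input(bx[:9], np.full(9, 0.01), by[:9],
                              np.full(9, 0.02))
        assert est.estimate == pytest.approx(mr.ivw(clean).estimate, abs=1e-8)

    def test_solution_satisfies_subgradient_conditions(self):
        d = random_dataset(19, J=8)
        by = d.by.copy()
        by[0] += 0.5
        dd = mr.make_input(d.bx, d.bxse, by, d.byse)
        from mrsum.univariable import _lasso_fit
        w = dd.byse ** -2.0
        lam = 5.0
        theta, a = _lasso_fit(dd.bx, dd.by, w, lam)
        resid = dd.by - a - theta * dd.bx
        # stationarity in theta
        assert np.sum(w * dd.bx * resid) == pytest.approx(0.0, abs=1e-6)
        # KKT for each per-variant intercept
        for j in range(8):
            g = -2 * w[j] * resid[j]
            if a[j] != 0:
                assert g + lam * np.sign(a[j]) == pytest.approx(0.0, abs=1e-6)
            else:
                assert abs(g) <= lam + 1e-6


# --------------------------------------------------------------------------
# heterogeneity statistics
# --------------------------------------------------------------------------


class TestHeterogeneity:
    def test_exact_fit_gives_zero_q(self, exact_data):
        het = mr.heterogeneity(exact_data, "ivw")
        assert het.statistic == pytest.approx(0.0, abs=1e-18)
        assert het.p_value == pytest.approx(1.0)

    def test_two_study_closed_form(self):
        # classic two-estimate Cochran formula: Q = (r1-r2)^2/(v1+v2)
        bx = np.array([1.0, 1.0])
        by = np.array([0.3, 0.6])
        byse = np.array([0.1, 0.2])
        d = mr.make_input(bx, [0.01] * 2, by, byse)
        het = mr.heterogeneity(d, "ivw")
        assert het.statistic == pytest.approx((0.3 - 0.6) ** 2 / (0.01 + 0.04))

    @pytest.mark.parametrize("seed", range(8))
    def test_ruecker_q_never_exceeds_cochran_q(self, seed):
        d = random_dataset(300 + seed, J=9)
        assert (mr.heterogeneity(d, "egger").statistic
                <= mr.heterogeneity(d, "ivw").statistic + 1e-10)


# --------------------------------------------------------------------------
# run_all and cross-method invariants
# --------------------------------------------------------------------------


class TestRunAll:
    def test_default_panel_has_ordered_cis(self, clean_data):
        out = mr.run_all(clean_data, seed=1, iterations=200)
        assert len(out) >= 6
        for est in out:
            assert est.ci_lower <= est.estimate <= est.ci_upper

    def test_single_method_matches_direct_call(self, clean_data):
        out = mr.run_all(clean_data, ["ivw"], seed=1)
        assert len(out) == 1
        assert out[0].estimate == mr.ivw(clean_data).estimate

    def test_empty_method_list_rejected(self, clean_data):
        with pytest.raises(ValidationError):
            mr.run_all(clean_data, [], seed=1)

    def test_all_methods_consistent_at_exact_proportionality(self, exact_data):
        out = mr.run_all(exact_data, seed=1, iterations=200)
        assert len(out) == 8
        for est in out:
            assert est.estimate == pytest.approx(0.5, abs=1e-6), est.method


_SCALE_METHODS = {
    "ivw": lambda d: mr.ivw(d).estimate,
    "egger": lambda d: mr.egger(d).estimate,
    "wmedian": lambda d: mr.median(d, seed=0, iterations=50).estimate,
    "maxlik": lambda d: mr.maxlik(d).estimate,
    "conmix": lambda d: mr.conmix(d).estimate,
    "lasso": lambda d: mr.lasso(d, lam=1e9).estimate,
}


@pytest.mark.parametrize("method", sorted(_SCALE_METHODS))
def test_outcome_scale_equivariance(method):
    d = random_dataset(41, J=10)
    c = 2.5
    scaled = mr.make_input(d.bx, d.bxse, c * d.by, c * d.byse)
    est = _SCALE_METHODS[method](d)
    est_scaled = _SCALE_METHODS[method](scaled)
    assert est_scaled == pytest.approx(c * est, rel=1e-6)


@pytest.mark.parametrize("method", sorted(_SCALE_METHODS))
def test_exposure_scale_equivariance(method):
    d = random_dataset(43, J=10)
    c = 2.0
    scaled = mr.make_input(c * d.bx, c * d.bxse, d.by, d.byse)
    est = _SCALE_METHODS[method](d)
    est_scaled = _SCALE_METHODS[method](scaled)
    assert est_scaled == pytest.approx(est / c, rel=1e-6)


@pytest.mark.parametrize("method", sorted(_SCALE_METHODS))
def test_variant_flip_invariance(method):
    d = random_dataset(47, J=10)
    flip = np.ones(10)
    flip[[0, 3, 8]] = -1.0
    flipped = mr.make_input(d.bx * flip, d.bxse, d.by * flip, d.byse)
    assert _SCALE_METHODS[method](flipped) == pytest.approx(
        _SCALE_METHODS[method](d), rel=1e-6)
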