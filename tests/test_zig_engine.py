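import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from conftest import make_toy_design
from zigrow.errors import RankDeficiencyError, SizeGuardError
from zigrow.model_design import DesignMatrices, ModelSpec, build_design
from zigrow.synthetic_data import SimConfig, simulate_trial
from zigrow.zig_engine import (
    FitControl,
    FittedZIG,
    ZIGParameters,
    _LaplaceWork,
    brute_force_marginal_loglik,
    fit_from_json,
    fit_to_json,
    fit_zig,
    laplace_marginal_loglik,
    wald_tests,
    zig_joint_loglik,
)


def gaussian_instance(n=20, seed=3):
    d = make_toy_design(n, {"g1": 2}, zi=False, kc=2, seed=seed)
    p = ZIGParameters(np.array([1.0, 0.5]), None, 0.8, {"g1": 0.7}, None)
    return d, p


def mvn_loglik(d, p):
    """Closed-form marginal likelihood of the Gaussian mixed model."""
    n = d.n_obs
    Z = np.zeros((n, d.n_levels["g1"]))
    Z[np.arange(n), d.codes["g1"]] = 1.0
    cov = Z @ (p.re_sd_cond["g1"] ** 2 * np.eye(Z.shape[1])) @ Z.T
    cov += p.sigma_resid**2 * np.eye(n)
    return multivariate_normal.logpdf(d.y, mean=d.X @ p.beta_cond, cov=cov)


class TestJointLoglik:
    def test_zero_inflation_off_collapses_to_gaussian(self):
        d = make_toy_design(15, {"g1": 3}, zi=True, kc=2, seed=4, zero_frac=0.0)
        p = ZIGParameters(
            np.array([1.0, 0.2]), np.array([-30.0, 0.0]), 0.9, {"g1": 0.5}, {"g1": 0.5}
        )
        b = {"cond": {"g1": np.zeros(3)}, "zi": {"g1": np.zeros(3)}}
        got = zig_joint_loglik(p, b, d)
        mu = d.X @ p.beta_cond
        expected = norm.logpdf(d.y, mu, 0.9).sum()
        # prior of 6 standard-normal-scaled zeros
        expected += 2 * 3 * norm.logpdf(0.0, 0.0, 0.5)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_single_zero_observation_value(self):
        d = make_toy_design(1, {"g1": 1}, zi=True, kc=1, seed=0, zero_frac=1.0)
        d.y[:] = 0.0
        d.is_zero[:] = True
        p = ZIGParameters(np.array([0.0]), np.array([0.0]), 1.0, {"g1": 1.0}, {"g1": 1.0})
        b = {"cond": {"g1": np.zeros(1)}, "zi": {"g1": np.zeros(1)}}
        got = zig_joint_loglik(p, b, d)
        expected = np.log(0.5 + 0.5 * norm.pdf(0.0)) + 2 * norm.logpdf(0.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_positive_observation_with_no_inflation(self):
        d = make_toy_design(1, {"g1": 1}, zi=True, kc=1, seed=0, zero_frac=0.0)
        p = ZIGParameters(np.array([1.0]), np.array([-30.0]), 0.7, {"g1": 1.0}, {"g1": 1.0})
        b = {"cond": {"g1": np.zeros(1)}, "zi": {"g1": np.zeros(1)}}
        got = zig_joint_loglik(p, b, d)
        expected = norm.logpdf(d.y[0], 1.0, 0.7) + 2 * norm.logpdf(0.0)
        assert got == pytest.approx(expected, abs=1e-8)


class TestLaplace:
    def test_exact_for_gaussian_model(self):
        d, p = gaussian_instance()
        val, _ = laplace_marginal_loglik(p, d)
        assert val == pytest.approx(mvn_loglik(d, p), abs=1e-8)

    def test_vanishing_re_sd_approaches_fixed_effects_likelihood(self):
        d, p = gaussian_instance()
        p.re_sd_cond = {"g1": 1e-8}
        val, _ = laplace_marginal_loglik(p, d)
        no_re = norm.logpdf(d.y, d.X @ p.beta_cond, p.sigma_resid).sum()
        assert val == pytest.approx(no_re, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self):
        d = make_toy_design(60, {"grp": 4, "ind": 15}, zi=True, kc=3, seed=5)
        work = _LaplaceWork(d, FitControl())
        p = ZIGParameters(
            np.array([1.0, 0.3, -0.2]),
            np.array([-0.5, 0.2, 0.1]),
            0.7,
            {"grp": 0.5, "ind": 0.4},
            {"grp": 0.3, "ind": 0.25},
        )
        theta = work.pk.pack(p)
        _, g, b = work.laplace_with_grad(theta)
        h = 1e-6
        for t in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[t] += h
            tm[t] -= h
            vp, _ = work.laplace(tp, b)
            vm, _ = work.laplace(tm, b)
            fd = (vp - vm) / (2 * h)
            assert g[t] == pytest.approx(fd, abs=5e-6)

    def test_invariant_to_row_order_and_level_relabeling(self):
        d = make_toy_design(40, {"grp": 4}, zi=True, kc=2, seed=8)
        p = ZIGParameters(
            np.array([1.0, 0.4]), np.array([-0.5, 0.2]), 0.8, {"grp": 0.4}, {"grp": 0.3}
        )
        v1, _ = laplace_marginal_loglik(p, d)
        perm = np.random.default_rng(0).permutation(40)
        relabel = np.array([2, 0, 3, 1])
        d2 = DesignMatrices(
            y=d.y[perm],
            is_zero=d.is_zero[perm],
            X=d.X[perm],
            columns=d.columns,
            X_zi=d.X_zi[perm],
            columns_zi=d.columns_zi,
            factors=d.factors,
            codes={"grp": relabel[d.codes["grp"][perm]]},
            n_levels=d.n_levels,
            level_labels=d.level_labels,
            scaling=None,
            spec=None,
        )
        v2, _ = laplace_marginal_loglik(p, d2)
        assert v2 == pytest.approx(v1, abs=1e-8)


class TestBruteForce:
    def test_gaussian_instance_matches_closed_form(self):
        d, p = gaussian_instance()
        bf = brute_force_marginal_loglik(p, d, n_nodes=50)
        assert bf == pytest.approx(mvn_loglik(d, p), abs=1e-8)

    def test_tiny_re_sd_equals_fixed_effects_likelihood(self):
        d, p = gaussian_instance()
        p.re_sd_cond = {"g1": 1e-8}
        bf = brute_force_marginal_loglik(p, d, n_nodes=50)
        no_re = norm.logpdf(d.y, d.X @ p.beta_cond, p.sigma_resid).sum()
        assert bf == pytest.approx(no_re, abs=1e-6)

    def test_size_guard(self):
        d = make_toy_design(30, {"grp": 9}, zi=True, kc=2)
        p = ZIGParameters(
            np.array([1.0, 0.2]), np.array([0.0, 0.0]), 1.0, {"grp": 0.5}, {"grp": 0.5}
        )
        with pytest.raises(SizeGuardError):
            brute_force_marginal_loglik(p, d)


class TestFit:
    def test_reduces_to_ols_without_noise_sources(self):
        rng = np.random.default_rng(2)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([2.0, 0.7, -0.4])
        y = X @ beta + rng.normal(0, 0.3, n)
        y = np.abs(y) + 0.05
        d = DesignMatrices(
            y=y,
            is_zero=np.zeros(n, bool),
            X=X,
            columns=("c0", "c1", "c2"),
            X_zi=None,
            columns_zi=(),
            factors=("grp",),
            codes={"grp": rng.integers(0, 5, n)},
            n_levels={"grp": 5},
            level_labels={"grp": list(range(5))},
            scaling=None,
            spec=None,
        )
        fit = fit_zig(d, FitControl(compute_vcov=False))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # with the RE variance driven to the boundary the fit is OLS
        assert fit.params.re_sd_cond["grp"] < 2e-3
        assert np.allclose(fit.params.beta_cond, ols, atol=1e-4)

    def test_loglik_invariant_to_covariate_rescaling(self, small_trial):
        data, _ = small_trial
        spec = ModelSpec(variant="full")
        d1 = build_design(data, spec)
        scaled_data = data.copy()
        scaled_data.genotypes = scaled_data.genotypes.assign(
            pc1=scaled_data.genotypes["pc1"] * 7.0
        )
        d2 = build_design(scaled_data, spec)
        c = FitControl(compute_vcov=False)
        f1, f2 = fit_zig(d1, c), fit_zig(d2, c)
        assert f2.loglik == pytest.approx(f1.loglik, abs=5e-3)
        # the raw-scale coefficient absorbs the rescaling through the
        # recorded divisor, so the scaled-space estimates coincide
        i = d1.columns.index("pc1")
        assert f2.params.beta_cond[i] == pytest.approx(f1.params.beta_cond[i], abs=5e-3)

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        d = DesignMatrices(
            y=np.abs(rng.normal(1, 1, n)) + 0.1,
            is_zero=np.zeros(n, bool),
            X=X,
            columns=("c0", "c1", "c1_again"),
            X_zi=None,
            columns_zi=(),
            factors=("grp",),
            codes={"grp": rng.integers(0, 4, n)},
            n_levels={"grp": 4},
            level_labels={"grp": list(range(4))},
            scaling=None,
            spec=None,
        )
        with pytest.raises(RankDeficiencyError):
            fit_zig(d)

    def test_no_zero_responses_pins_zi_part(self):
        d = make_toy_design(80, {"grp": 4}, zi=True, kc=2, seed=6, zero_frac=0.0)
        with pytest.warns(RuntimeWarning, match="zi part pinned"):
            fit = fit_zig(d, FitControl(compute_vcov=False))
        assert fit.params.beta_zi[0] == -30.0

    def test_all_zero_responses_degenerate(self):
        d = make_toy_design(20, {"grp": 2}, zi=True, kc=2, seed=6, zero_frac=1.0)
        d.y[:] = 0.0
        d.is_zero[:] = True
        with pytest.warns(RuntimeWarning, match="all responses are zero"):
            fit = fit_zig(d)
        assert not fit.converged
        assert np.isnan(fit.params.sigma_resid)

    def test_objective_log_is_monotone(self, small_fit):
        log = small_fit.objective_log
        assert len(log) > 5
        assert np.all(np.diff(log) > -1e-6)

    def test_serialization_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "fit.json"
        fit_to_json(small_fit, path)
        back = fit_from_json(path)
        assert np.allclose(back.params.beta_cond, small_fit.params.beta_cond)
        assert np.allclose(back.vcov_fixed, small_fit.vcov_fixed)
        assert back.params.re_sd_cond == pytest.approx(small_fit.params.re_sd_cond)
        assert back.loglik == small_fit.loglik
        assert back.scaling.divisors == small_fit.scaling.divisors


class TestWald:
    def _manual_fit(self, est, se):
        k = len(est)
        return FittedZIG(
            params=ZIGParameters(np.asarray(est, float), None, 1.0, {"g": 0.5}, None),
            vcov_fixed=np.diag(np.asarray(se, float) ** 2),
            re_modes={},
            loglik=0.0,
            converged=True,
            n_obs=10,
            scaling=None,
            spec=None,
            columns=tuple(f"c{i}" for i in range(k)),
            columns_zi=(),
        )

    def test_two_sigma_coefficient(self):
        w = wald_tests(self._manual_fit([2.0], [1.0]))
        assert w.loc[0, "chi2"] == pytest.approx(4.0)
        assert w.loc[0, "p"] == pytest.approx(0.0455, abs=2e-4)
        assert w.loc[0, "df"] == 1

    def test_null_coefficient(self):
        w = wald_tests(self._manual_fit([0.0], [1.0]))
        assert w.loc[0, "chi2"] == 0.0
        assert w.loc[0, "p"] == 1.0

    def test_joint_test_reduces_to_single_column(self):
        from zigrow.zig_engine import wald_joint_test

        fit = self._manual_fit([2.0, 0.3], [1.0, 0.5])
        chi2, df, p = wald_joint_test(fit, ["c0"])
        assert (chi2, df) == (pytest.approx(4.0), 1)
        chi2_2, df_2, _ = wald_joint_test(fit, ["c0", "c1"])
        # independent coordinates: the joint statistic is the sum
        assert chi2_2 == pytest.approx(4.0 + (0.3 / 0.5) ** 2)
        assert df_2 == 2


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_against_reference_mixed_model_engine(tmp_path):
    """Cross-check fit against glmmTMB (independent reference) on a tiny
    zero-inflated Gaussian instance with two crossed random intercepts."""
    rng = np.random.default_rng(5)
    from scipy.special import expit

    n, L, M = 300, 6, 8
    grp, grp2 = rng.integers(0, L, n), rng.integers(0, M, n)
    x = rng.normal(size=n)
    eta_c = 1.5 + 0.6 * x + rng.normal(0, 0.4, L)[grp] + rng.normal(0, 0.3, M)[grp2]
    eta_z = -0.8 + 0.4 * x + rng.normal(0, 0.3, L)[grp] + rng.normal(0, 0.2, M)[grp2]
    z = rng.random(n) < expit(eta_z)
    y = np.where(z, 0.0, np.maximum(eta_c + rng.normal(0, 0.6, n), 0.01))
    df = pd.DataFrame({"y": y, "x": x, "g": grp, "h": grp2})
    csv = tmp_path / "data.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        d$g <- factor(d$g); d$h <- factor(d$h)
        m <- glmmTMB(y ~ x + (1|g) + (1|h), ziformula = ~ x + (1|g) + (1|h),
                     family = gaussian(), data = d)
        cat(as.numeric(logLik(m)), fixef(m)$cond, fixef(m)$zi, sigma(m), "\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = np.array([float(v) for v in out.stdout.split()])
    ref_ll, ref_bc, ref_bz, ref_sigma = ref[0], ref[1:3], ref[3:5], ref[5]

    X = np.column_stack([np.ones(n), x])
    d = DesignMatrices(
        y=y,
        is_zero=(y == 0),
        X=X,
        columns=("intercept", "x"),
        X_zi=X,
        columns_zi=("intercept", "x"),
        factors=("g", "h"),
        codes={"g": grp, "h": grp2},
        n_levels={"g": L, "h": M},
        level_labels={"g": list(range(L)), "h": list(range(M))},
        scaling=None,
        spec=None,
    )
    fit = fit_zig(d, FitControl(compute_vcov=False))
    assert fit.loglik == pytest.approx(ref_ll, abs=1e-3)
    assert np.allclose(fit.params.beta_cond, ref_bc, atol=1e-3)
    assert np.allclose(fit.params.beta_zi, ref_bz, atol=5e-3)
    assert fit.params.sigma_resid == pytest.approx(ref_sigma, abs=1e-3)
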