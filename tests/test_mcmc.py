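"""Sampler diagnostics, conjugate full conditionals, and knot recovery."""

import warnings

import numpy as np
import pytest
from scipy import stats

import knotpgm as kp
from knotpgm.mcmc import (
    MCMCConfig,
    PosteriorResult,
    _inv_wishart_rvs,
    _update_alpha,
    _update_eta,
    _update_sigma2,
)


def empty_dataset(grid):
    return kp.LongitudinalDataset(
        np.zeros((0, grid.n_occasions)), np.zeros((0, grid.n_occasions), bool), grid
    )


class TestRhat:
    def test_identical_chains_return_one_by_convention(self):
        x = np.ones((4, 100))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert kp.compute_rhat(x) == 1.0

    def test_classic_split_formula_oracle(self):
        """Two alternating chains offset by 10 must be flagrantly nonconverged."""
        a = np.tile([0.0, 1.0], 500)
        x = np.vstack([a, a + 10.0])
        # hand-coded classic split potential scale reduction
        split = np.vstack([x[:, :500], x[:, 500:]])
        m, n = split.shape
        within = split.var(axis=1, ddof=1).mean()
        between = n * split.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * within + between / n) / within)
        got = kp.compute_rhat(x, method="split")
        assert got == pytest.approx(expected, abs=1e-10)
        assert got > 5.0

    def test_rank_normalized_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        for shift in (0.0, 0.3, 2.0):
            x = rng.standard_normal((4, 800))
            x[2] += shift
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                theirs = float(
                    np.asarray(
                        az.rhat(az.from_dict({"p": x[:, :, None]}), method="rank")
                        .to_array()
                    ).ravel()[0]
                )
            assert kp.compute_rhat(x, method="rank") == pytest.approx(theirs, abs=1e-8)

    def test_calibration_under_the_null(self):
        """Independent same-distribution chains rarely exceed 1.01."""
        rng = np.random.default_rng(77)
        below = sum(
            kp.compute_rhat(rng.standard_normal((4, 1000))) < 1.01 for _ in range(100)
        )
        assert below >= 95

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2 chains"):
            kp.compute_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="at least 2 chains"):
            kp.compute_rhat(np.zeros((4, 3)))


def _result_from_draws(draws):
    draws = np.asarray(draws, float)
    return PosteriorResult(
        draws=draws[:, :, None] if draws.ndim == 2 else draws,
        param_names=["gamma"],
        rhat=np.array([1.0]),
        converged=True,
        knot_acceptance=0.4,
        config=MCMCConfig.scaled(seed=0),
    )


class TestSummarize:
    def test_small_sample_mean_and_median(self):
        result = _result_from_draws(np.array([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]]))
        table = kp.summarize(result)
        assert table.loc["gamma", "mean"] == 3.0
        assert table.loc["gamma", "median"] == 3.0

    def test_percentiles_match_sorting_oracle(self):
        rng = np.random.default_rng(8)
        draws = rng.standard_normal((2, 501))
        table = kp.summarize(_result_from_draws(draws))

        def quantile_by_sorting(values, q):
            s = np.sort(values)
            pos = q * (s.size - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return s[lo] * (1 - frac) + s[min(lo + 1, s.size - 1)] * frac

        pooled = draws.reshape(-1)
        assert table.loc["gamma", "ci_lower"] == pytest.approx(
            quantile_by_sorting(pooled, 0.025), abs=1e-12
        )
        assert table.loc["gamma", "ci_upper"] == pytest.approx(
            quantile_by_sorting(pooled, 0.975), abs=1e-12
        )
        assert (
            table.loc["gamma", "ci_lower"]
            <= table.loc["gamma", "median"]
            <= table.loc["gamma", "ci_upper"]
        )


class TestCheckConvergence:
    def _with_rhat(self, values):
        result = _result_from_draws(np.zeros((2, 8)) + np.arange(8))
        result.rhat = np.asarray(values, float)
        return result

    def test_all_converged(self):
        assert kp.check_convergence(self._with_rhat([1.0, 1.0]), 1.1)

    def test_single_failure(self):
        assert not kp.check_convergence(self._with_rhat([1.0, 1.2]), 1.1)

    def test_boundary_is_strict(self):
        assert not kp.check_convergence(self._with_rhat([1.1]), 1.1)


class TestConjugateFullConditionals:
    """Each Gibbs block must reproduce its analytic conditional (KS p > 0.01)."""

    N_DRAWS = 5000

    def test_alpha_update_matches_normal_posterior(self):
        rng = np.random.default_rng(10)
        eta = rng.standard_normal((20, 3)) + [1.0, -2.0, 0.5]
        omega_inv = np.linalg.inv(np.diag([1.0, 0.5, 0.25]))
        priors = kp.default_nuisance_priors()
        prec = 20 * omega_inv + np.eye(3) / priors.sigma2_alpha
        cov = np.linalg.inv(prec)
        mean = cov @ (omega_inv @ eta.sum(axis=0))
        draws = np.array(
            [_update_alpha(rng, eta, omega_inv, priors)[0] for _ in range(self.N_DRAWS)]
        )
        p = stats.kstest(draws, "norm", args=(mean[0], np.sqrt(cov[0, 0]))).pvalue
        assert p > 0.01

    def test_sigma2_update_matches_inverse_gamma(self):
        rng = np.random.default_rng(11)
        priors = kp.default_nuisance_priors()
        rss = np.array([40.0, 80.0])
        n = 25
        draws = np.array(
            [_update_sigma2(rng, rss, n, priors) for _ in range(self.N_DRAWS)]
        )
        for j in range(2):
            dist = stats.invgamma(priors.a + n / 2, scale=priors.b + rss[j] / 2)
            assert stats.kstest(draws[:, j], dist.cdf).pvalue > 0.01

    def test_eta_update_matches_mvn_conditional(self, grid):
        rng = np.random.default_rng(12)
        lam = kp.build_loading_matrix(grid, 3.0)
        sigma2 = np.full(7, 2.0)
        omega = np.diag([4.0, 0.3, 0.3])
        omega_inv = np.linalg.inv(omega)
        alpha = np.array([10.0, 1.0, 2.0])
        y = (lam @ alpha + rng.standard_normal(7)).reshape(1, 7)
        prec = lam.T @ (lam / sigma2[:, None]) + omega_inv
        cov = np.linalg.inv(prec)
        mean = cov @ ((lam / sigma2[:, None]).T @ y[0] + omega_inv @ alpha)
        draws = np.array(
            [
                _update_eta(rng, y, lam, sigma2, omega_inv, alpha)[0, 0]
                for _ in range(self.N_DRAWS)
            ]
        )
        assert stats.kstest(draws, "norm", args=(mean[0], np.sqrt(cov[0, 0]))).pvalue > 0.01

    def test_inverse_wishart_matches_scipy(self):
        rng = np.random.default_rng(13)
        scale = np.array([[2.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.5]])
        df = 12.0
        mine = np.array(
            [_inv_wishart_rvs(rng, df, scale)[0] for _ in range(4000)]
        )
        ref = stats.invwishart(df=df, scale=scale).rvs(4000, random_state=14)
        for idx in [(0, 0), (1, 0), (2, 2)]:
            p = stats.ks_2samp(mine[:, idx[0], idx[1]], ref[:, idx[0], idx[1]]).pvalue
            assert p > 0.01


class TestPriorRecovery:
    """Without data the posterior for the knot must reproduce its prior."""

    def _fit_empty(self, preset, grid, seed):
        priors = kp.default_nuisance_priors(kp.knot_prior_preset(preset, grid), grid)
        config = MCMCConfig.scaled(seed=seed)
        return kp.fit(empty_dataset(grid), priors, config).gamma_draws()

    def test_uniform_prior_recovered(self, grid):
        g = self._fit_empty("DIF", grid, 21)
        mean, sd = kp.knot_prior_preset("DIF", grid).mean_sd()
        assert g.mean() == pytest.approx(mean, abs=0.15)
        assert g.std() == pytest.approx(sd, abs=0.15)
        assert g.min() >= 0.0 and g.max() <= 6.0

    def test_truncated_normal_prior_recovered(self, grid):
        g = self._fit_empty("I-ATK", grid, 22)
        mean, sd = kp.knot_prior_preset("I-ATK", grid).mean_sd()
        assert g.mean() == pytest.approx(mean, abs=0.06)
        assert g.std() == pytest.approx(sd, abs=0.06)


class TestFit:
    def test_deterministic_under_fixed_seed(self, population, grid):
        data = kp.generate_complete(population, 30, grid, seed=30)
        priors = kp.default_nuisance_priors(kp.knot_prior_preset("I-ATK"))
        config = MCMCConfig.scaled(seed=31, n_iter=500, burn_in=200)
        a = kp.fit(data, priors, config)
        b = kp.fit(data, priors, config)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.knot_acceptance == b.knot_acceptance

    def test_zero_missing_augmentation_path_is_noop(self, population, grid):
        """Routing complete data through the MAR no-op changes nothing."""
        data = kp.generate_complete(population, 30, grid, seed=32)
        via_mar = kp.apply_mar(data, kp.MissingnessSpec.from_pattern("complete"), seed=33)
        priors = kp.default_nuisance_priors(kp.knot_prior_preset("I-ATK"))
        config = MCMCConfig.scaled(seed=34, n_iter=500, burn_in=200)
        np.testing.assert_array_equal(
            kp.fit(data, priors, config).draws, kp.fit(via_mar, priors, config).draws
        )

    def test_knot_recovered_with_diffuse_prior_at_large_n(self, population, grid):
        data = kp.generate_complete(population, 500, grid, seed=35)
        priors = kp.default_nuisance_priors(kp.knot_prior_preset("DIF"))
        result = kp.fit(data, priors, MCMCConfig.scaled(seed=36))
        table = kp.summarize(result)
        assert table.loc["gamma", "mean"] == pytest.approx(3.0, abs=0.5)
        assert table.loc["gamma", "ci_lower"] <= 3.0 <= table.loc["gamma", "ci_upper"]

    def test_average_knot_bias_small_at_large_n(self, grid):
        """Posterior-mean bias under a diffuse prior averages out over reps."""
        design = kp.StudyDesign(
            sample_sizes=(500,),
            missing_levels=("Complete",),
            prior_names=("DIF",),
            replications=20,
            seed=404,
        )
        cell = kp.enumerate_design(design)[0]
        metrics, _ = kp.run_cell(design, cell)
        assert abs(metrics.avg_bias) < 0.1

    def test_knot_draws_respect_truncation_support(self, population, grid):
        data = kp.generate_complete(population, 30, grid, seed=37)
        priors = kp.default_nuisance_priors(kp.knot_prior_preset("WI-PSK"))
        result = kp.fit(data, priors, MCMCConfig.scaled(seed=38, n_iter=1000, burn_in=300))
        g = result.gamma_draws()
        assert g.min() >= 0.0 and g.max() <= 6.0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="at least two chains"):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError, match="iteration plan"):
            MCMCConfig(thin=0)
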