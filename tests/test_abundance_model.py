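import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from nicheshift.abundance_model import (ModelSpec, Z975, climate_optimum, compare_aic,
                                        fit_zinb_glmm, marginal_loglik, nakagawa_r2,
                                        nb_logpmf, predict_expected, wald_table,
                                        zinb_logpmf, _design, _expit)


class TestNBLogpmf:
    def test_geometric_special_case(self):
        # theta = 1, mu = 1: P(0) = theta/(theta+mu) = 1/2
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_matches_scipy_parameterization(self):
        y = np.arange(0, 20)
        mu, theta = 3.7, 2.1
        # NB2 in scipy terms: n = theta, p = theta / (theta + mu)
        want = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
        np.testing.assert_allclose(nb_logpmf(y, mu, theta), want, atol=1e-12)

    def test_poisson_limit(self):
        y = np.arange(0, 15)
        mu = 2.5
        np.testing.assert_allclose(nb_logpmf(y, mu, 1e8),
                                   stats.poisson.logpmf(y, mu), atol=1e-4)

    def test_normalization(self):
        y = np.arange(0, 500)
        total = np.exp(nb_logpmf(y, 4.0, 0.7)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nb_logpmf(-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_logpmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_logpmf(0.5, 1.0, 1.0)


class TestZINBLogpmf:
    def test_reduces_to_nb_when_pi_zero(self):
        y = np.arange(0, 10)
        np.testing.assert_array_equal(zinb_logpmf(y, 0.0, 2.0, 1.5),
                                      nb_logpmf(y, 2.0, 1.5))

    def test_pure_zero_inflation(self):
        assert zinb_logpmf(0, 1.0, 2.0, 1.0) == 0.0
        assert zinb_logpmf(3, 1.0, 2.0, 1.0) == -np.inf

    def test_mixture_zero_mass(self):
        # pi=0.5, mu=1, theta=1: P(0) = 0.5 + 0.5 * 0.5 = 0.75
        assert zinb_logpmf(0, 0.5, 1.0, 1.0) == pytest.approx(np.log(0.75))

    def test_matches_statsmodels_zinb(self):
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        y = np.array([0, 1, 3, 0, 2, 7, 0, 0, 4])
        X = np.ones((len(y), 1))
        mod = ZeroInflatedNegativeBinomialP(y, X, exog_infl=X, p=2)
        beta0, logit_pi, alpha = 0.4, -0.7, 0.8
        sm_ll = mod.loglike(np.array([logit_pi, beta0, alpha]))
        mine = zinb_logpmf(y, _expit(logit_pi), np.exp(beta0), 1.0 / alpha).sum()
        assert mine == pytest.approx(sm_ll, abs=1e-10)


def brute_force_marginal(params, y, eta, gidx, n_grids):
    """Independent oracle: adaptive quad of the random-intercept integral."""
    theta, pi, sigma = params["theta"], params["pi"], params["sigma_u"]
    total = 0.0
    for g in range(n_grids):
        sel = gidx == g

        def integrand(u):
            ll = zinb_logpmf(y[sel], pi, np.exp(np.clip(eta[sel] + u, -30, 30)), theta)
            return np.exp(ll.sum()) * stats.norm.pdf(u, 0.0, sigma)

        val, _ = integrate.quad(integrand, -10 * sigma, 10 * sigma, limit=200,
                                epsabs=1e-13, epsrel=1e-11)
        total += np.log(val)
    return total


class TestMarginalLoglik:
    def _params(self, **kw):
        p = {"theta": 1.4, "pi": 0.25, "sigma_u": 0.7}
        p.update(kw)
        return p

    def test_sigma_zero_degenerates_to_plain_sum(self, toy_zinb_data):
        y, x, gidx = toy_zinb_data
        eta = 0.3 + 0.5 * x
        p = self._params(sigma_u=0.0)
        want = zinb_logpmf(y, p["pi"], np.exp(eta), p["theta"]).sum()
        got = marginal_loglik(p, y, eta, gidx, 3)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("sigma", [0.3, 0.7, 1.5])
    def test_quadrature_matches_brute_force_integration(self, toy_zinb_data, sigma):
        y, x, gidx = toy_zinb_data
        eta = 0.3 + 0.5 * x
        p = self._params(sigma_u=sigma)
        want = brute_force_marginal(p, y, eta, gidx, 3)
        got = marginal_loglik(p, y, eta, gidx, 3, nodes=15)
        assert got == pytest.approx(want, abs=1e-6)

    def test_node_count_converged(self, toy_zinb_data):
        y, x, gidx = toy_zinb_data
        eta = 0.3 + 0.5 * x
        p = self._params()
        a = marginal_loglik(p, y, eta, gidx, 3, nodes=31)
        b = marginal_loglik(p, y, eta, gidx, 3, nodes=63)
        assert a == pytest.approx(b, abs=1e-8)

    def test_laplace_single_node_close(self, toy_zinb_data):
        y, x, gidx = toy_zinb_data
        eta = 0.3 + 0.5 * x
        p = self._params(sigma_u=0.4)
        laplace = marginal_loglik(p, y, eta, gidx, 3, nodes=1)
        exact = brute_force_marginal(p, y, eta, gidx, 3)
        assert laplace == pytest.approx(exact, abs=0.1)


class TestFit:
    def test_recovers_truth_within_wald_cis(self, marula_adult_fit):
        # single-replicate recovery; the full coverage study is the
        # calibration suite in the acceptance tests
        fit = marula_adult_fit
        assert fit.converged
        truth = {"beta2": -0.10, "log_theta": np.log(1.5),
                 "logit_pi": np.log(0.2 / 0.8), "log_sigma_u": np.log(0.4)}
        tab = wald_table(fit).set_index("term")
        for term, true_val in truth.items():
            lo, hi = tab.loc[term, "ci_lo"], tab.loc[term, "ci_hi"]
            assert lo - 0.5 < true_val < hi + 0.5  # generous single-draw check

    def test_aic_identity(self, marula_adult_fit):
        fit = marula_adult_fit
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-9)

    def test_multistart_agreement(self, count_table):
        lls = [fit_zinb_glmm(ModelSpec("marula", "adult"), count_table,
                             n_starts=k, compute_vcov=False).loglik
               for k in (1, 2, 3)]
        assert max(lls) - min(lls) < 1e-6

    def test_sigma_zero_truth_hits_boundary(self, scene):
        from nicheshift.survey_data import build_count_table
        from nicheshift.synthetic_scene import TruthParams, simulate_trees

        tp = TruthParams("marula", "adult", beta0=-38.0, x_opt=20.0, beta2=-0.1,
                         sigma_u=0.0, theta=2.0, pi=0.1)
        # ML of a zero variance component sits at/near the boundary in the
        # typical draw; individual draws can absorb overdispersion into
        # sigma, so test the median over a few seeds
        sigmas, flags = [], []
        for s in (21, 22, 23, 24):
            recs = simulate_trees(scene.design, [tp], scene.stack, scene.spec, seed=s)
            tab = build_count_table(recs, scene.design, scene.stack)
            fit = fit_zinb_glmm(ModelSpec("marula", "adult"), tab, compute_vcov=False)
            sigmas.append(fit.params["sigma_u"])
            flags.append(fit.boundary["sigma_zero"])
        assert np.median(sigmas) < 0.1
        assert sum(flags) >= 2

    def test_paper_mode_uses_corrected_counts(self, count_table):
        fit = fit_zinb_glmm(ModelSpec("marula", "young", mode="paper"),
                            count_table, compute_vcov=False, n_starts=1)
        # x20 counts: intercept ~ log(20) higher than the offset-mode fit
        fit_off = fit_zinb_glmm(ModelSpec("marula", "young", mode="offset"),
                                count_table, compute_vcov=False, n_starts=1)
        assert fit.n_obs == fit_off.n_obs

    def test_too_few_grids_rejected(self, count_table):
        sub = count_table[count_table.grid_id == count_table.grid_id.iloc[0]]
        with pytest.raises(ValueError, match="grids"):
            fit_zinb_glmm(ModelSpec("marula", "adult"), sub)


class TestCompareAIC:
    def _fake_fit(self, marula_adult_fit, aic_shift, cov):
        import copy

        f = copy.copy(marula_adult_fit)
        f.spec = ModelSpec("marula", "adult", covariate=cov)
        f.loglik = marula_adult_fit.loglik - aic_shift / 2.0
        return f

    def test_single_model_competing(self, marula_adult_fit):
        df = compare_aic([marula_adult_fit])
        assert df["delta_aic"].iloc[0] == 0.0
        assert df["competing"].iloc[0]

    def test_competing_within_two_units(self, marula_adult_fit):
        fits = [marula_adult_fit, self._fake_fit(marula_adult_fit, 0.6, "pet")]
        df = compare_aic(fits)
        assert df["competing"].all()
        assert df["delta_aic"].max() == pytest.approx(0.6)

    def test_three_units_not_competing(self, marula_adult_fit):
        fits = [marula_adult_fit, self._fake_fit(marula_adult_fit, 3.0, "pet")]
        df = compare_aic(fits)
        assert not df.loc[df.covariate == "pet", "competing"].iloc[0]

    def test_delta_invariant_to_loglik_shift(self, marula_adult_fit):
        fits = [marula_adult_fit, self._fake_fit(marula_adult_fit, 3.0, "pet")]
        d1 = compare_aic(fits)["delta_aic"].to_numpy()
        for f in fits:
            f.loglik += 100.0
        d2 = compare_aic(fits)["delta_aic"].to_numpy()
        np.testing.assert_allclose(np.sort(d1), np.sort(d2), atol=1e-9)

    def test_mixed_responses_rejected(self, marula_adult_fit, count_table):
        other = fit_zinb_glmm(ModelSpec("knobthorn", "adult"), count_table,
                              n_starts=1, compute_vcov=False)
        with pytest.raises(ValueError, match="different"):
            compare_aic([marula_adult_fit, other])


class TestWald:
    def test_closed_form_example(self, marula_adult_fit):
        import copy

        f = copy.copy(marula_adult_fit)
        f.estimates = np.array([2.0, 0.5, -1.0, 0.0, 0.0, 0.0])
        f.vcov = np.eye(6)
        tab = wald_table(f)
        row = tab.iloc[0]
        assert row.z == pytest.approx(2.0)
        assert row.p == pytest.approx(0.0455, abs=3e-4)
        assert (row.ci_lo, row.ci_hi) == (pytest.approx(2 - Z975), pytest.approx(2 + Z975))
        assert row.relevant
        assert not tab.iloc[1].relevant  # est 0.5, SE 1: CI includes 0

    def test_ci_excludes_zero_iff_z_exceeds_critical(self, marula_adult_fit):
        rng = np.random.default_rng(3)
        import copy

        for _ in range(20):
            f = copy.copy(marula_adult_fit)
            f.estimates = rng.normal(0, 2, size=6)
            d = rng.uniform(0.1, 2, size=6)
            f.vcov = np.diag(d**2)
            tab = wald_table(f)
            excl = (tab.ci_lo > 0) | (tab.ci_hi < 0)
            np.testing.assert_array_equal(excl, np.abs(tab.z) > Z975)
            np.testing.assert_array_equal(tab.relevant, excl)


class TestOptimumAndPrediction:
    def test_vertex_formula(self, marula_adult_fit):
        import copy

        f = copy.copy(marula_adult_fit)
        f.params = dict(f.params, beta1=1.2, beta2=-0.02)
        assert climate_optimum(f, se=False)["optimum"] == pytest.approx(30.0)

    def test_convex_fit_reports_monotone(self, marula_adult_fit):
        import copy

        f = copy.copy(marula_adult_fit)
        f.params = dict(f.params, beta1=0.5, beta2=0.01)
        out = climate_optimum(f)
        assert out["optimum"] is None
        assert out["monotone"] == "increasing"

    def test_optimum_matches_grid_search(self, marula_adult_fit):
        fit = marula_adult_fit
        xs = np.linspace(*fit.x_range, 20001)
        preds = predict_expected(fit, xs)
        x_grid = xs[np.argmax(preds)]
        x_star = climate_optimum(fit, se=False)["optimum"]
        assert abs(x_star - x_grid) <= (xs[1] - xs[0]) * 1.01

    def test_structural_zeros_scale_prediction(self, marula_adult_fit):
        import copy

        f0 = copy.copy(marula_adult_fit)
        f0.params = dict(f0.params, pi=0.0)
        f5 = copy.copy(marula_adult_fit)
        f5.params = dict(f5.params, pi=0.5)
        x = np.linspace(*marula_adult_fit.x_range, 7)
        np.testing.assert_allclose(predict_expected(f5, x),
                                   0.5 * predict_expected(f0, x), rtol=1e-12)

    def test_marginal_exceeds_population_mean(self, marula_adult_fit):
        x = np.array([marula_adult_fit.x_mean])
        pop = predict_expected(marula_adult_fit, x, level="population")
        marg = predict_expected(marula_adult_fit, x, level="marginal")
        assert marg >= pop

    def test_extrapolation_warns(self, marula_adult_fit):
        with pytest.warns(UserWarning, match="beyond the fitted"):
            predict_expected(marula_adult_fit, marula_adult_fit.x_range[1] + 50.0)

    def test_prediction_matches_simulated_means(self, scene):
        # simulation oracle: empirical transect means track the model mean
        from nicheshift.survey_data import build_count_table
        from nicheshift.synthetic_scene import TruthParams, simulate_trees

        tp = TruthParams("marula", "adult", beta0=-38.0, x_opt=20.0, beta2=-0.1,
                         sigma_u=0.0, theta=3.0, pi=0.0)
        counts = np.zeros(len(scene.design.transects))
        n_rep = 200
        for s in range(n_rep):
            recs = simulate_trees(scene.design, [tp], scene.stack, scene.spec,
                                  seed=5000 + s)
            tab = build_count_table(recs, scene.design)
            sub = tab[(tab.species == "marula") & (tab.size_class == "adult")] \
                .sort_values("transect_id")
            counts += sub["count"].to_numpy()
        emp = counts / n_rep
        tab = build_count_table(recs, scene.design, scene.stack)
        sub = tab[(tab.species == "marula") & (tab.size_class == "adult")] \
            .sort_values("transect_id")
        x = sub["annual_mean_temp"].to_numpy()
        mu = tp.mean_at(x)
        se = np.sqrt(np.asarray(mu) * (1 + np.asarray(mu) / tp.theta) / n_rep)
        assert np.mean(np.abs(emp - mu) < 4 * se + 0.02) > 0.95


class TestR2:
    def test_conditional_at_least_marginal(self, marula_adult_fit, count_table):
        r2m, r2c = nakagawa_r2(marula_adult_fit, count_table)
        assert 0 <= r2m <= r2c <= 1

    def test_intercept_only_fixed_effects_zero_marginal(self, marula_adult_fit, count_table):
        import copy

        f = copy.copy(marula_adult_fit)
        f.params = dict(f.params, beta1=0.0, beta2=0.0)
        r2m, _ = nakagawa_r2(f, count_table)
        assert r2m == pytest.approx(0.0, abs=1e-12)

    def test_strong_effect_high_marginal_r2(self, scene):
        # sharply hump-shaped truth, small grid variance, mild overdispersion:
        # the fixed effects should explain most of the latent variation
        from nicheshift.survey_data import build_count_table
        from nicheshift.synthetic_scene import TruthParams, simulate_trees

        tp = TruthParams("marula", "adult", beta0=-207.1, x_opt=20.5, beta2=-0.5,
                         sigma_u=0.1, theta=5.0, pi=0.1)
        recs = simulate_trees(scene.design, [tp], scene.stack, scene.spec, seed=31)
        tab = build_count_table(recs, scene.design, scene.stack)
        fit = fit_zinb_glmm(ModelSpec("marula", "adult"), tab, n_starts=2)
        r2m, r2c = nakagawa_r2(fit, tab)
        assert r2m > 0.5
        assert r2c >= r2m
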