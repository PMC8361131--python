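"""Scale fitting: oracle equivalence (exhaustive grid search and a probit
GLM), parameter recovery, nested-likelihood ordering, LR tests, bootstrap
and cross-observer averaging."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import stats as sstats

from metalsense.fitting import (
    SeparationWarning,
    bootstrap_ci,
    fit_mlcm,
    fit_mlds,
    lr_test,
    normalize_and_average,
)
from metalsense.trials import (
    ModelObserver,
    build_mlcm_session,
    build_mlds_session,
    enumerate_mlcm_pairs,
    enumerate_mlds_quadruples,
    simulate_responses,
)


def additive_session(psi_s, psi_b, noise_sd=1.0, n_repeats=4, n_views=8, seed=0):
    """Simulate an additive observer: statistic value = psi_S(s) + psi_B(b),
    identical across views, Gaussian decision noise."""
    n_s, n_b = len(psi_s), len(psi_b)
    table = {(s, b, v): psi_s[s] + psi_b[b]
             for s in range(n_s) for b in range(n_b) for v in range(n_views)}
    session = build_mlcm_session(enumerate_mlcm_pairs(n_s, n_b),
                                 n_repeats=n_repeats, n_views=n_views, seed=seed)
    return simulate_responses(
        session, ModelObserver("synthetic", noise_sd, seed=seed + 1), table)


def mlds_session(psi, noise_sd=1.0, n_repeats=4, n_views=8, seed=0):
    table = {(lvl, v): psi[lvl] for lvl in range(len(psi)) for v in range(n_views)}
    quads = enumerate_mlds_quadruples(len(psi)) * n_repeats
    session = build_mlds_session(quads, "smoothness", n_views=n_views, seed=seed)
    return simulate_responses(
        session, ModelObserver("synthetic", noise_sd, seed=seed + 1), table)


class TestGridSearchOracle:
    """The optimizer attains the exhaustive grid-search likelihood maximum
    on small problems (grid step 0.05)."""

    @staticmethod
    def _loglik(X, y, beta):
        z = (2 * y - 1) * (X @ beta)
        return sstats.norm.logcdf(z).sum()

    def test_mlcm_additive_2x2(self):
        trials = additive_session([0.0, 1.2], [0.0, -0.8], noise_sd=1.0,
                                  n_repeats=4, n_views=4, seed=0)[:40]
        fit = fit_mlcm(trials, "additive")
        # exhaustive search over the two free parameters
        X = np.array([[int(t.cond_1[0] == 1) - int(t.cond_2[0] == 1),
                       int(t.cond_1[1] == 1) - int(t.cond_2[1] == 1)]
                      for t in trials], dtype=float)
        y = np.array([t.response for t in trials], dtype=float)
        grid = np.arange(-3, 3 + 1e-9, 0.05)
        gg = np.array(np.meshgrid(grid, grid)).reshape(2, -1).T
        lls = sstats.norm.logcdf(
            (2 * y - 1)[None, :] * (gg @ X.T)).sum(axis=1)
        best = gg[np.argmax(lls)]
        assert fit.log_likelihood >= lls.max() - 1e-6
        assert fit.psi_s[1] == pytest.approx(best[0], abs=0.1)
        assert fit.psi_b[1] == pytest.approx(best[1], abs=0.1)

    def test_mlds_attains_grid_maximum_likelihood(self):
        """On a 4-level design the likelihood depends on a single contrast;
        the optimizer's maximum matches the exhaustive scan over it."""
        trials = mlds_session([0.0, 1.0, 1.8, 3.0], noise_sd=1.0,
                              n_repeats=40, n_views=8, seed=0)[:40]
        fit = fit_mlds(trials)
        k = sum(t.response for t in trials)
        n = len(trials)
        zgrid = np.arange(-3, 3 + 1e-9, 0.05)
        lls = (k * sstats.norm.logcdf(zgrid)
               + (n - k) * sstats.norm.logcdf(-zgrid))
        assert fit.log_likelihood >= lls.max() - 1e-6


class TestProbitGLMOracle:
    """statsmodels' probit GLM is an independent route to the same MLE."""

    def test_additive_fit_matches_glm(self):
        import statsmodels.api as sm

        trials = additive_session([0, 1, 2, 3, 4], [0, -0.5, -1, -1.5, -2],
                                  noise_sd=1.0, seed=11)
        fit = fit_mlcm(trials, "additive")
        n_s = n_b = 5
        X = np.zeros((len(trials), 8))
        for r, t in enumerate(trials):
            for (s, b), w in ((t.cond_1, 1.0), (t.cond_2, -1.0)):
                if s > 0:
                    X[r, s - 1] += w
                if b > 0:
                    X[r, 4 + b - 1] += w
        y = np.array([t.response for t in trials], dtype=float)
        glm = sm.GLM(y, X, family=sm.families.Binomial(
            sm.families.links.Probit())).fit()
        ours = np.concatenate([fit.psi_s[1:], fit.psi_b[1:]])
        np.testing.assert_allclose(ours, glm.params, atol=1e-3)

    def test_mlds_fit_matches_glm(self):
        import statsmodels.api as sm

        trials = mlds_session([0, 1, 2, 3, 4, 5], noise_sd=1.0, seed=4)
        fit = fit_mlds(trials)
        levels = 6
        X = np.zeros((len(trials), levels - 1))
        y = np.empty(len(trials))
        for r, t in enumerate(trials):
            a, b, c, d = t.levels
            for lvl, w in ((b, 1.0), (a, -1.0), (c, 1.0), (d, -1.0)):
                if lvl > 0:
                    X[r, lvl - 1] += w
            y[r] = t.response
        glm = sm.GLM(y, X, family=sm.families.Binomial(
            sm.families.links.Probit())).fit()
        np.testing.assert_allclose(fit.psi[1:], glm.params, atol=1e-3)


class TestMLDS:
    def test_noise_free_recovery_is_rank_identical(self):
        trials = mlds_session([0, 1, 2, 3, 4], noise_sd=0.0, n_repeats=62)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            fit = fit_mlds(trials)
        assert np.all(np.diff(fit.psi) > 0)

    def test_noisy_recovery_accuracy(self):
        """Mean absolute error below 0.5 d-prime at full design size."""
        psi_true = np.linspace(0, 6, 11)
        errors = []
        for seed in range(5):
            trials = mlds_session(list(psi_true), noise_sd=1.0,
                                  n_repeats=4, seed=seed)
            fit = fit_mlds(trials)
            errors.append(np.mean(np.abs(fit.psi - psi_true)))
        assert np.mean(errors) < 0.5

    def test_direct_method_agrees_with_linearization(self):
        # generous noise and repeats keep the problem well-conditioned
        # (away from separation, where the two surfaces differ)
        trials = mlds_session([0, 0.6, 1.2, 1.8, 2.4], noise_sd=1.5,
                              n_repeats=30, seed=0)
        signed = fit_mlds(trials, method="signed")
        direct = fit_mlds(trials, method="direct")
        np.testing.assert_allclose(direct.psi, signed.psi, atol=0.05)
        assert direct.log_likelihood >= signed.log_likelihood - 1e-6

    def test_degenerate_design_rejected(self):
        """A 2-level design admits no quadruples at all."""
        assert enumerate_mlds_quadruples(2) == []
        with pytest.raises(ValueError):
            fit_mlds([])

    def test_anchoring(self):
        trials = mlds_session([0, 1, 2, 3, 4], noise_sd=1.0)
        assert fit_mlds(trials).psi[0] == 0.0


class TestMLCM:
    def test_additive_recovery(self):
        psi_s = np.array([0, 1, 2, 3, 4], dtype=float)
        psi_b = np.array([0, -0.5, -1, -1.5, -2])
        errs = []
        for seed in range(5):
            fit = fit_mlcm(additive_session(psi_s, psi_b, seed=seed), "additive")
            errs.append(np.mean(np.abs(np.concatenate([fit.psi_s - psi_s,
                                                       fit.psi_b - psi_b]))))
        assert np.mean(errs) < 0.5

    def test_independent_truth_gives_small_bumpiness_terms(self):
        """When only smoothness drives the observer, the fitted bumpiness
        contributions are small and their CIs overwhelmingly include 0
        (each interval misses with ~5% probability by construction)."""
        fit = fit_mlcm(additive_session([0, 1, 2, 3, 4], [0, 0, 0, 0, 0],
                                        seed=2), "additive")
        boot = bootstrap_ci(additive_session([0, 1, 2, 3, 4], [0] * 5, seed=2),
                            "additive", n_boot=100, seed=3)
        contains_zero = ((boot.ci["psi_b_low"][1:] <= 0)
                         & (boot.ci["psi_b_high"][1:] >= 0))
        assert contains_zero.sum() >= 3
        assert np.max(np.abs(fit.psi_b)) < 0.4

    def test_likelihood_ordering_of_nested_classes(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=5)
        ind = fit_mlcm(trials, "independent")
        add = fit_mlcm(trials, "additive")
        sat = fit_mlcm(trials, "saturated")
        assert sat.log_likelihood >= add.log_likelihood - 1e-6
        assert add.log_likelihood >= ind.log_likelihood - 1e-6

    def test_parameter_counts(self):
        trials = additive_session([0, 1, 2, 3, 4], [0, -1, -2, -3, -4], seed=0)
        assert fit_mlcm(trials, "independent").n_parameters == 4
        assert fit_mlcm(trials, "additive").n_parameters == 8
        assert fit_mlcm(trials, "saturated").n_parameters == 24

    def test_anchors_exactly_zero(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=1)
        fit = fit_mlcm(trials, "additive")
        assert fit.psi_s[0] == 0.0 and fit.psi_b[0] == 0.0
        sat = fit_mlcm(trials, "saturated")
        assert sat.psi_cell[0, 0] == 0.0

    def test_order_invariance(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=7)
        rng = np.random.default_rng(0)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        a = fit_mlcm(trials, "additive")
        b = fit_mlcm(shuffled, "additive")
        np.testing.assert_allclose(a.psi_s, b.psi_s, atol=1e-6)

    def test_all_identical_responses_warns_not_crashes(self):
        trials = additive_session([0, 1, 2], [0, 0, 0], n_views=4, seed=0)
        trials = [dataclasses.replace(t, response=1) for t in trials]
        with pytest.warns(SeparationWarning):
            fit_mlcm(trials, "independent", independent_dimension="smoothness")

    def test_unknown_class_rejected(self):
        trials = additive_session([0, 1], [0, 1], n_views=4, seed=0)
        with pytest.raises(ValueError):
            fit_mlcm(trials, "kitchen-sink")


class TestLRTest:
    def test_identical_models_give_null_result(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=0)
        add = fit_mlcm(trials, "additive")
        nested = dataclasses.replace(add, n_parameters=add.n_parameters - 4)
        res = lr_test(nested, add)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_df_for_independent_vs_additive_on_5x5(self):
        trials = additive_session([0, 1, 2, 3, 4], [0, -1, -2, -3, -4], seed=0)
        res = lr_test(fit_mlcm(trials, "independent"),
                      fit_mlcm(trials, "additive"))
        assert res.df == 4

    def test_additive_truth_detected(self):
        trials = additive_session([0, 1, 2, 3, 4], [0, -0.5, -1, -1.5, -2],
                                  seed=3)
        res = lr_test(fit_mlcm(trials, "independent"),
                      fit_mlcm(trials, "additive"))
        assert res.p_value < 0.001

    def test_same_data_required(self):
        t1 = additive_session([0, 1], [0, 1], n_views=4, seed=0)
        t2 = additive_session([0, 1], [0, 1], n_views=4, seed=1)[:10]
        with pytest.raises(ValueError):
            lr_test(fit_mlcm(t1, "independent"), fit_mlcm(t2, "additive"))


class TestBootstrap:
    def test_zero_replicates_rejected(self):
        trials = additive_session([0, 1], [0, 1], n_views=4, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(trials, n_boot=0)

    def test_intervals_bracket_estimates(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=0)
        fit = bootstrap_ci(trials, "additive", n_boot=100, seed=1)
        assert np.all(fit.ci["psi_s_low"] <= fit.psi_s + 1e-9)
        assert np.all(fit.psi_s <= fit.ci["psi_s_high"] + 1e-9)

    def test_reproducible_by_seed(self):
        trials = additive_session([0, 1, 2], [0, -1, -2], n_views=4, seed=0)
        a = bootstrap_ci(trials, "additive", n_boot=50, seed=5)
        b = bootstrap_ci(trials, "additive", n_boot=50, seed=5)
        np.testing.assert_array_equal(a.ci["psi_s_low"], b.ci["psi_s_low"])

    def test_noise_free_observer_gives_narrow_mlds_intervals(self):
        trials = mlds_session([0, 2, 4, 6, 8], noise_sd=0.0, n_repeats=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            fit = bootstrap_ci(trials, n_boot=50, seed=0)
        # deterministic data: resampling changes nothing qualitative
        assert np.all(fit.ci_high - fit.ci_low < 1.0)


class TestAveraging:
    def _fit(self, seed=0):
        return fit_mlcm(additive_session([0, 1, 2], [0, -1, -2],
                                         n_views=4, seed=seed), "additive")

    def test_single_fit_returns_itself_normalized(self):
        f = self._fit()
        avg = normalize_and_average([f])
        pooled = np.concatenate([f.psi_s, f.psi_b])
        norm = np.sqrt(np.mean(pooled**2))
        np.testing.assert_allclose(avg["psi_s_mean"], f.psi_s / norm)
        assert np.all(avg["psi_s_sem"] == 0)

    def test_two_identical_fits_zero_sem(self):
        f = self._fit()
        avg = normalize_and_average([f, f])
        np.testing.assert_allclose(avg["psi_s_sem"], 0, atol=1e-12)

    def test_scale_invariance_by_construction(self):
        f = self._fit()
        scaled = dataclasses.replace(f, psi_s=10 * f.psi_s, psi_b=10 * f.psi_b)
        a = normalize_and_average([f, f])
        b = normalize_and_average([f, scaled])
        np.testing.assert_allclose(a["psi_s_mean"], b["psi_s_mean"], atol=1e-12)
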