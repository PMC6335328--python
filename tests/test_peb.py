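"""Bayesian model reduction and the group-level PEB model."""

import numpy as np
import pytest

from bdc import (
    DesignMatrix,
    GaussianDensity,
    ReducedPriorSpec,
    ScalarGaussian,
    SimulationConfig,
    TimeseriesData,
    bayesian_model_reduction,
    default_covariance_components,
    empirical_bayes_update,
    fit_dataset,
    fit_glm_vb,
    fit_peb,
    generate_dataset,
    log_evidence_linear_gaussian,
)
from bdc.glm import ModelFit
from bdc.peb import GroupModel, InvalidReductionError, PebConfig, reduce_gaussian

from conftest import make_linear_gaussian_fit


def analytic_reduction_df(fit, y, X, tau, off_idx):
    """Oracle: evidence difference from refitting with columns removed.

    Switched-off coefficients are fixed at their prior means, so their
    contribution moves into the data offset.
    """
    keep = [j for j in range(X.p) if j not in off_idx]
    y_adj = TimeseriesData(y.response - X.values[:, off_idx] @ fit.prior.mean[off_idx])
    Xr = DesignMatrix(X.values[:, keep], [X.column_labels[j] for j in keep])
    pr = GaussianDensity(
        fit.prior.mean[keep], fit.prior.cov[np.ix_(keep, keep)], Xr.column_labels
    )
    return log_evidence_linear_gaussian(y_adj, Xr, pr, tau) - log_evidence_linear_gaussian(
        y, X, fit.prior, tau
    )


class TestBayesianModelReduction:
    def test_identity_reduction_is_exact_zero(self, rng):
        fit, *_ = make_linear_gaussian_fit(rng)
        post, dF = bayesian_model_reduction(fit, ReducedPriorSpec())
        assert dF == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(post.mean, fit.posterior.mean, atol=1e-9)
        np.testing.assert_allclose(post.cov, fit.posterior.cov, atol=1e-9)

    def test_matches_analytic_evidence_difference(self, rng):
        worst = 0.0
        for i in range(100):
            fit, y, X, tau = make_linear_gaussian_fit(rng)
            _, dF = bayesian_model_reduction(fit, ReducedPriorSpec(("b1", "b3")))
            oracle = analytic_reduction_df(fit, y, X, tau, [1, 3])
            worst = max(worst, abs(dF - oracle))
        assert worst < 1e-6

    def test_null_parameter_switch_off_is_nearly_free(self, rng):
        # when the data leave a zero-valued coefficient's posterior close
        # to its prior, eliminating it barely moves the evidence
        n, p, tau = 40, 3, 0.002
        X = DesignMatrix(rng.normal(size=(n, p)), ["a", "b", "null"])
        beta = np.array([1.0, -0.7, 0.0])
        costs = []
        for _ in range(20):
            y = TimeseriesData(X.values @ beta + rng.normal(0, tau**-0.5, n))
            prior = GaussianDensity(np.zeros(p), np.eye(p), X.column_labels)
            fit = fit_glm_vb(y, X, prior, noise_prior=ScalarGaussian(np.log(tau), 0.0))
            _, dF = bayesian_model_reduction(fit, ReducedPriorSpec(("null",)))
            costs.append(abs(dF))
        assert np.median(costs) < 0.05

    def test_compositional_over_switch_off_sets(self, rng):
        fit, *_ = make_linear_gaussian_fit(rng, p=5)
        post_a, dF_a = reduce_gaussian(fit.prior, fit.posterior, ReducedPriorSpec(("b1",)))
        prior_a = fit.prior.marginal(list(post_a.labels))
        post_ab, dF_b = reduce_gaussian(prior_a, post_a, ReducedPriorSpec(("b3",)))
        post_direct, dF_direct = reduce_gaussian(
            fit.prior, fit.posterior, ReducedPriorSpec(("b1", "b3"))
        )
        assert dF_a + dF_b == pytest.approx(dF_direct, abs=1e-8)
        np.testing.assert_allclose(post_ab.mean, post_direct.mean, atol=1e-8)
        np.testing.assert_allclose(post_ab.cov, post_direct.cov, atol=1e-8)

    def test_cannot_switch_off_everything(self, rng):
        fit, *_ = make_linear_gaussian_fit(rng, p=2)
        with pytest.raises(InvalidReductionError):
            bayesian_model_reduction(fit, ReducedPriorSpec(("b0", "b1")))


@pytest.fixture(scope="module")
def clamped_noise_fits():
    """16 simulated subjects fitted with known noise (exact evidences)."""
    cfg = SimulationConfig(n_subjects=16, master_seed=3)
    ds = generate_dataset(cfg, 0, 99)
    prior = GaussianDensity(np.zeros(3), np.eye(3), ds.subjects[0][1].column_labels)
    fits, taus = [], []
    for (y, X, beta) in ds.subjects:
        nv = float(np.var(y.response - X.values @ beta))
        taus.append(1.0 / nv)
        fits.append(
            fit_glm_vb(
                y, X, prior,
                noise_prior=ScalarGaussian(np.log(taus[-1]), 0.0),
                tol=1e-10, max_iter=200,
            )
        )
    return cfg, ds, fits, taus


class TestFitPeb:
    def test_fixed_gamma_matches_collapsed_hierarchy(self, clamped_noise_fits):
        """At clamped gamma the PEB posterior must equal the posterior of the
        one-level model obtained by marginalizing subject effects."""
        cfg, ds, fits, taus = clamped_noise_fits
        gm = fit_peb(fits, config=PebConfig(gamma_prior=ScalarGaussian(0.0, 0.0)))
        Q0, Q1 = default_covariance_components(3)
        Sb = np.linalg.inv(Q0 + Q1)
        prec = np.eye(3)
        lin = np.zeros(3)
        for (y, X, _beta), tau in zip(ds.subjects, taus):
            V = X.values @ Sb @ X.values.T + np.eye(cfg.n_scans) / tau
            Vi = np.linalg.inv(V)
            prec += X.values.T @ Vi @ X.values
            lin += X.values.T @ Vi @ y.response
        cov = np.linalg.inv(prec)
        mean = cov @ lin
        np.testing.assert_allclose(gm.beta_posterior.mean, mean, atol=1e-4)
        np.testing.assert_allclose(gm.beta_posterior.cov, cov, atol=1e-4)

    def test_degenerate_hierarchy_tracks_single_subject(self, clamped_noise_fits):
        # N copies of one subject + between-subject precision forced very
        # high: the group mean collapses onto that subject's posterior mean
        # (up to the vanishing 1/N share of the group-level prior pull)
        _cfg, _ds, fits, _taus = clamped_noise_fits
        copies = [fits[0]] * 8
        gm = fit_peb(copies, config=PebConfig(gamma_prior=ScalarGaussian(-8.0, 0.0)))
        np.testing.assert_allclose(
            gm.beta_posterior.mean, fits[0].posterior.mean, atol=0.02
        )

    def test_subject_order_invariance(self, clamped_noise_fits):
        _cfg, _ds, fits, _taus = clamped_noise_fits
        a = fit_peb(fits)
        b = fit_peb(fits[::-1])
        assert a.free_energy == pytest.approx(b.free_energy, abs=1e-8)
        np.testing.assert_allclose(a.beta_posterior.mean, b.beta_posterior.mean, atol=1e-10)

    def test_gamma_tracks_between_subject_variance(self):
        """Larger generating sigma_B^2 must yield larger gamma (lower
        between-subject precision, Pi = Q0 + exp(-gamma) Q1)."""
        gammas = []
        for sb in (0.05, 0.18, 0.5):
            cfg = SimulationConfig(n_subjects=16, between_var=sb, master_seed=11)
            fits = fit_dataset(generate_dataset(cfg, 0, 99), cfg)
            gammas.append(fit_peb(fits).gamma_posterior.mean)
        assert gammas[0] < gammas[1] < gammas[2]

    def test_needs_two_subjects(self, clamped_noise_fits):
        with pytest.raises(ValueError):
            fit_peb(clamped_noise_fits[2][:1])

    def test_well_specified_coverage_is_nominal(self):
        """When data are drawn from the model's own priors, the 90% group
        credible intervals must cover at close to the nominal rate."""
        z90 = 1.6448536269514722
        rng = np.random.default_rng(5)
        hits, total = 0, 0
        for e in range(100):
            mu = rng.normal(0, 1, 3)
            gamma = rng.normal(0, 0.25)
            sb = 1.0 / (1 / 128 + 16 * np.exp(-gamma))
            cfg = SimulationConfig(
                n_subjects=16, snr_grid=np.array([0.5]), n_experiments=1,
                group_means=mu, between_var=sb, master_seed=3000 + e,
            )
            fits = fit_dataset(generate_dataset(cfg, 0, 0), cfg)
            g = fit_peb(fits)
            sd = np.sqrt(np.diag(g.beta_posterior.cov))
            hits += int(np.sum(np.abs(g.beta_posterior.mean - mu) <= z90 * sd))
            total += 3
        assert 0.84 <= hits / total <= 0.96


class TestEmpiricalBayesUpdate:
    def test_group_matching_original_prior_changes_nothing(self, rng):
        fit, *_ = make_linear_gaussian_fit(rng, p=3)
        # craft a group model whose posterior predictive equals the prior
        Q0, Q1 = default_covariance_components(3)
        Sb = np.linalg.inv(Q0 + Q1)
        gm = GroupModel(
            n_subjects=2,
            beta_prior=fit.prior,
            beta_posterior=GaussianDensity(fit.prior.mean, fit.prior.cov - Sb, fit.labels),
            gamma_prior=ScalarGaussian(0.0, 1 / 16),
            gamma_posterior=ScalarGaussian(0.0, 0.0),
            Q0=Q0, Q1=Q1, free_energy=0.0,
        )
        updated = empirical_bayes_update(fit, gm)
        assert updated.free_energy == pytest.approx(fit.free_energy, abs=1e-8)
        np.testing.assert_allclose(updated.posterior.mean, fit.posterior.mean, atol=1e-8)

    def test_updated_means_shrink_toward_group_mean(self, clamped_noise_fits):
        _cfg, _ds, fits, _taus = clamped_noise_fits
        gm = fit_peb(fits)
        for fit in fits[:5]:
            upd = empirical_bayes_update(fit, gm)
            lo = np.minimum(fit.posterior.mean, gm.beta_posterior.mean) - 1e-9
            hi = np.maximum(fit.posterior.mean, gm.beta_posterior.mean) + 1e-9
            assert np.all(upd.posterior.mean >= lo) and np.all(upd.posterior.mean <= hi)

    def test_refit_after_update_is_a_fixed_point(self, clamped_noise_fits):
        _cfg, _ds, fits, _taus = clamped_noise_fits
        gm = fit_peb(fits)
        updated = [empirical_bayes_update(f, gm) for f in fits]
        refit = fit_peb(updated, beta_prior=gm.beta_prior)
        np.testing.assert_allclose(
            refit.beta_posterior.mean, gm.beta_posterior.mean, atol=1e-3
        )
        np.testing.assert_allclose(
            refit.beta_posterior.cov, gm.beta_posterior.cov, atol=1e-3
        )


class TestCovarianceComponents:
    def test_zero_gamma_precision_is_q0_plus_q1(self):
        Q0, Q1 = default_covariance_components(4)
        prec = Q0 + np.exp(-0.0) * Q1
        np.testing.assert_allclose(prec, Q0 + Q1)

    def test_large_gamma_leaves_precision_floor(self):
        Q0, Q1 = default_covariance_components(2)
        prec = Q0 + np.exp(-40.0) * Q1
        np.testing.assert_allclose(prec, Q0, atol=1e-10)

    def test_precision_positive_definite_across_gamma_sweep(self):
        Q0, Q1 = default_covariance_components(3)
        for gamma in np.linspace(-10, 10, 41):
            w = np.linalg.eigvalsh(Q0 + np.exp(-gamma) * Q1)
            assert w.min() > 0

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            default_covariance_components(0)
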