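"""Neural posterior estimation: prior sampling, training-set construction,
flow training contracts, posterior consistency, the collective posterior
against a conjugate analytic oracle, posterior predictive checks, and the
fitness transforms."""

import math

import numpy as np
import pytest
from scipy import stats

from cnvrevert.inference import (
    PosteriorSamples,
    PriorSpec,
    build_training_set,
    collective_posterior,
    fitness_transforms,
    posterior_predictive_check,
    posterior_sample,
    sample_prior,
    save_posterior_samples,
    save_training_set,
    train_npe,
    _simulate_theta_batch,
)
from cnvrevert.wf import PopulationConfig

TINY_FLOW = dict(
    n_transforms=2, hidden=16, n_networks=1, noise_replicates=2,
    batch_size=100, max_epochs=10, patience=5,
)


def small_config():
    return PopulationConfig(N=10_000, T=60, sample_gens=tuple(range(0, 61, 12)))


class TestPrior:
    def test_support(self):
        prior = PriorSpec()
        theta = sample_prior(prior, 500, np.random.default_rng(0))
        assert np.all(theta >= prior.lo) and np.all(theta <= prior.hi)

    def test_log_uniform_median(self):
        prior = PriorSpec(loci=("G",), bounds={"s": (1e-5, 1e-1),
                                               "delta": (1e-5, 1e-1),
                                               "phi": (1e-5, 1e-1)})
        theta = sample_prior(prior, 100_000, np.random.default_rng(1))
        for j in range(3):
            assert np.median(theta[:, j]) == pytest.approx(1e-3, rel=0.05)

    def test_degenerate_bounds_collapse(self):
        lo = 1e-3
        prior = PriorSpec(loci=("G",), bounds={"s": (lo, lo * (1 + 1e-12)),
                                               "delta": (lo, lo * (1 + 1e-12)),
                                               "phi": (lo, lo * (1 + 1e-12))})
        theta = sample_prior(prior, 100, np.random.default_rng(2))
        assert np.allclose(theta, lo, rtol=1e-9)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec(bounds={"s": (0.0, 1.0), "delta": (1e-7, 1e-2), "phi": (1e-7, 1e-1)})


class TestTrainingSet:
    def test_zero_noise_is_exact(self):
        ts = build_training_set(
            PriorSpec(), small_config(), n=20, noise_sigma=0.0,
            rng=np.random.default_rng(3),
        )
        assert np.array_equal(ts.x, ts.x_noisy)

    def test_shapes_and_layout(self):
        cfg = small_config()
        ts = build_training_set(PriorSpec(), cfg, n=50, rng=np.random.default_rng(4))
        assert ts.theta.shape == (50, 6)
        assert ts.x.shape == (50, 2 * len(cfg.sample_gens))

    def test_noise_model_recovered(self):
        ts = build_training_set(
            PriorSpec(), small_config(), n=10_000, noise_sigma=0.02,
            rng=np.random.default_rng(5),
        )
        eps = (ts.x_noisy - ts.x).ravel()
        assert eps.std() == pytest.approx(0.02, rel=0.05)
        assert stats.normaltest(eps[::37]).pvalue > 0.01


class TestTrainNPE:
    def test_validation_loss_decreases(self, trained_estimator):
        log = trained_estimator.log
        assert log.best_val_nll < log.val_nll[0]

    def test_deterministic_given_seed(self):
        ts = build_training_set(
            PriorSpec(), small_config(), n=300, rng=np.random.default_rng(6)
        )
        a = train_npe(ts, flow_config=TINY_FLOW, seed=3)
        b = train_npe(ts, flow_config=TINY_FLOW, seed=3)
        assert a.log.best_val_nll == b.log.best_val_nll

    def test_too_few_simulations(self):
        ts = build_training_set(
            PriorSpec(), small_config(), n=5, rng=np.random.default_rng(7)
        )
        with pytest.raises(ValueError, match="simulations"):
            train_npe(ts, flow_config=TINY_FLOW)

    def test_posterior_consistency_at_midprior(self, trained_estimator, two_locus_prior,
                                               experiment_config):
        # the true parameter's log-density under the posterior for its own
        # observation should not sit in the far tail of prior-draw densities
        est = trained_estimator
        theta_star = np.array([0.08, 1e-4, 1e-5, 0.08, 1e-4, 1e-5])
        det = PopulationConfig(N=math.inf, T=experiment_config.T,
                               sample_gens=experiment_config.sample_gens)
        obs = _simulate_theta_batch(theta_star[None, :], two_locus_prior, det, None)[0]
        lp_star = est.log_prob(theta_star[None, :], obs)[0]
        prior_draws = two_locus_prior.sample(500, np.random.default_rng(8))
        lp_prior = est.log_prob(prior_draws, obs)
        assert lp_star > np.percentile(lp_prior, 5)


class TestPosteriorSample:
    def test_draws_within_prior(self, trained_estimator, two_locus_prior,
                                experiment_config):
        rng = np.random.default_rng(9)
        theta = two_locus_prior.sample(1, rng)
        obs = _simulate_theta_batch(theta, two_locus_prior, experiment_config, rng)[0]
        ps = posterior_sample(trained_estimator, obs, 500, rng)
        assert np.all(two_locus_prior.contains(ps.samples))

    def test_point_estimates_are_medians(self, trained_estimator, two_locus_prior,
                                         experiment_config):
        rng = np.random.default_rng(10)
        theta = two_locus_prior.sample(1, rng)
        obs = _simulate_theta_batch(theta, two_locus_prior, experiment_config, rng)[0]
        ps = posterior_sample(trained_estimator, obs, 500, rng)
        assert ps.point_estimates["sG"] == np.median(ps.samples[:, 0])


class GaussianToyEstimator:
    """Analytic conjugate-normal posterior standing in for the flow.

    Model: theta ~ N(0, tau^2); each replicate observes x_i ~ N(theta, sigma^2).
    The per-replicate posterior and the all-replicate product posterior are
    closed-form, which makes this an exact oracle for the collective
    posterior machinery.
    """

    def __init__(self, tau=2.0, sigma=1.0):
        self.tau, self.sigma = tau, sigma
        self.post_var = 1.0 / (1.0 / tau**2 + 1.0 / sigma**2)

        class _Prior:
            param_names = ("theta",)

            def logpdf(_self, theta):
                return stats.norm.logpdf(np.atleast_2d(theta)[:, 0], 0.0, tau)

        self.prior = _Prior()

    def _mean(self, obs):
        return self.post_var * float(np.asarray(obs).ravel()[0]) / self.sigma**2

    def sample(self, obs, m, rng):
        return rng.normal(self._mean(obs), np.sqrt(self.post_var), size=(m, 1))

    def log_prob(self, theta, obs):
        return stats.norm.logpdf(
            np.atleast_2d(theta)[:, 0], self._mean(obs), np.sqrt(self.post_var)
        )


class TestCollective:
    def test_single_replicate_equals_individual(self, trained_estimator,
                                                two_locus_prior, experiment_config):
        rng = np.random.default_rng(11)
        theta = np.array([[0.08, 1e-4, 1e-5, 0.08, 1e-4, 1e-5]])
        x = _simulate_theta_batch(theta, two_locus_prior, experiment_config, rng)[0]
        obs = x + rng.normal(0, 0.02, size=x.shape)
        cp = collective_posterior(trained_estimator, [obs], m=5000,
                                  rng=np.random.default_rng(12))
        ind = posterior_sample(trained_estimator, obs, 5000, np.random.default_rng(13))
        for j in range(6):
            ks = stats.ks_2samp(cp.samples[:, j], ind.samples[:, j])
            assert ks.pvalue > 0.01

    def test_matches_conjugate_product_posterior(self):
        # analytic oracle: the collective of n normal replicates must match
        # the closed-form product posterior
        toy = GaussianToyEstimator(tau=2.0, sigma=1.0)
        obs_list = [np.array([1.0]), np.array([2.0]), np.array([0.5]), np.array([1.5])]
        cp = collective_posterior(toy, obs_list, prior=toy.prior, m=20_000,
                                  rng=np.random.default_rng(14), n_proposal=200_000)
        n = len(obs_list)
        prec = 1 / toy.tau**2 + n / toy.sigma**2
        true_var = 1 / prec
        true_mean = sum(float(o[0]) for o in obs_list) / toy.sigma**2 / prec
        assert cp.samples[:, 0].mean() == pytest.approx(true_mean, abs=0.02 * abs(true_mean) + 0.01)
        assert cp.samples[:, 0].var() == pytest.approx(true_var, rel=0.10)

    def test_replicates_concentrate_conjugate(self):
        # information accumulation: 4 replicates at one truth give a tighter
        # posterior than a single replicate, per the analytic oracle
        toy = GaussianToyEstimator(tau=2.0, sigma=1.0)
        rng = np.random.default_rng(15)
        obs_list = [np.array([0.8 + rng.normal(0, 1)]) for _ in range(4)]
        cp = collective_posterior(toy, obs_list, prior=toy.prior, m=10_000,
                                  rng=np.random.default_rng(16), n_proposal=100_000)
        ind = toy.sample(obs_list[0], 10_000, np.random.default_rng(17))
        iqr = lambda a: np.subtract(*np.percentile(a, [75, 25]))
        assert iqr(cp.samples[:, 0]) <= iqr(ind[:, 0])

    def test_empty_obs_list(self, trained_estimator):
        with pytest.raises(ValueError):
            collective_posterior(trained_estimator, [])


class TestPPC:
    def test_number_of_simulated_trajectories(self, trained_estimator,
                                              two_locus_prior, experiment_config):
        rng = np.random.default_rng(18)
        theta = two_locus_prior.sample(1, rng)
        x = _simulate_theta_batch(theta, two_locus_prior, experiment_config, rng)[0]
        obs = x + rng.normal(0, 0.02, size=x.shape)
        rep = posterior_predictive_check(trained_estimator, obs, experiment_config,
                                         n_draws=100, rng=rng)
        assert rep.simulated.shape[0] == 100

    def test_self_consistency_coverage(self, trained_estimator, two_locus_prior,
                                       experiment_config):
        # an observation generated by the model at a posterior draw should
        # mostly fall inside the 95% predictive envelope
        rng = np.random.default_rng(19)
        theta = np.array([[0.08, 1e-4, 1e-5, 0.08, 1e-4, 1e-5]])
        x = _simulate_theta_batch(theta, two_locus_prior, experiment_config, rng)[0]
        obs = x + rng.normal(0, 0.02, size=x.shape)
        rep = posterior_predictive_check(trained_estimator, obs, experiment_config,
                                         n_draws=100, rng=rng)
        assert rep.coverage >= 0.8

    def test_zero_noise_deterministic_rmse(self, two_locus_prior):
        det = PopulationConfig(N=math.inf, T=60, sample_gens=tuple(range(0, 61, 12)))
        point = np.array([0.08, 1e-4, 1e-5, 0.08, 1e-4, 1e-5])
        obs = _simulate_theta_batch(point[None, :], two_locus_prior, det, None)[0]
        fixed = PosteriorSamples(np.tile(point, (10, 1)), two_locus_prior.param_names)
        rep = posterior_predictive_check(fixed, obs, det, n_draws=10,
                                         rng=np.random.default_rng(20),
                                         prior=two_locus_prior, noise_sigma=0.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)


class TestFitnessTransforms:
    def test_neutral(self):
        assert fitness_transforms(0.0, 0.0).w_per_locus["G"] == 1.0

    def test_reported_mep2_range_consistency(self):
        # s = 0.0846 corresponds to CNV fitness 0.922 relative to wild type
        ft = fitness_transforms(0.0, 0.0846)
        assert ft.w_per_locus["M"] == pytest.approx(0.922, abs=0.001)

    def test_multiplicative_combination(self):
        ft = fitness_transforms(0.02, 0.05)
        assert ft.s_GM == pytest.approx(0.071, abs=1e-6)
        assert ft.w_strain == pytest.approx(1 / 1.071, rel=1e-12)

    def test_invalid_selection(self):
        with pytest.raises(ValueError):
            fitness_transforms(-1.5)


def test_serialization_roundtrip(tmp_path):
    prior = PriorSpec()
    ts = build_training_set(prior, small_config(), n=10, rng=np.random.default_rng(21))
    save_training_set(tmp_path / "ts.csv", tmp_path / "ts.json", ts)
    ps = PosteriorSamples(prior.sample(50, np.random.default_rng(22)), prior.param_names)
    save_posterior_samples(tmp_path / "ps.csv", tmp_path / "ps.json", ps)
    import json

    import pandas as pd

    meta = json.loads((tmp_path / "ts.json").read_text())
    assert meta["n"] == 10 and meta["noise_sigma"] == 0.02
    back = pd.read_csv(tmp_path / "ps.csv")
    assert list(back.columns) == list(prior.param_names)
    assert len(back) == 50
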