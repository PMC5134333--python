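"""Population distributions, hyperpriors, joint posterior and predictives."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import fisk, gamma, kstest, logistic

import hillbayes as hb
from hillbayes.fit import make_hierarchical_target
from hillbayes.hierarchical import (
    GammaSpec,
    PredictiveDistribution,
    logistic_logpdf,
    loglogistic_cdf,
    loglogistic_logpdf,
)


class TestPopulationDensities:
    @pytest.mark.parametrize("mu, s", [(6.0, 0.1), (0.0, 1.0), (-2.0, 2.5)])
    def test_logistic_matches_scipy(self, mu, s):
        p = np.linspace(mu - 8 * s, mu + 8 * s, 33)
        np.testing.assert_allclose(
            logistic_logpdf(p, mu, s), logistic.logpdf(p, loc=mu, scale=s), rtol=1e-10
        )

    def test_logistic_mode_and_symmetry(self):
        mu, s = 6.0, 0.3
        assert logistic_logpdf(mu, mu, s) == pytest.approx(np.log(1 / (4 * s)), rel=1e-12)
        for d in (0.1, 1.0, 7.0):
            assert logistic_logpdf(mu + d, mu, s) == pytest.approx(
                logistic_logpdf(mu - d, mu, s), rel=1e-12
            )

    def test_logistic_integrates_to_one(self):
        total, _ = integrate.quad(
            lambda p: np.exp(logistic_logpdf(p, 6.0, 0.4)), -np.inf, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("alpha, beta", [(1.0, 5.0), (0.8, 2.5), (2.0, 12.0)])
    def test_loglogistic_matches_scipy_fisk(self, alpha, beta):
        """The scale-shape log-logistic is scipy's Fisk distribution."""
        h = np.geomspace(0.05, 20.0, 33)
        np.testing.assert_allclose(
            loglogistic_logpdf(h, alpha, beta),
            fisk.logpdf(h, c=beta, scale=alpha),
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            loglogistic_cdf(h, alpha, beta), fisk.cdf(h, c=beta, scale=alpha), rtol=1e-10
        )

    def test_alpha_is_the_median(self):
        assert loglogistic_cdf(1.7, 1.7, 3.3) == pytest.approx(0.5, abs=1e-12)

    def test_loglogistic_integrates_to_one(self):
        total, _ = integrate.quad(
            lambda h: np.exp(loglogistic_logpdf(h, 1.0, 2.5)), 0.0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_no_mass_or_gradient_at_zero_when_beta_above_two(self):
        # for beta > 2 the density vanishes at h -> 0 with zero slope
        beta = 2.5
        h = np.array([1e-8, 1e-6, 1e-4])
        pdf = np.exp(loglogistic_logpdf(h, 1.0, beta))
        assert np.all(pdf < 1e-5)
        assert pdf[0] / h[0] < 1e-3           # slope estimate also vanishes
        assert loglogistic_logpdf(0.0, 1.0, beta) == -np.inf
        assert loglogistic_logpdf(-1.0, 1.0, beta) == -np.inf

    def test_invalid_scales_raise(self):
        with pytest.raises(ValueError):
            logistic_logpdf(1.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            loglogistic_logpdf(1.0, -1.0, 2.0)


class TestHyperprior:
    def test_gamma_spec_matches_scipy(self):
        spec = GammaSpec(7.5, 1.5, shift=-4.0)
        x = np.linspace(-3.9, 20.0, 41)
        np.testing.assert_allclose(
            spec.logpdf(x), gamma.logpdf(x, a=7.5, scale=1.5, loc=-4.0), rtol=1e-10
        )

    @pytest.mark.parametrize(
        "top",
        [
            hb.TopLevelParams(1.0, 1.5, 6.0, 0.1, 1.0),    # beta <= 2
            hb.TopLevelParams(1.0, 5.0, 6.0, 0.1, 1e-4),   # sigma <= 1e-3
            hb.TopLevelParams(-0.5, 5.0, 6.0, 0.1, 1.0),   # alpha outside support
            hb.TopLevelParams(1.0, 5.0, -5.0, 0.1, 1.0),   # mu below the -4 shift
        ],
    )
    def test_hard_constraints(self, top):
        assert hb.log_hyperprior(top) == -np.inf

    def test_finite_inside_support(self):
        assert np.isfinite(hb.log_hyperprior(hb.TopLevelParams(1.0, 5.0, 6.0, 0.1, 1.0)))

    def test_little_mu_mass_below_minus_two(self):
        assert hb.HierPriorConfig().mu.cdf(-2.0) < 0.05


class TestJointPosterior:
    def _random_state(self, rng, ne):
        top = hb.TopLevelParams(
            rng.uniform(0.5, 2), rng.uniform(2.5, 8), rng.uniform(4, 8),
            rng.uniform(0.05, 1), rng.uniform(0.5, 5),
        )
        return top, rng.uniform(5, 7, ne), rng.uniform(0.5, 2, ne)

    def test_composition_of_three_groups(self, fig9_dataset, rng):
        """Joint density equals independently computed likelihood + population
        + hyperprior terms assembled from scipy building blocks."""
        ne = fig9_dataset.n_experiments
        top, pic50_i, hill_i = self._random_state(rng, ne)
        cfg = hb.HierPriorConfig()
        expected = hb.log_hyperprior(top, cfg)
        expected += fisk.logpdf(hill_i, c=top.beta, scale=top.alpha).sum()
        expected += logistic.logpdf(pic50_i, loc=top.mu, scale=top.s).sum()
        for k, (label, doses, responses) in enumerate(fig9_dataset.by_experiment()):
            f = hb.hill_response(doses, pic50_i[k], hill_i[k])
            expected += hb.truncnorm_loglik(responses, f, top.sigma).sum()
        got = hb.log_posterior_hier(fig9_dataset, top, pic50_i, hill_i, cfg)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_fast_target_matches_reference(self, fig9_dataset, rng):
        target, bounds, names = make_hierarchical_target(fig9_dataset)
        assert len(names) == 5 + 2 * fig9_dataset.n_experiments
        for _ in range(10):
            top, pic50_i, hill_i = self._random_state(rng, fig9_dataset.n_experiments)
            vec = np.concatenate([top.as_array(), pic50_i, hill_i])
            ref = hb.log_posterior_hier(fig9_dataset, top, pic50_i, hill_i)
            assert target(vec) == pytest.approx(ref, rel=1e-9)

    def test_exchangeability_under_relabelling(self, rng):
        """Permuting experiment labels together with their data blocks and
        their (pIC50_i, Hill_i) leaves the joint density unchanged."""
        data = hb.generate_dataset(hb.preset("shamiodarone", seed=9))
        ne = data.n_experiments
        top, pic50_i, hill_i = self._random_state(rng, ne)
        ref = hb.log_posterior_hier(data, top, pic50_i, hill_i)
        perm = rng.permutation(ne)
        relabel = {old + 1: int(np.where(perm == old)[0][0]) + 1 for old in range(ne)}
        new_ids = np.array([relabel[int(e)] for e in data.experiment_ids])
        permuted = hb.DoseResponseDataset(data.doses, data.responses, new_ids)
        got = hb.log_posterior_hier(permuted, top, pic50_i[perm], hill_i[perm])
        assert got == pytest.approx(ref, rel=1e-12)

    def test_nonpositive_hill_gives_minus_inf(self, noiseless_dataset):
        ne = noiseless_dataset.n_experiments
        top = hb.TopLevelParams(1.0, 5.0, 6.0, 0.1, 1.0)
        hill_i = np.ones(ne)
        hill_i[0] = 0.0
        assert hb.log_posterior_hier(noiseless_dataset, top, np.full(ne, 6.0), hill_i) == -np.inf

    def test_mismatched_experiment_count_raises(self, noiseless_dataset):
        top = hb.TopLevelParams(1.0, 5.0, 6.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            hb.log_posterior_hier(noiseless_dataset, top, np.array([6.0]), np.array([1.0]))

    def test_degenerate_population_concentrates(self, noiseless_dataset):
        """As s -> 0 and beta -> inf the hierarchical likelihood density at
        (pIC50_i = mu, Hill_i = alpha) grows without bound."""
        ne = noiseless_dataset.n_experiments
        vals = []
        for s, beta in [(0.1, 5.0), (0.01, 20.0), (0.001, 200.0)]:
            vals.append(
                loglogistic_logpdf(np.ones(ne), 1.0, beta).sum()
                + logistic_logpdf(np.full(ne, 6.0), 6.0, s).sum()
            )
        assert vals[0] < vals[1] < vals[2]


class TestPredictive:
    def test_single_component_is_the_component(self):
        dist = hb.posterior_predictive(np.array([6.0]), np.array([0.2]), "pIC50")
        p = np.linspace(4, 8, 11)
        np.testing.assert_allclose(dist.pdf(p), logistic.pdf(p, 6.0, 0.2), rtol=1e-10)
        np.testing.assert_allclose(dist.cdf(p), logistic.cdf(p, 6.0, 0.2), rtol=1e-10)

    def test_cdf_limits_and_monotonicity(self, rng):
        dist = hb.posterior_predictive(
            rng.uniform(0.8, 1.2, 50), rng.uniform(3, 8, 50), "Hill"
        )
        xs = np.geomspace(1e-6, 1e4, 200)
        cdf = dist.cdf(xs)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[0] < 1e-4 and cdf[-1] > 1 - 1e-4
        assert dist.cdf(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_mixture_density_integrates_to_one(self, rng):
        mus = rng.normal(6.0, 0.3, 25)
        ss = rng.uniform(0.05, 0.5, 25)
        dist = hb.posterior_predictive(mus, ss, "pIC50")
        total, _ = integrate.quad(dist.pdf, -np.inf, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_inverse_cdf_sampling_ks(self, rng):
        """Empirical CDF of 1e5 inverse-CDF draws matches the averaged CDF."""
        dist = hb.posterior_predictive(
            rng.uniform(0.7, 1.4, 100), rng.uniform(2.5, 10, 100), "Hill"
        )
        draws = hb.sample_predictive(dist, 100_000, seed=4)
        assert np.all(draws > 0)
        assert kstest(draws, dist.cdf).statistic < 0.01

    def test_sampling_is_deterministic(self, rng):
        dist = hb.posterior_predictive(np.array([6.0, 6.2]), np.array([0.1, 0.3]), "pIC50")
        np.testing.assert_array_equal(
            hb.sample_predictive(dist, 1000, seed=3), hb.sample_predictive(dist, 1000, seed=3)
        )

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            PredictiveDistribution("logistic", np.array([]), np.array([]))
        with pytest.raises(ValueError):
            hb.posterior_predictive(np.array([1.0]), np.array([3.0]), "slope")
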