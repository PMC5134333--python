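"""Pooled-model likelihood, prior and posterior behaviour."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import truncnorm

import hillbayes as hb
from hillbayes.fit import make_single_level_target
from hillbayes.single_level import truncnorm_loglik


class TestTruncatedNormalDensity:
    @pytest.mark.parametrize("f", [0.0, 5.0, 50.0, 95.0, 100.0])
    @pytest.mark.parametrize("sigma", [0.5, 5.0, 25.0])
    def test_normalises_to_one(self, f, sigma):
        """Quadrature of the truncated density over [0, 100] gives unit mass."""
        total, err = integrate.quad(
            lambda y: np.exp(truncnorm_loglik(y, f, sigma)), 0.0, 100.0, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_truncnorm(self):
        """Cross-check against scipy's truncated normal on a parameter grid."""
        for f in (0.0, 3.0, 50.0, 99.0):
            for sigma in (0.5, 2.0, 30.0):
                y = np.linspace(0.0, 100.0, 23)
                a, b = (0.0 - f) / sigma, (100.0 - f) / sigma
                expected = truncnorm.logpdf(y, a, b, loc=f, scale=sigma)
                np.testing.assert_allclose(
                    truncnorm_loglik(y, f, sigma), expected, rtol=1e-9
                )

    def test_centre_value_with_unit_sigma(self):
        # at y = f = 50 and sigma = 1 the truncation factor is ~1, leaving
        # the standard normal peak -log sqrt(2 pi)
        assert truncnorm_loglik(50.0, 50.0, 1.0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_tail_shrinks_with_smaller_sigma(self):
        y, f = 80.0, 50.0
        assert truncnorm_loglik(y, f, 1.0) < truncnorm_loglik(y, f, 10.0)

    def test_no_underflow_at_extreme_mismatch(self):
        # sigma down to 1e-3 with |y - f| = 100 must stay finite (log domain)
        val = truncnorm_loglik(100.0, 0.0, 1e-3)
        assert np.isfinite(val)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            truncnorm_loglik(50.0, 50.0, 0.0)

    def test_point_likelihood_rejects_out_of_range_response(self):
        params = hb.SingleLevelParams(6.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            hb.log_likelihood_point(101.0, 1.0, params)


class TestPrior:
    def test_in_support_constant(self):
        # product of uniform densities 1/16 * 1/10 * 1/50
        expected = -(np.log(16.0) + np.log(10.0) + np.log(50.0))
        assert hb.log_prior_single(hb.SingleLevelParams(6.0, 1.0, 5.0)) == pytest.approx(
            expected, abs=1e-10
        )

    @pytest.mark.parametrize(
        "params",
        [
            hb.SingleLevelParams(6.0, 11.0, 5.0),   # Hill above (0, 10)
            hb.SingleLevelParams(-2.0, 1.0, 5.0),   # pIC50 below -1
            hb.SingleLevelParams(6.0, 1.0, 55.0),   # sigma above 50
            hb.SingleLevelParams(16.0, 1.0, 5.0),
        ],
    )
    def test_outside_support_is_minus_inf(self, params):
        assert hb.log_prior_single(params) == -np.inf

    def test_custom_bounds_widen_support(self):
        wide = hb.UniformPriorBounds(hill=(0.0, 20.0))
        params = hb.SingleLevelParams(6.0, 11.0, 5.0)
        assert np.isfinite(hb.log_prior_single(params, wide))


class TestPosterior:
    def test_single_point_additivity(self):
        data = hb.DoseResponseDataset([1.0], [50.0], [1])
        params = hb.SingleLevelParams(6.0, 1.0, 1.0)
        expected = hb.log_likelihood_point(50.0, 1.0, params) + hb.log_prior_single(params)
        assert hb.log_posterior_single(data, params) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance(self, fig9_dataset, rng):
        params = hb.SingleLevelParams(5.8, 1.2, 2.0)
        ref = hb.log_posterior_single(fig9_dataset, params)
        perm = rng.permutation(fig9_dataset.n_records)
        shuffled = hb.DoseResponseDataset(
            fig9_dataset.doses[perm],
            fig9_dataset.responses[perm],
            fig9_dataset.experiment_ids[perm],
        )
        assert hb.log_posterior_single(shuffled, params) == pytest.approx(ref, rel=1e-12)

    def test_support_matches_prior_box(self, noiseless_dataset):
        inside = hb.SingleLevelParams(6.0, 1.0, 5.0)
        outside = hb.SingleLevelParams(6.0, -1.0, 5.0)
        assert np.isfinite(hb.log_posterior_single(noiseless_dataset, inside))
        assert hb.log_posterior_single(noiseless_dataset, outside) == -np.inf

    def test_grid_argmax_near_generating_values(self):
        """With small noise the posterior mode sits at the generating point."""
        spec = hb.GeneratorSpec(
            pic50=6.0, hill=1.0, sigma=0.2, n_experiments=3,
            concentrations=(0.05, 0.3, 1.0, 9.0), seed=7,
        )
        data = hb.generate_dataset(spec)
        pgrid = np.linspace(5.5, 6.5, 21)      # step 0.05
        hgrid = np.linspace(0.5, 1.5, 21)
        best, best_val = None, -np.inf
        for p in pgrid:
            for h in hgrid:
                val = hb.log_posterior_single(data, hb.SingleLevelParams(p, h, 0.2))
                if val > best_val:
                    best, best_val = (p, h), val
        assert abs(best[0] - 6.0) <= 0.05 + 1e-9
        assert abs(best[1] - 1.0) <= 0.05 + 1e-9

    def test_fast_target_matches_reference(self, fig9_dataset, rng):
        """The vectorised MCMC closure equals the reference log posterior."""
        target, _ = make_single_level_target(fig9_dataset)
        for _ in range(20):
            theta = np.array(
                [rng.uniform(0, 10), rng.uniform(0.2, 8), rng.uniform(0.3, 40)]
            )
            ref = hb.log_posterior_single(fig9_dataset, hb.SingleLevelParams(*theta))
            assert target(theta) == pytest.approx(ref, rel=1e-10)
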