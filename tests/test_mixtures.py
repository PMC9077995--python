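"""Closed-form mixture algebra against textbook oracles and Monte Carlo."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecborrow.mixtures import (
    GaussianSummary,
    NormalMixture,
    prob_difference_positive,
    robustify,
    update_posterior,
)

from conftest import make_mixture

# strategy for a modest random mixture with well-scaled parameters
weights_st = st.lists(st.floats(0.05, 1.0), min_size=1, max_size=4)


@st.composite
def mixtures(draw):
    w = draw(weights_st)
    k = len(w)
    means = draw(st.lists(st.floats(-50, 50), min_size=k, max_size=k))
    sds = draw(st.lists(st.floats(0.1, 20), min_size=k, max_size=k))
    return make_mixture(w, means, sds)


class TestValidation:
    def test_weights_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            NormalMixture(np.array([0.5, 0.6]), np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="sds"):
            NormalMixture(np.array([1.0]), np.array([0.0]), np.array([0.0]))

    def test_from_unnormalized_rescales(self):
        mix = NormalMixture.from_unnormalized([2.0, 2.0], [0.0, 1.0], [1.0, 1.0])
        assert np.allclose(mix.weights, [0.5, 0.5])


class TestRobustify:
    def test_psp_robust_construction(self, psp_map_prior):
        """50:50 mix of the MAP prior and the vague Normal(15, 10)."""
        robust = robustify(psp_map_prior, 0.5, 15.0, 10.0)
        assert len(robust) == 2
        assert np.allclose(robust.weights, [0.5, 0.5])
        assert robust.means[1] == 15.0 and robust.sds[1] == 10.0
        assert robust.means[0] == psp_map_prior.means[0]

    def test_weights_sum_to_one(self):
        mix = make_mixture([0.3, 0.7], [0.0, 5.0], [1.0, 2.0])
        robust = robustify(mix, 0.2, 0.0, 50.0)
        assert abs(robust.weights.sum() - 1.0) < 1e-12

    def test_vanishing_vague_weight_recovers_prior(self):
        mix = make_mixture([1.0], [3.0], [2.0])
        xs = np.linspace(-5, 11, 9)
        robust = robustify(mix, 1e-9, 100.0, 10.0)
        assert np.allclose(robust.cdf(xs), mix.cdf(xs), atol=1e-8)

    @pytest.mark.parametrize("w", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_weight_rejected(self, w):
        with pytest.raises(ValueError):
            robustify(make_mixture([1.0], [0.0], [1.0]), w, 0.0, 10.0)


class TestUpdatePosterior:
    def test_agreeing_data_keeps_mean(self):
        prior = NormalMixture.single(10.8, 1.19)
        post = update_posterior(prior, GaussianSummary(43, 10.8, 8.0))
        assert post.mean() == pytest.approx(10.8, abs=1e-12)

    def test_precision_addition_closed_form(self):
        prior = NormalMixture.single(10.8, 1.19)
        post = update_posterior(prior, GaussianSummary(43, 10.8, 8.0))
        expected_sd = (1 / 1.19**2 + 43 / 64) ** -0.5
        assert post.sds[0] == pytest.approx(expected_sd, abs=1e-12)

    @given(
        m=st.floats(-20, 20),
        s=st.floats(0.1, 10),
        n=st.integers(1, 500),
        ybar=st.floats(-20, 20),
        sigma=st.floats(0.5, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_single_component_matches_textbook(self, m, s, n, ybar, sigma):
        """Normal-normal conjugate update, exact to 1e-12."""
        post = update_posterior(NormalMixture.single(m, s), GaussianSummary(n, ybar, sigma))
        prec = 1 / s**2 + n / sigma**2
        assert post.means[0] == pytest.approx((m / s**2 + ybar * n / sigma**2) / prec, abs=1e-12)
        assert post.sds[0] == pytest.approx(prec**-0.5, abs=1e-12)

    def test_conflict_shifts_weight_to_vague(self, psp_robust_prior):
        """Data far from the informative component makes the vague
        component dominate the posterior (dynamic borrowing)."""
        post = update_posterior(psp_robust_prior, GaussianSummary(43, 20.0, 8.0))
        # weight oracle by direct density evaluation
        marg_sd = np.sqrt(psp_robust_prior.sds**2 + 64 / 43)
        lik = stats.norm.pdf(20.0, psp_robust_prior.means, marg_sd)
        expected = psp_robust_prior.weights * lik / np.sum(psp_robust_prior.weights * lik)
        assert np.allclose(post.weights, expected, atol=1e-12)
        assert post.weights[1] > 0.5

    def test_weights_invariant_to_prior_rescaling(self):
        mix1 = make_mixture([0.25, 0.75], [0.0, 6.0], [1.0, 3.0])
        mix2 = make_mixture([25.0, 75.0], [0.0, 6.0], [1.0, 3.0])
        data = GaussianSummary(10, 4.0, 2.0)
        assert np.allclose(
            update_posterior(mix1, data).weights, update_posterior(mix2, data).weights
        )


class TestCdfQuantileMoments:
    def test_standard_normal_upper_quantile(self):
        assert NormalMixture.single(0, 1).quantile(0.975) == pytest.approx(
            1.959964, abs=1e-6
        )

    @given(mix=mixtures(), p=st.floats(0.001, 0.999))
    @settings(max_examples=80, deadline=None)
    def test_quantile_cdf_roundtrip(self, mix, p):
        assert mix.cdf(mix.quantile(p)) == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("a", [0.5, 2.0, 10.0])
    def test_symmetric_mixture_median_at_zero(self, a):
        mix = make_mixture([0.5, 0.5], [-a, a], [1.0, 1.0])
        assert mix.cdf(0.0) == pytest.approx(0.5, abs=1e-14)

    def test_two_component_moments_closed_form(self):
        mix = make_mixture([0.5, 0.5], [0.0, 4.0], [1.0, 1.0])
        mean, sd = mix.moments()
        assert mean == pytest.approx(2.0, abs=1e-14)
        assert sd == pytest.approx(np.sqrt(5.0), abs=1e-14)

    def test_moments_match_sampling(self, rng):
        mix = make_mixture([0.3, 0.5, 0.2], [-2.0, 1.0, 8.0], [0.5, 2.0, 1.0])
        draws = mix.rvs(1_000_000, rng)
        n = draws.size
        se_mean = draws.std() / np.sqrt(n)
        assert mix.mean() == pytest.approx(draws.mean(), abs=4 * se_mean)
        se_sd = draws.std() / np.sqrt(2 * n)  # delta-method SE of the sample sd
        assert mix.sd() == pytest.approx(draws.std(ddof=1), abs=4 * se_sd)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.5])
    def test_invalid_quantile_level(self, p):
        with pytest.raises(ValueError):
            NormalMixture.single(0, 1).quantile(p)


class TestProbDifferencePositive:
    def test_identical_mixtures_give_half(self):
        mix = make_mixture([0.4, 0.6], [1.0, 3.0], [1.0, 2.0])
        assert prob_difference_positive(mix, mix) == pytest.approx(0.5, abs=1e-14)

    def test_normal_difference_closed_form(self):
        p = prob_difference_positive(NormalMixture.single(4, 1), NormalMixture.single(0, 1))
        assert p == pytest.approx(stats.norm.cdf(4 / np.sqrt(2)), abs=1e-14)

    def test_matches_monte_carlo(self, rng):
        a = make_mixture([0.7, 0.3], [1.0, 5.0], [1.0, 2.0])
        b = make_mixture([0.5, 0.5], [0.0, 3.0], [1.5, 0.5])
        n = 1_000_000
        diff = a.rvs(n, rng) - b.rvs(n, rng)
        est = np.mean(diff > 0)
        se = np.sqrt(est * (1 - est) / n)
        assert prob_difference_positive(a, b) == pytest.approx(est, abs=3 * se)

    @given(a=mixtures(), b=mixtures())
    @settings(max_examples=60, deadline=None)
    def test_complementarity(self, a, b):
        assert prob_difference_positive(a, b) + prob_difference_positive(b, a) == pytest.approx(
            1.0, abs=1e-12
        )


def test_json_roundtrip_is_bit_exact():
    mix = make_mixture([1 / 3, 2 / 3], [10.905880258761158, 15.0], [1.190139866477712, 10.0])
    recovered = NormalMixture.from_dict(json.loads(json.dumps(mix.to_dict())))
    assert recovered.weights.tolist() == mix.weights.tolist()
    assert recovered.means.tolist() == mix.means.tolist()
    assert recovered.sds.tolist() == mix.sds.tolist()
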