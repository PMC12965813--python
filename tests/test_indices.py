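import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import bayesrct as brc


class TestProbabilityOfDirection:
    def test_unanimous_direction(self):
        assert brc.probability_of_direction(np.full(100, 0.3)) == 1.0
        assert brc.probability_of_direction(np.full(100, -0.3)) == 1.0

    def test_normal_tail_oracle(self, rng):
        draws = rng.normal(1.0, 1.0, size=1_000_000)
        expected = norm.cdf(1.0)
        mcse = math.sqrt(expected * (1 - expected) / draws.size)
        assert brc.probability_of_direction(draws) == pytest.approx(expected, abs=3 * mcse)

    def test_draws_at_null_belong_to_neither_tail(self):
        draws = np.array([0.0, 0.0, 1.0, -1.0, 2.0])
        assert brc.probability_of_direction(draws) == pytest.approx(2 / 5)

    @settings(derandomize=True, max_examples=100)
    @given(
        loc=st.floats(-3, 3), scale=st.floats(0.01, 3), seed=st.integers(0, 2**20)
    )
    def test_range_and_scale_invariance(self, loc, scale, seed):
        draws = np.random.default_rng(seed).normal(loc, scale, size=400)
        pd_log = brc.probability_of_direction(draws)
        assert 0.5 <= pd_log <= 1.0
        # same index computed on OR draws relative to 1
        or_draws = np.exp(draws)
        manual = max(np.mean(or_draws > 1), np.mean(or_draws < 1))
        assert pd_log == pytest.approx(manual, abs=1e-12)


class TestRopeFull:
    def test_null_posterior_fully_inside(self):
        assert brc.rope_full(np.zeros(50)) == 1.0

    def test_boundary_draws_count_as_inside(self):
        rope = brc.RopeInterval(0.84, 1.20)
        draws = np.array([math.log(0.84), math.log(1.20)])
        assert brc.rope_full(draws, rope) == 1.0

    def test_normal_oracle(self, rng):
        mu, sigma = 0.3, 0.25
        draws = rng.normal(mu, sigma, size=1_000_000)
        lo, hi = math.log(0.84), math.log(1.20)
        expected = norm.cdf((hi - mu) / sigma) - norm.cdf((lo - mu) / sigma)
        mcse = math.sqrt(expected * (1 - expected) / draws.size)
        assert brc.rope_full(draws) == pytest.approx(expected, abs=3 * mcse)

    @settings(derandomize=True, max_examples=100)
    @given(loc=st.floats(-2, 2), seed=st.integers(0, 2**20))
    def test_range_and_scale_invariance(self, loc, seed):
        draws = np.random.default_rng(seed).normal(loc, 0.5, size=300)
        rope = brc.RopeInterval(0.84, 1.20)
        val = brc.rope_full(draws, rope)
        assert 0.0 <= val <= 1.0
        manual = np.mean((np.exp(draws) >= 0.84) & (np.exp(draws) <= 1.20))
        assert val == pytest.approx(manual, abs=1e-12)

    def test_rope_interval_validation(self):
        with pytest.raises(ValueError):
            brc.RopeInterval(1.2, 0.84)
        with pytest.raises(ValueError):
            brc.RopeInterval(-1.0, 1.2)
        default = brc.RopeInterval()
        assert (default.or_low, default.or_high) == (0.84, 1.20)


class TestEqualTailedCri:
    def test_order_statistic_definition(self):
        draws = np.log(np.arange(1, 101))
        lo, hi = brc.equal_tailed_cri(draws, level=0.90)
        # independent order-statistic interpolation on the sorted set
        srt = np.sort(draws)
        pos_lo, pos_hi = 0.05 * 99, 0.95 * 99
        want_lo = srt[4] + (pos_lo - 4) * (srt[5] - srt[4])
        want_hi = srt[94] + (pos_hi - 94) * (srt[95] - srt[94])
        assert (math.log(lo), math.log(hi)) == pytest.approx((want_lo, want_hi))

    def test_normal_quantile_oracle(self, rng):
        draws = rng.standard_normal(1_000_000)
        lo, hi = brc.equal_tailed_cri(draws, level=0.95)
        assert math.log(lo) == pytest.approx(-1.959964, abs=0.01)
        assert math.log(hi) == pytest.approx(1.959964, abs=0.01)

    def test_monotone_in_level(self, rng):
        draws = rng.standard_normal(20_000)
        widths = [
            np.log(brc.equal_tailed_cri(draws, lv)[1] / brc.equal_tailed_cri(draws, lv)[0])
            for lv in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert np.all(np.diff(widths) > 0)

    def test_level_validation(self, rng):
        with pytest.raises(ValueError):
            brc.equal_tailed_cri(rng.standard_normal(10), level=1.0)


class TestPdPConversion:
    @pytest.mark.parametrize("pd_val, p_val", [(1.0, 0.0), (0.5, 1.0), (0.973, 0.054)])
    def test_pd_to_p(self, pd_val, p_val):
        assert brc.pd_to_p(pd_val) == pytest.approx(p_val, abs=1e-12)

    @pytest.mark.parametrize("p_val, pd_val", [(0.05, 0.975), (1.0, 0.5), (0.0, 1.0)])
    def test_p_to_pd(self, p_val, pd_val):
        assert brc.p_to_pd(p_val) == pytest.approx(pd_val, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(0.0, 1.0))
    def test_round_trip(self, p):
        assert brc.pd_to_p(brc.p_to_pd(p)) == pytest.approx(p, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            brc.pd_to_p(0.3)
        with pytest.raises(ValueError):
            brc.p_to_pd(1.2)


def test_empty_draws_rejected():
    for fn in (brc.probability_of_direction, brc.rope_full):
        with pytest.raises(ValueError, match="empty"):
            fn(np.array([]))
    with pytest.raises(ValueError, match="empty"):
        brc.equal_tailed_cri(np.array([]), 0.95)


def test_null_pd_transform_is_uniform():
    """Under a true null effect, 2*(1 - pd) behaves like a two-sided
    P value: approximately uniform on [0, 1] across simulated trials
    (1000 replicates at n = 200/arm)."""
    import warnings

    from scipy.stats import kstest

    from bayesrct.simulate import generate_trial

    trials = [
        generate_trial(0.4, 0.0, 200, 200, seed=700_000 + i, trial_id=f"null-{i}")[0]
        for i in range(1000)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", brc.ConvergenceWarning)
        fits = brc.fit_posterior_many(
            trials, sampler=brc.SamplerConfig(n_draws=4000, warmup=600, seed=31)
        )
    stat = np.array([brc.pd_to_p(max(brc.probability_of_direction(f), 0.5)) for f in fits])
    ks = kstest(stat, "uniform").statistic
    assert ks < 0.05


def test_summarize_draws_consistency(amisulpride_draws):
    rep = brc.summarize_draws(amisulpride_draws)
    assert rep.cri_low <= rep.median_or <= rep.cri_high
    assert 0.5 <= rep.pd <= 1.0
    assert 0.0 <= rep.rope_full <= 1.0
    assert rep.converged == amisulpride_draws.converged
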