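import numpy as np
import pytest

import bayesrct as brc
from bayesrct.cohort import summarize_frame
from bayesrct.frequentist import FrequentistReport
from bayesrct.indices import IndexReport
from bayesrct.trial_data import TwoByTwoTrial

FAST = brc.SamplerConfig(n_draws=20_000, n_chains=4, warmup=1000, seed=0)


def mk_report(tid, p, pd_val, rope_val, n=100, or_hat=1.5):
    """Hand-built report for summary-level tests (no fitting needed)."""
    return brc.TrialReport(
        trial_id=tid,
        freq=FrequentistReport(or_hat=or_hat, p_fisher=p, ci_low=0.8, ci_high=2.0),
        bayes=IndexReport(pd=pd_val, rope_full=rope_val, cri_low=0.9, cri_high=2.1,
                          median_or=or_hat),
        n_total=n,
    )


class TestAnalyzeTrial:
    def test_worked_example_pd_p_correspondence(self, amisulpride):
        rep = brc.analyze_trial(amisulpride, sampler=FAST)
        assert abs(brc.pd_to_p(rep.bayes.pd) - rep.freq.p_fisher) < 0.01

    def test_null_data(self):
        trial = TwoByTwoTrial("null", 50, 100, 50, 100)
        rep = brc.analyze_trial(trial, sampler=FAST)
        assert rep.freq.p_fisher == pytest.approx(1.0)
        assert rep.bayes.pd < 0.6

    def test_cri_brackets_median(self, amisulpride):
        rep = brc.analyze_trial(amisulpride, sampler=FAST)
        assert rep.bayes.cri_low <= rep.bayes.median_or <= rep.bayes.cri_high
        assert rep.n_total == 318


class TestAnalyzeCohort:
    def test_order_independent_and_reproducible(self):
        trials = [
            TwoByTwoTrial("a", 30, 60, 25, 55),
            TwoByTwoTrial("b", 10, 40, 18, 42),
        ]
        fwd = brc.analyze_cohort(trials, sampler=FAST, master_seed=3)
        rev = brc.analyze_cohort(trials[::-1], sampler=FAST, master_seed=3)
        by_id_fwd = {r.trial_id: r for r in fwd}
        by_id_rev = {r.trial_id: r for r in rev}
        for tid in ("a", "b"):
            assert by_id_fwd[tid].bayes == by_id_rev[tid].bayes


class TestSummarizeCohort:
    def test_single_report(self):
        s = brc.summarize_cohort([mk_report("a", 0.3, 0.85, 0.4)])
        assert s.median_p == s.iqr_p_low == s.iqr_p_high == 0.3
        assert s.median_pd == 0.85 and s.median_rope == 0.4
        assert s.n_estimates == 1

    def test_odd_length_median(self):
        reports = [mk_report(f"t{i}", 0.5, pd_val, 0.3) for i, pd_val in
                   enumerate([0.6, 0.8, 1.0])]
        assert brc.summarize_cohort(reports).median_pd == 0.8

    def test_permutation_invariance(self, rng):
        reports = [
            mk_report(f"t{i}", rng.uniform(0, 1), rng.uniform(0.5, 1), rng.uniform(0, 1))
            for i in range(11)
        ]
        perm = [reports[i] for i in rng.permutation(len(reports))]
        assert brc.summarize_cohort(reports) == brc.summarize_cohort(perm)

    def test_iqr_brackets_median_and_ranges(self, rng):
        reports = [
            mk_report(f"t{i}", rng.uniform(0, 1), rng.uniform(0.5, 1), rng.uniform(0, 1))
            for i in range(25)
        ]
        s = brc.summarize_cohort(reports)
        for name in ("p", "pd", "rope"):
            med = getattr(s, f"median_{name}")
            assert getattr(s, f"iqr_{name}_low") <= med <= getattr(s, f"iqr_{name}_high")
        for corr in (s.spearman_pd_p, s.spearman_rope_p, s.spearman_pd_rope):
            assert -1 <= corr <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            brc.summarize_cohort([])

    def test_summarize_frame_matches_reports(self, rng):
        reports = [
            mk_report(f"t{i}", rng.uniform(0, 1), rng.uniform(0.5, 1), rng.uniform(0, 1))
            for i in range(9)
        ]
        assert summarize_frame(brc.reports_to_frame(reports)) == brc.summarize_cohort(reports)


class TestDichotomization:
    def test_near_threshold_discordant_pair_flagged(self):
        reports = [
            mk_report("study-12", 0.057, 0.973, 0.13),
            mk_report("study-15", 0.042, 0.979, 0.11),
            mk_report("study-x", 0.80, 0.60, 0.70),
        ]
        res = brc.dichotomization_table(reports, alpha=0.05)
        assert set(res.near_threshold["trial_id"]) == {"study-12", "study-15"}
        assert len(res.discordant_pairs) == 1
        pair = res.discordant_pairs.iloc[0]
        assert {pair["trial_id_a"], pair["trial_id_b"]} == {"study-12", "study-15"}

    def test_all_nonsignificant(self):
        reports = [mk_report(f"t{i}", 0.6 + 0.03 * i, 0.7, 0.5) for i in range(5)]
        res = brc.dichotomization_table(reports, alpha=0.05)
        assert True not in res.by_pd.index  # no significant stratum exists
        assert len(res.near_threshold) == 0
        assert len(res.discordant_pairs) == 0

    def test_counts_match_brute_force_recount(self, rng):
        reports = [
            mk_report(f"t{i}", rng.uniform(0, 0.2), rng.uniform(0.5, 1), rng.uniform(0, 1))
            for i in range(40)
        ]
        res = brc.dichotomization_table(reports, alpha=0.05)
        sig_high_pd = sum(
            1 for r in reports if r.freq.p_fisher < 0.05 and r.bayes.pd >= 0.975
        )
        if True in res.by_pd.index and "pd>=97.5%" in res.by_pd.columns:
            assert res.by_pd.loc[True, "pd>=97.5%"] == sig_high_pd
        assert res.by_pd.to_numpy().sum() == len(reports)
        assert res.by_rope.to_numpy().sum() == len(reports)
        n_near = sum(1 for r in reports if abs(r.freq.p_fisher - 0.05) < 0.02)
        assert len(res.near_threshold) == n_near

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            brc.dichotomization_table([mk_report("a", 0.5, 0.7, 0.5)], alpha=0)
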