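"""Bias screen, criterion detection, perseveration and latency scoring."""

import math

import numpy as np
import pytest

from conftest import build_session, session_with_errors
from touchcog.scoring import (
    ScoringConfig,
    binomial_bias_test,
    criterion_point,
    criterion_point_from_logs,
    fifty_percent_point,
    latency_summary,
    perseveration_binomial,
    summarize_animal,
)
from touchcog.task_engine import Phase


def exhaustive_binomial_p(k: int, n: int, p0: float = 0.5) -> float:
    """Summation oracle: add up P(X = j) over every outcome j whose
    probability does not exceed that of the observed k."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestBinomialBias:
    def test_symmetric_mode_not_biased(self):
        res = binomial_bias_test(15, 30)
        assert res.p_value == pytest.approx(1.0)
        assert not res.biased and res.direction == "none"

    def test_extreme_tail_two_sided_doubling(self):
        res = binomial_bias_test(30, 30)
        assert res.p_value == pytest.approx(2 * 2.0**-30)
        assert res.biased and res.direction == "toward"

    def test_aversion_direction(self):
        res = binomial_bias_test(2, 30)
        assert res.biased and res.direction == "against"

    @pytest.mark.parametrize("k", range(0, 31))
    def test_matches_exhaustive_summation_oracle(self, k):
        assert binomial_bias_test(k, 30).p_value == pytest.approx(
            exhaustive_binomial_p(k, 30))

    def test_cutoff_at_30_trials_is_21(self):
        flagged = [k for k in range(16, 31)
                   if binomial_bias_test(k, 30).biased]
        assert min(flagged) == 21
        # symmetric lower tail: the largest biased low count is 9
        assert max(k for k in range(0, 16)
                   if binomial_bias_test(k, 30).biased) == 9

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_bias_test(5, 0)
        with pytest.raises(ValueError):
            binomial_bias_test(-1, 30)


class TestCriterionPoint:
    def test_immediate_criterion(self):
        cp = criterion_point([0.9, 0.9], [30, 30])
        assert (cp.n_sessions, cp.n_trials, cp.n_errors) == (2, 60, 6)

    def test_window_must_be_consecutive(self):
        cp = criterion_point([0.85, 0.7, 0.8, 0.83], [30] * 4)
        assert cp.n_sessions == 4 and cp.n_trials == 120

    def test_not_reached(self):
        assert criterion_point([0.7, 0.9, 0.7], [30] * 3) is None

    def test_trailing_sessions_do_not_change_the_point(self):
        accs = [0.5, 0.85, 0.9]
        cp1 = criterion_point(accs, [30] * 3)
        cp2 = criterion_point(accs + [0.2, 1.0, 1.0], [30] * 6)
        assert cp1 == cp2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            criterion_point([], [])

    def test_matches_independent_rescan_of_logs(self, small_cohort):
        """Scoring a simulated animal's PD logs equals a flat re-scan of
        the raw trial records."""
        animal = small_cohort.animals[0]
        logs = animal.logs_by_phase[Phase.PD]
        cp = criterion_point_from_logs(logs)
        # independent scan: recompute accuracies from raw trials
        accs, cnts = [], []
        for s in logs:
            oks = [t.correct for t in s.trials]
            accs.append(sum(oks) / len(oks))
            cnts.append(len(oks))
        i = next(j for j in range(1, len(accs))
                 if accs[j - 1] >= 0.8 and accs[j] >= 0.8)
        assert cp.n_sessions == i + 1
        assert cp.n_trials == sum(cnts[: i + 1])


class TestPerseveration:
    def test_single_heavily_biased_session(self):
        logs = [session_with_errors(25, session_index=1)]
        flagged, errors = perseveration_binomial(logs)
        assert flagged == (1,) and errors == 25

    def test_flagging_follows_binomial_cutoff(self):
        counts = [28, 24, 16, 12]
        logs = [session_with_errors(e, session_index=i + 1)
                for i, e in enumerate(counts)]
        flagged, errors = perseveration_binomial(logs)
        assert flagged == (1, 2)   # 28 and 24 exceed the 21/30 cutoff
        assert errors == 52

    def test_chance_sessions_never_flagged(self):
        logs = [session_with_errors(15, session_index=i + 1)
                for i in range(4)]
        flagged, errors = perseveration_binomial(logs)
        assert flagged == () and errors == 0

    def test_contiguous_scope_stops_at_first_gap(self):
        counts = [28, 14, 24, 12]
        logs = [session_with_errors(e, session_index=i + 1)
                for i, e in enumerate(counts)]
        cfg = ScoringConfig(perseveration_scope="contiguous")
        flagged, errors = perseveration_binomial(logs, cfg)
        assert flagged == (1,) and errors == 28
        flagged_all, errors_all = perseveration_binomial(logs)
        assert flagged_all == (1, 3) and errors_all == 52

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            perseveration_binomial([])


class TestFiftyPercentPoint:
    def test_direct_rule_application(self):
        accs = [0.2, 0.4, 0.5, 0.6]
        logs = [session_with_errors(round(30 * (1 - a)), session_index=i + 1)
                for i, a in enumerate(accs)]
        trials, errors = fifty_percent_point(logs)
        assert trials == 120
        assert errors == sum(round(30 * (1 - a)) for a in accs)

    def test_incomplete_session_cannot_serve_as_criterion(self):
        # an 18-trial session at 0.61 accuracy is above chance but
        # incomplete; its trials still accumulate
        s1 = session_with_errors(20, session_index=1)          # 0.33
        s2 = build_session([True] * 11 + [False] * 7, session_index=2)
        s3 = session_with_errors(12, session_index=3)          # 0.60
        s4 = session_with_errors(10, session_index=4)          # 0.67
        trials, errors = fifty_percent_point([s1, s2, s3, s4])
        assert trials == 30 + 18 + 30 + 30
        assert errors == 20 + 7 + 12 + 10

    def test_not_reached(self):
        logs = [session_with_errors(20, session_index=i + 1)
                for i in range(3)]
        assert fifty_percent_point(logs) is None

    def test_consistent_with_published_worst_case_arithmetic(self):
        """1680 trials to the 50 % criterion = exactly 56 complete
        30-trial sessions, the pattern seen in the slowest learner."""
        logs = [session_with_errors(18, session_index=i + 1)
                for i in range(54)]
        logs += [session_with_errors(14, session_index=55),
                 session_with_errors(14, session_index=56),
                 session_with_errors(2, session_index=57)]
        trials, errors = fifty_percent_point(logs)
        assert trials == 56 * 30 == 1680
        assert errors == 54 * 18 + 2 * 14


class TestLatencySummary:
    def test_constant_latencies(self):
        logs = [build_session([True] * 10, session_index=1),
                build_session([True] * 10, session_index=2)]
        resp, rew = latency_summary(logs)
        assert resp == 2.0 and rew == 1.0

    def test_pooling_is_trial_level_not_session_mean(self):
        s1 = build_session([True] * 3, session_index=1)
        for t, lat in zip(s1.trials, [1.0, 2.0, 3.0]):
            t.response_latency = lat
        s2 = build_session([True], session_index=2)
        s2.trials[0].response_latency = 5.0
        resp, _ = latency_summary([s1, s2])
        assert resp == pytest.approx(2.75)          # pooled over 4 trials
        cfg = ScoringConfig(latency_pooling="sessions")
        resp_sess, _ = latency_summary([s1, s2], config=cfg)
        assert resp_sess == pytest.approx((2.0 + 5.0) / 2)

    def test_reward_latency_only_on_correct_trials(self):
        s = build_session([True, False, True])
        _, rew = latency_summary([s])
        assert rew == 1.0
        all_wrong = build_session([False] * 5)
        _, rew2 = latency_summary([all_wrong])
        assert math.isnan(rew2)

    def test_matches_flat_rescan_of_simulated_log(self, small_cohort):
        animal = small_cohort.animals[1]
        logs = animal.logs_by_phase[Phase.PD]
        resp, rew = latency_summary(logs, Phase.PD)
        flat_resp = [t.response_latency for s in logs for t in s.trials]
        flat_rew = [t.reward_latency for s in logs for t in s.trials
                    if t.reward_latency is not None]
        assert resp == pytest.approx(np.mean(flat_resp))
        assert rew == pytest.approx(np.mean(flat_rew))


class TestSummarizeAnimal:
    def test_all_correct_animal_is_flagged_biased(self):
        """A perfect first PD session (30/30 for the rewarded image) is
        itself an extreme binomial outcome, so the screen flags it."""
        pd = [build_session([True] * 30, phase=Phase.PD, session_index=i + 1)
              for i in range(2)]
        out = summarize_animal({Phase.PD: pd}, subject_id="X", sex="f",
                               age_years=2.0, positive_image="marble",
                               negative_image="fan")
        assert out.pd_sessions == 2 and out.pd_trials == 60
        assert out.bias_flag and out.bias_toward == "marble"

    def test_age_group_threshold(self):
        young = summarize_animal({}, subject_id="a", sex="m", age_years=4.1)
        aged = summarize_animal({}, subject_id="b", sex="m", age_years=6.9)
        assert young.age_group == "YOUNG" and aged.age_group == "AGED"

    def test_missing_phases_leave_na_fields(self):
        out = summarize_animal({}, subject_id="x", sex="f", age_years=3.0)
        assert out.pd_trials is None and out.persev_errors_50 is None

    def test_simulated_summaries_respect_invariants(self, small_cohort):
        for animal in small_cohort.animals:
            s = animal.summarize()
            assert s.pd_trials >= s.pd_sessions >= 1
            assert s.pdr_trials >= s.pdr_sessions >= 1
            assert s.persev_errors_50 <= s.trials_to_50 <= s.pdr_trials
            assert s.persev_errors_binomial >= 0
            assert s.training_days >= 5
            assert s.pd_response_latency > 0 and s.pd_reward_latency > 0

    def test_flagged_perseverative_sessions_precede_criterion(
            self, small_cohort):
        """A session inside the 80 %/2-session criterion pair cannot be
        significantly biased toward the former image, so every flagged
        perseverative session precedes the criterion point."""
        from touchcog.scoring import criterion_point_from_logs

        for animal in small_cohort.animals:
            pdr = animal.logs_by_phase[Phase.PDR]
            cp = criterion_point_from_logs(pdr)
            if cp is None:
                continue
            flagged, _ = perseveration_binomial(pdr)
            assert all(idx <= cp.n_sessions - 2 for idx in flagged)

    def test_scoring_is_pure(self, small_cohort):
        animal = small_cohort.animals[0]
        assert animal.summarize() == animal.summarize()
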