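import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from stsbalance import (
    DegenerateStatisticError,
    engagement_report,
    one_sample_t,
    summarize_adherence,
    validity_rate,
)

# ---------------------------------------------------------------------------
# Independent Student-t oracle: two-sided p via the regularized incomplete
# beta function, evaluated with a Lentz continued fraction (no scipy.stats)
# ---------------------------------------------------------------------------


def _betacf(a, b, x, max_iter=300, eps=1e-14):
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        c = 1.0 + aa / c
        d = 1.0 / (d if abs(d) >= 1e-300 else 1e-300)
        c = c if abs(c) >= 1e-300 else 1e-300
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        c = 1.0 + aa / c
        d = 1.0 / (d if abs(d) >= 1e-300 else 1e-300)
        c = c if abs(c) >= 1e-300 else 1e-300
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def _reg_inc_beta(a, b, x):
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    front = math.exp(
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log(1.0 - x)
    )
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def t_two_sided_oracle(t, df):
    """P(|T_df| >= |t|) = I_{df/(df+t^2)}(df/2, 1/2)."""
    return _reg_inc_beta(df / 2.0, 0.5, df / (df + t * t))


# ---------------------------------------------------------------------------


class TestValidityRate:
    @pytest.mark.parametrize(
        "valid,total,expected",
        [(142, 192, 74.0), (81, 127, 63.8), (58, 62, 93.5), (0, 10, 0.0)],
    )
    def test_printed_proportions(self, valid, total, expected):
        assert validity_rate(valid, total) == expected

    @given(
        v=stn.integers(min_value=0, max_value=500),
        n=stn.integers(min_value=1, max_value=500),
        k=stn.integers(min_value=1, max_value=20),
    )
    @settings(deadline=None, max_examples=100)
    def test_scale_free(self, v, n, k):
        v = min(v, n)
        assert validity_rate(k * v, k * n) == validity_rate(v, n)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            validity_rate(0, 0)


class TestOneSampleT:
    def test_table_rows_not_significant(self):
        # cohort rows (n=17) against their protocol targets: no deviation
        assert one_sample_t(3.8, 1.3, 17, 4.0).p_two_sided > 0.05
        assert one_sample_t(23.1, 14.3, 17, 21.0).p_two_sided > 0.05

    def test_mean_equal_target_gives_p_one(self):
        res = one_sample_t(4.0, 1.2, 17, 4.0)
        assert res.t_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "mean,sd,n,target",
        [(23.1, 14.3, 17, 21.0), (3.8, 1.3, 17, 4.0), (10.0, 2.0, 5, 7.0),
         (0.1, 0.5, 100, 0.0), (-4.0, 3.0, 12, 1.0)],
    )
    def test_p_matches_independent_t_cdf_oracle(self, mean, sd, n, target):
        res = one_sample_t(mean, sd, n, target)
        oracle = t_two_sided_oracle(res.t_statistic, res.df)
        assert res.p_two_sided == pytest.approx(oracle, abs=1e-6)

    def test_oracle_agreement_on_grid(self):
        for t in (-5.0, -1.3, 0.0, 0.7, 2.1, 8.0):
            for df in (1, 4, 16, 60):
                mean = t * 1.0 / np.sqrt(df + 1)
                res = one_sample_t(mean, 1.0, df + 1, 0.0)
                assert res.p_two_sided == pytest.approx(
                    t_two_sided_oracle(res.t_statistic, df), abs=1e-6
                )

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            one_sample_t(3.8, 0.0, 17, 4.0)


class TestSummarizeAdherence:
    @staticmethod
    def _log(rows):
        return pd.DataFrame(
            rows, columns=["participant_id", "activity", "session_datetime"]
        )

    def test_weekly_schedule_arithmetic(self):
        rows = [
            ("P1", act, f"2023-01-{2 + d:02d}T09:00:00")
            for d in (0, 7, 14, 21)
            for act in ("sts", "slb")
        ]
        summ = summarize_adherence(self._log(rows))
        p = summ.per_participant.loc["P1"]
        assert p["n_sessions_sts"] == 4
        assert p["n_sessions_slb"] == 4
        assert p["mean_gap_days"] == 7.0
        assert p["trial_span_days"] == 21.0

    def test_single_session_participant_excluded_from_gaps(self):
        rows = [
            ("P1", "sts", "2023-01-02T09:00:00"),
            ("P2", "sts", "2023-01-02T09:00:00"),
            ("P2", "sts", "2023-01-09T09:00:00"),
        ]
        summ = summarize_adherence(self._log(rows))
        assert not summ.per_participant.loc["P1", "gap_defined"]
        assert summ.cohort.loc["mean_gap_days", "n"] == 1
        assert summ.cohort.loc["mean_gap_days", "mean"] == 7.0

    def test_same_day_repeats_collapse_for_gaps_only(self):
        rows = [
            ("P1", "sts", "2023-01-02T09:00:00"),
            ("P1", "sts", "2023-01-02T17:00:00"),
            ("P1", "sts", "2023-01-09T09:00:00"),
        ]
        summ = summarize_adherence(self._log(rows))
        p = summ.per_participant.loc["P1"]
        assert p["n_sessions_sts"] == 3  # totals count rows
        assert p["mean_gap_days"] == 7.0  # gaps use distinct days

    def test_permutation_invariance(self):
        rows = [
            ("P1", "sts", "2023-01-02T09:00:00"),
            ("P2", "slb", "2023-01-05T10:00:00"),
            ("P1", "slb", "2023-01-09T09:00:00"),
            ("P2", "sts", "2023-01-12T10:00:00"),
        ]
        a = summarize_adherence(self._log(rows))
        b = summarize_adherence(self._log(rows[::-1]))
        pd.testing.assert_frame_equal(a.per_participant, b.per_participant)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)

    def test_empty_log_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            summarize_adherence(self._log([]))


class TestEngagementReport:
    def test_report_contains_target_rows_and_validity(self):
        rows = [
            (f"P{p}", act, f"2023-01-{2 + 7 * w:02d}T09:00:00")
            for p in (1, 2, 3)
            for w in range(4)
            for act in ("sts", "slb")
        ]
        log = pd.DataFrame(rows, columns=["participant_id", "activity", "session_datetime"])
        summ = summarize_adherence(log)
        rep = engagement_report(
            summ, validity_counts={"sts": (58, 62), "slb": (81, 127), "overall": (142, 192)}
        )
        for metric in ("trial_span_days", "mean_gap_days", "n_sessions_sts",
                       "n_sessions_slb"):
            assert metric in rep.index
        assert rep.loc["valid_uploads_pct_overall", "mean"] == 74.0
        assert rep.loc["valid_uploads_pct_slb", "mean"] == 63.8
        # degenerate schedule: every participant exactly on target
        assert rep.loc["n_sessions_sts", "mean"] == 4.0

    def test_single_participant_cohort_has_no_tests(self):
        log = pd.DataFrame(
            [("P1", "sts", f"2023-01-{2 + 7 * w:02d}T09:00:00") for w in range(4)],
            columns=["participant_id", "activity", "session_datetime"],
        )
        rep = engagement_report(summarize_adherence(log))
        assert np.isnan(rep.loc["n_sessions_sts", "p_vs_target"])
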