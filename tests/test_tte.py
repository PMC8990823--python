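import math

import numpy as np
import pytest

from faersvig.pipeline import run_pipeline
from faersvig.synthetic import ScenarioConfig, generate
from faersvig.tte import (
    cumulative_curve,
    onset_days,
    onset_records,
    onset_summary,
    outcome_comparison,
)


class TestOnsetDays:
    @pytest.mark.parametrize(
        "event_dt,start_dt,days,reason",
        [
            ("20200410", "20200405", 5, None),
            ("20200405", "20200405", 0, None),  # same-day onset kept
            ("202004", "20200405", None, "partial_date"),
            ("20200410", "", None, "partial_date"),
            ("20200401", "20200405", None, "negative_interval"),
            ("20200301", "20200228", 2, None),  # 2020 is a leap year
            ("20210301", "20210228", 1, None),  # 2021 is not
            ("20200230", "20200201", None, "invalid_date"),
        ],
    )
    def test_calendar_arithmetic_and_exclusions(self, event_dt, start_dt, days, reason):
        o = onset_days(event_dt, start_dt)
        assert o.days == days and o.reason == reason

    def test_accounting_is_exhaustive(self, small_quarter):
        cohort = run_pipeline(small_quarter.tables).cohort
        recs = onset_records(cohort)
        n_event = int(cohort.event.sum())
        assert len(recs) == n_event
        assert recs.days.notna().sum() + (recs.reason != "").sum() == n_event

    def test_clean_quarter_days_match_planted_onsets(self, clean_quarter):
        cohort = run_pipeline(clean_quarter.tables).cohort
        recs = onset_records(cohort).set_index("caseid")
        truth = clean_quarter.truth.onset_days
        assert set(recs.index) == set(truth)
        for caseid, days in truth.items():
            assert recs.loc[caseid, "days"] == days


class TestOnsetSummary:
    def test_mean_and_sample_sd(self):
        s = onset_summary([0, 5, 10])
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(5.0)  # n-1 denominator

    def test_single_observation_has_no_sd(self):
        s = onset_summary([4])
        assert s.n == 1 and s.mean == 4.0 and s.sd is None

    def test_cumulative_curve_monotone_reaching_one(self):
        curve = cumulative_curve([3, 1, 1, 7, 3, 10])
        assert (np.diff(curve.cum_prop) > 0).all()
        assert curve.cum_prop.iloc[-1] == pytest.approx(1.0)
        assert curve.day.iloc[-1] == 10
        # fraction within 3 days: 4 of 6 onsets
        assert float(curve.loc[curve.day == 3, "cum_prop"].iloc[0]) == pytest.approx(4 / 6)

    def test_exponential_onsets_recover_distribution_mean(self):
        scale = 5.0
        cfg = ScenarioConfig(
            n_exposed=1000,
            n_control=1000,
            true_or=1.0,
            baseline_event_prob=0.25,
            partial_date_prob=0.0,
            preexisting_event_prob=0.0,
            onset_dist=("exponential", {"scale": scale}),
            seed=101,
        )
        cohort = run_pipeline(generate(cfg).tables).cohort
        days = onset_records(cohort).days.dropna()
        # days are floor(Exp(scale)); E = 1/(exp(1/scale)-1), Var via geometric
        q = math.exp(-1 / scale)
        mean_true = q / (1 - q)
        sd_true = math.sqrt(q) / (1 - q)
        assert len(days) > 300
        assert abs(days.mean() - mean_true) < 3 * sd_true / math.sqrt(len(days))


@pytest.fixture(scope="module")
def outcome_cohort():
    probs = {
        "event": {"DE": 0.30, "LT": 0.05, "HO": 0.2, "DS": 0.0, "CA": 0.0, "RI": 0.0, "OT": 0.3},
        "no_event": {"DE": 0.10, "LT": 0.05, "HO": 0.3, "DS": 0.0, "CA": 0.0, "RI": 0.0, "OT": 0.4},
    }
    cfg = ScenarioConfig(
        n_exposed=1500,
        n_control=1500,
        true_or=2.0,
        baseline_event_prob=0.20,
        outcome_probs=probs,
        outcome_report_prob=1.0,
        seed=55,
    )
    return run_pipeline(generate(cfg).tables).cohort


class TestOutcomeComparison:
    def test_death_fraction_within_binomial_bounds(self, outcome_cohort):
        table = outcome_comparison(outcome_cohort, "remdesivir").set_index("outcome")
        n_event = outcome_cohort[
            (outcome_cohort.exposure == "remdesivir")
            & outcome_cohort.event
            & (outcome_cohort.outcome != "none")
        ].shape[0]
        # collapse keeps DE whenever drawn; conditioning on having any
        # outcome, the expected death share is p_DE / (1 - prod(1 - p_c))
        p_none = (1 - 0.30) * (1 - 0.05) * (1 - 0.2) * (1 - 0.3)
        p_de = 0.30 / (1 - p_none)
        p_hat = table.loc["DE", "event_pct"] / 100
        se = math.sqrt(p_de * (1 - p_de) / n_event)
        assert abs(p_hat - p_de) < 1.96 * se + 1e-9

    def test_percentages_sum_to_100_per_column(self, outcome_cohort):
        table = outcome_comparison(outcome_cohort, "control")
        assert table.event_pct.sum() == pytest.approx(100.0)
        assert table.nonevent_pct.sum() == pytest.approx(100.0)

    def test_empty_group_skips_tests(self, outcome_cohort):
        sub = outcome_cohort[~outcome_cohort.event].copy()
        table = outcome_comparison(sub, "remdesivir")
        assert (table.event_n == 0).all()
        assert (table.test == "skipped").all()
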