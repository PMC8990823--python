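import numpy as np
import pandas as pd
import pytest

from faersvig.cohort import cohort_2x2
from faersvig.pipeline import run_pipeline
from faersvig.psm import (
    MatchSpec,
    balance_table,
    estimate_propensity,
    match_pairs,
    matched_cohort,
    standardized_differences,
)
from faersvig.synthetic import ConfounderSpec, ScenarioConfig, confounded_scenario, generate


def frame(rows):
    return pd.DataFrame(rows)


class TestEstimatePropensity:
    def test_saturated_model_equals_stratum_fractions(self):
        rows = []
        for stratum, n_exp, n_ctl in [("a", 30, 70), ("b", 10, 90)]:
            rows += [{"caseid": f"{stratum}e{i}", "exposure": "remdesivir", "g": stratum} for i in range(n_exp)]
            rows += [{"caseid": f"{stratum}c{i}", "exposure": "control", "g": stratum} for i in range(n_ctl)]
        model = estimate_propensity(frame(rows), covariates=("g",))
        scores = model.scores
        assert scores.loc["ae0"] == pytest.approx(0.30, abs=1e-6)
        assert scores.loc["bc0"] == pytest.approx(0.10, abs=1e-6)

    def test_independent_exposure_gives_flat_scores(self):
        rng = np.random.default_rng(5)
        n = 4000
        df = frame(
            {
                "caseid": [str(i) for i in range(n)],
                "exposure": np.where(rng.random(n) < 0.3, "remdesivir", "control"),
                "g": rng.choice(["a", "b", "c"], size=n),
            }
        )
        scores = estimate_propensity(df, covariates=("g",)).scores
        prevalence = (df.exposure == "remdesivir").mean()
        assert np.abs(scores - prevalence).max() < 0.05

    def test_recovers_planted_exposure_coefficient_within_2_se(self):
        cfg = ScenarioConfig(
            n_exposed=6000,
            n_control=14000,
            true_or=1.5,
            baseline_event_prob=0.05,
            confounders={
                "grp": ConfounderSpec(
                    levels=("a", "b"), probs=(0.5, 0.5), exposure_logodds=(0.0, 0.8)
                )
            },
            seed=17,
        )
        cases = generate(cfg).truth.cases
        df = cases.assign(
            exposure=np.where(cases.exposed, "remdesivir", "control")
        )[["caseid", "exposure", "grp"]]
        model = estimate_propensity(df, covariates=("grp",))
        beta, se = model.params["grp_b"], model.bse["grp_b"]
        assert abs(beta - 0.8) < 2 * se

    def test_scores_in_open_unit_interval(self, small_quarter):
        cohort = run_pipeline(small_quarter.tables).cohort
        scores = estimate_propensity(cohort).scores
        assert ((scores > 0) & (scores < 1)).all()


def brute_force_optimum(exp_scores, ctl_scores, caliper):
    """(max pairs, min total distance) by bitmask DP over controls."""
    n_e, n_c = len(exp_scores), len(ctl_scores)
    best = {0: 0.0}  # control-usage mask -> min distance, per pair count
    # dp[i][mask] = min cost pairing first i exposed using controls in mask
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def dp(i, mask):
        if i == n_e:
            return (0, 0.0)
        skip = dp(i + 1, mask)
        best_pairs, best_cost = skip
        for j in range(n_c):
            if mask & (1 << j):
                continue
            d = abs(exp_scores[i] - ctl_scores[j])
            if d > caliper:
                continue
            p, c = dp(i + 1, mask | (1 << j))
            cand = (p + 1, c + d)
            if cand[0] > best_pairs or (cand[0] == best_pairs and cand[1] < best_cost - 1e-15):
                best_pairs, best_cost = cand
        return (best_pairs, best_cost)

    return dp(0, 0)


class TestMatchPairs:
    def test_only_admissible_pair_selected(self):
        scores = pd.Series({"e1": 0.30, "c1": 0.3002, "c2": 0.40})
        res = match_pairs(scores, ["e1"], ["c1", "c2"], MatchSpec(caliper=0.001))
        assert res.pairs == [("e1", "c1")]

    def test_optimal_beats_greedy_crossing(self):
        scores = pd.Series({"e1": 0.30, "e2": 0.31, "c1": 0.31, "c2": 0.30})
        res = match_pairs(scores, ["e1", "e2"], ["c1", "c2"], MatchSpec(caliper=0.05))
        assert sorted(res.pairs) == [("e1", "c2"), ("e2", "c1")]  # total distance 0

    def test_no_admissible_pair_warns_not_raises(self):
        scores = pd.Series({"e1": 0.1, "c1": 0.9})
        res = match_pairs(scores, ["e1"], ["c1"], MatchSpec(caliper=0.001))
        assert res.pairs == [] and res.warning is not None

    def test_matches_exhaustive_optimum_on_small_instances(self):
        rng = np.random.default_rng(29)
        for trial in range(40):
            n_e = int(rng.integers(1, 9))
            n_c = int(rng.integers(1, 11))
            e = rng.random(n_e)
            c = rng.random(n_c)
            caliper = float(rng.uniform(0.05, 0.6))
            scores = pd.Series(
                np.concatenate([e, c]),
                index=[f"e{i}" for i in range(n_e)] + [f"c{j}" for j in range(n_c)],
            )
            res = match_pairs(
                scores, [f"e{i}" for i in range(n_e)], [f"c{j}" for j in range(n_c)],
                MatchSpec(caliper=caliper),
            )
            got_pairs = len(res.pairs)
            got_cost = sum(abs(scores[a] - scores[b]) for a, b in res.pairs)
            opt_pairs, opt_cost = brute_force_optimum(tuple(e), tuple(c), caliper)
            assert got_pairs == opt_pairs
            assert got_cost == pytest.approx(opt_cost, abs=1e-12)

    def test_one_to_one_within_caliper(self, small_quarter):
        cohort = run_pipeline(small_quarter.tables).cohort
        scores = estimate_propensity(cohort).scores
        spec = MatchSpec(caliper=0.05)
        res = match_pairs(
            scores,
            cohort.loc[cohort.exposure == "remdesivir", "caseid"],
            cohort.loc[cohort.exposure == "control", "caseid"],
            spec,
            covariate_frame=cohort.set_index("caseid"),
        )
        ids = [i for p in res.pairs for i in p]
        assert len(ids) == len(set(ids))  # no caseid reused
        for e, c in res.pairs:
            assert abs(scores[e] - scores[c]) <= spec.caliper + 1e-12
        matched = matched_cohort(cohort, res)
        assert (matched.exposure == "remdesivir").sum() == (matched.exposure == "control").sum()

    def test_exact_pairs_agree_on_all_covariate_levels(self, small_quarter):
        cohort = run_pipeline(small_quarter.tables).cohort
        scores = estimate_propensity(cohort).scores
        spec = MatchSpec(caliper=0.05, exact_then_fuzzy=True)
        cf = cohort.set_index("caseid")
        res = match_pairs(
            scores,
            cohort.loc[cohort.exposure == "remdesivir", "caseid"],
            cohort.loc[cohort.exposure == "control", "caseid"],
            spec,
            covariate_frame=cf,
        )
        assert res.n_exact > 0
        for e, c in res.pairs[: res.n_exact]:
            for cov in spec.covariates:
                assert cf.loc[e, cov] == cf.loc[c, cov]


@pytest.fixture(scope="module")
def confounded_run():
    quarter = generate(confounded_scenario(seed=3, n_exposed=2000, n_control=4000))
    cohort = run_pipeline(quarter.tables).cohort
    scores = estimate_propensity(cohort).scores
    res = match_pairs(
        scores,
        cohort.loc[cohort.exposure == "remdesivir", "caseid"],
        cohort.loc[cohort.exposure == "control", "caseid"],
        MatchSpec(caliper=0.01),
        covariate_frame=cohort.set_index("caseid"),
    )
    return cohort, res


class TestBalance:
    def test_matching_reduces_standardized_differences(self, confounded_run):
        cohort, res = confounded_run
        pre = standardized_differences(
            cohort,
            cohort.loc[cohort.exposure == "remdesivir", "caseid"],
            cohort.loc[cohort.exposure == "control", "caseid"],
        )
        post = standardized_differences(
            cohort, [e for e, _ in res.pairs], [c for _, c in res.pairs]
        )
        # the planted confounders must improve markedly
        assert post["age_band"] < pre["age_band"]
        assert post["sex"] < pre["sex"]
        assert (post < 0.1).all()

    def test_post_match_balance_not_significant(self, confounded_run):
        cohort, res = confounded_run
        balance = balance_table(cohort, res)
        for cov, b in balance.items():
            assert b.test.p > 0.05, f"{cov} unbalanced after matching"

    def test_matching_removes_positive_confounding(self, confounded_run):
        # older/male cases are both more exposed and more at risk, so the
        # crude ROR is inflated relative to the confounding-free contrast;
        # balancing the covariates must pull the estimate down.  (The
        # matched ROR is not expected to equal the conditional OR: the
        # odds ratio is non-collapsible.)
        from faersvig.stats import ror_2x2

        cohort, res = confounded_run
        crude = ror_2x2(*cohort_2x2(cohort)).ror
        matched = ror_2x2(*cohort_2x2(matched_cohort(cohort, res))).ror
        assert matched < crude
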