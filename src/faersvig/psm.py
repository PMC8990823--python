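"""Propensity-score estimation, 1:1 optimal matching, balance diagnostics.

The propensity score is the modelled probability of being in the exposed
group given observed covariates — here the categorical FAERS demographics
age band, sex, reporter type and occurrence country, each with an explicit
``Unknown`` level (missingness is a category of its own, never imputed).
Scores come from a main-effects logistic regression on one-hot covariates.

Matching is 1:1 without replacement with a caliper (maximum allowed score
distance within a pair, default 0.001).  "Optimal" means the pairing
minimises the total within-pair score distance over all pairings that
respect the caliper, solved exactly as a rectangular assignment problem.
When ``exact_then_fuzzy`` is on, cases agreeing on *all* covariate levels
are paired first (still optimally on score within each stratum), and only
the leftovers enter the global fuzzy phase — mirroring the exact+fuzzy
matching options of mainstream PSM software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

from .stats import RxCResult, pearson_rxc

__all__ = [
    "MatchSpec",
    "PropensityModel",
    "MatchResult",
    "estimate_propensity",
    "match_pairs",
    "balance_table",
    "standardized_differences",
]

DEFAULT_COVARIATES = ("age_band", "sex", "reporter", "country")


@dataclass(frozen=True)
class MatchSpec:
    """Matching configuration: 1:1, without replacement, caliper on the
    propensity-score scale."""

    covariates: tuple = DEFAULT_COVARIATES
    caliper: float = 0.001
    exact_then_fuzzy: bool = True

    def __post_init__(self):
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")


@dataclass
class PropensityModel:
    """Fitted exposure model: per-case scores plus coefficient table."""

    scores: pd.Series  # indexed by caseid, values in (0, 1)
    params: pd.Series  # logit coefficients (one-hot, first level dropped)
    bse: pd.Series  # coefficient standard errors
    reference_levels: dict  # covariate -> level absorbed into the intercept


@dataclass
class MatchResult:
    pairs: list = field(default_factory=list)  # (exposed caseid, control caseid)
    scores: pd.Series | None = None
    n_matched: int = 0
    n_exact: int = 0
    unmatched_exposed: list = field(default_factory=list)
    warning: str | None = None

    @property
    def matched_ids(self) -> set:
        return {i for pair in self.pairs for i in pair}


def _design_matrix(cohort: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    cats = cohort[list(covariates)].astype(str)
    refs = {c: sorted(cats[c].unique())[0] for c in covariates}
    X = pd.get_dummies(cats, drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    return X, refs


def estimate_propensity(
    cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> PropensityModel:
    """Logistic regression of exposure on one-hot categorical covariates.

    The first level of each covariate (alphabetically) is the reference,
    absorbed into the intercept.  Returns in-sample scores indexed by
    ``caseid``.
    """
    X, refs = _design_matrix(cohort, covariates)
    y = (cohort["exposure"] == "remdesivir").astype(float)
    fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200, method="lbfgs")
    scores = pd.Series(fit.predict(X.to_numpy()), index=cohort["caseid"].to_numpy())
    return PropensityModel(
        scores=scores,
        params=pd.Series(fit.params, index=X.columns),
        bse=pd.Series(fit.bse, index=X.columns),
        reference_levels=refs,
    )


def _optimal_1to1(
    exp_ids: list, exp_scores: np.ndarray, ctl_ids: list, ctl_scores: np.ndarray, caliper: float
) -> list[tuple]:
    """Min-total-distance 1:1 assignment under a caliper; exact solution."""
    if not exp_ids or not ctl_ids:
        return []
    cost = np.abs(exp_scores[:, None] - ctl_scores[None, :])
    admissible = cost <= caliper
    if not admissible.any():
        return []
    # a large finite penalty keeps the problem feasible; penalised pairs
    # are discarded afterwards, which cannot hurt the caliper-respecting
    # pairs (the assignment is still distance-optimal among them)
    big = caliper * (len(exp_ids) + len(ctl_ids) + 1) + 1.0
    masked = np.where(admissible, cost, big)
    rows, cols = linear_sum_assignment(masked)
    return [
        (exp_ids[i], ctl_ids[j]) for i, j in zip(rows, cols) if admissible[i, j]
    ]


def match_pairs(
    scores: pd.Series,
    exposed_ids,
    control_ids,
    spec: MatchSpec = MatchSpec(),
    covariate_frame: pd.DataFrame | None = None,
) -> MatchResult:
    """1:1 optimal matching of exposed to control cases on propensity score.

    Parameters
    ----------
    scores
        Propensity scores indexed by caseid (from
        :func:`estimate_propensity`).
    exposed_ids, control_ids
        Caseids of the two groups (disjoint).
    spec
        Caliper and phase configuration.
    covariate_frame
        Covariate levels indexed by caseid; required for the exact phase
        when ``spec.exact_then_fuzzy`` is on, ignored otherwise.

    Returns
    -------
    MatchResult
        One-to-one pairs (no caseid reused), each within the caliper.
        Exposed cases with no admissible partner are listed in
        ``unmatched_exposed``; an empty result carries a warning instead
        of raising.
    """
    exposed = sorted(exposed_ids)
    control = sorted(control_ids)
    result = MatchResult(scores=scores)

    pairs: list[tuple] = []
    used_e: set = set()
    used_c: set = set()

    if spec.exact_then_fuzzy and covariate_frame is not None and len(spec.covariates):
        cf = covariate_frame[list(spec.covariates)].astype(str)
        pattern = cf.apply(tuple, axis=1)
        strata_e: dict[tuple, list] = {}
        for cid in exposed:
            strata_e.setdefault(pattern.loc[cid], []).append(cid)
        strata_c: dict[tuple, list] = {}
        for cid in control:
            strata_c.setdefault(pattern.loc[cid], []).append(cid)
        for pat in sorted(strata_e):
            if pat not in strata_c:
                continue
            e_ids, c_ids = strata_e[pat], strata_c[pat]
            got = _optimal_1to1(
                e_ids,
                scores.loc[e_ids].to_numpy(),
                c_ids,
                scores.loc[c_ids].to_numpy(),
                spec.caliper,
            )
            pairs.extend(got)
            used_e.update(e for e, _ in got)
            used_c.update(c for _, c in got)
        result.n_exact = len(pairs)

    rest_e = [c for c in exposed if c not in used_e]
    rest_c = [c for c in control if c not in used_c]
    fuzzy = _optimal_1to1(
        rest_e,
        scores.loc[rest_e].to_numpy() if rest_e else np.empty(0),
        rest_c,
        scores.loc[rest_c].to_numpy() if rest_c else np.empty(0),
        spec.caliper,
    )
    pairs.extend(fuzzy)
    used_e.update(e for e, _ in fuzzy)

    result.pairs = pairs
    result.n_matched = len(pairs)
    result.unmatched_exposed = [c for c in exposed if c not in used_e]
    if not pairs:
        result.warning = "no admissible pair under the caliper"
    return result


def matched_cohort(cohort: pd.DataFrame, result: MatchResult) -> pd.DataFrame:
    """Subset of the cohort restricted to matched cases."""
    return cohort[cohort["caseid"].isin(result.matched_ids)].copy()


@dataclass
class CovariateBalance:
    counts: pd.DataFrame  # level x group counts with percentages
    test: RxCResult


def balance_table(
    cohort: pd.DataFrame, result: MatchResult, covariates=DEFAULT_COVARIATES
) -> dict[str, CovariateBalance]:
    """Post-match per-covariate level counts, percentages and chi-square.

    For each covariate, levels are cross-tabulated against the exposure
    group on matched cases only, with column percentages and the
    uncorrected Pearson r x c test of post-match independence.
    """
    sub = matched_cohort(cohort, result)
    out: dict[str, CovariateBalance] = {}
    for cov in covariates:
        ct = pd.crosstab(sub[cov], sub["exposure"])
        for g in ct.columns:
            total = ct[g].sum()
            ct[f"{g}_pct"] = 100.0 * ct[g] / total if total else 0.0
        test = pearson_rxc(ct[[c for c in ct.columns if not str(c).endswith("_pct")]].to_numpy())
        out[cov] = CovariateBalance(counts=ct, test=test)
    return out


def standardized_differences(
    cohort: pd.DataFrame, exposed_ids, control_ids, covariates=DEFAULT_COVARIATES
) -> pd.Series:
    """Max absolute standardized difference per covariate between groups.

    For a categorical covariate the standardized difference of each level's
    prevalence is |p1 - p0| / sqrt((p1(1-p1) + p0(1-p0))/2); the covariate
    is summarised by its worst level.  Used to verify that matching reduces
    imbalance.
    """
    idx = cohort.set_index("caseid")
    e = idx.loc[sorted(exposed_ids)]
    c = idx.loc[sorted(control_ids)]
    out = {}
    for cov in covariates:
        levels = sorted(set(e[cov]) | set(c[cov]))
        worst = 0.0
        for lev in levels:
            p1 = (e[cov] == lev).mean()
            p0 = (c[cov] == lev).mean()
            denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
            if denom > 0:
                worst = max(worst, abs(p1 - p0) / denom)
        out[cov] = worst
    return pd.Series(out)
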