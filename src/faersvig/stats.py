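"""Disproportionality and contingency-table statistics.

The reporting odds ratio (ROR) is the workhorse of spontaneous-report
signal detection.  On the drug x event 2x2 table of report counts

====================  =========  ============
group                 event      no event
====================  =========  ============
drug of interest      a          b
comparator drugs      c          d
====================  =========  ============

the ROR is ``(a/b)/(c/d) = ad/bc`` — the odds of the event among reports
of the drug relative to the odds among comparator reports.  It is a
measure of *reporting* disproportionality, not of incidence.  The 95%
confidence interval is the Woolf log-odds interval

    exp( ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = Phi^-1(0.975)

and a signal is declared when the lower bound exceeds 1.

Group comparisons use the uncorrected Pearson chi-square (no Yates
continuity correction); sparse tables (any expected count < 5) switch to
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyResult",
    "RxCResult",
    "ror_2x2",
    "pearson_rxc",
    "fisher_2x2",
    "choose_test",
]

# two-sided 95% normal quantile; at 2-decimal reporting this is
# indistinguishable from the conventional 1.96
Z_95 = float(sps.norm.ppf(0.975))


@dataclass
class ContingencyResult:
    """A 2x2 drug x event table with its disproportionality statistics.

    ``a`` = exposed & event, ``b`` = exposed & no event, ``c`` = control &
    event, ``d`` = control & no event.  ``signal`` is True iff the CI lower
    bound exceeds 1.  ``degenerate`` marks tables with a zero cell, where
    the Woolf interval is undefined and the Haldane–Anscombe +0.5
    correction was applied to every cell for the ROR and CI.
    """

    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    test_used: str  # "chi-square" | "fisher"
    signal: bool
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def choose_test(table) -> str:
    """Pearson chi-square unless any expected count is below 5, else Fisher.

    ``table`` is any r x c array of counts; expected counts are the usual
    product-of-margins estimates.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        return "fisher"
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return "fisher" if (expected < 5).any() else "chi-square"


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (at the observed margins) no more likely than the observed one."""
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def ror_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Reporting odds ratio with 95% Woolf CI, chi-square and p for a 2x2.

    The p-value comes from the uncorrected Pearson chi-square test, or from
    Fisher's exact test when any expected count is below 5 (``test_used``
    records which).  All four counts must be non-negative.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)

    degenerate = 0 in (a, b, c, d)
    if degenerate:
        # Haldane–Anscombe: +0.5 to every cell for estimation only
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)

    ror = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(ror) - Z_95 * se)
    ci_high = math.exp(math.log(ror) + Z_95 * se)

    chi2 = _pearson_chi2_2x2(a, b, c, d)
    test = choose_test([[a, b], [c, d]])
    if test == "chi-square":
        p = float(sps.chi2.sf(chi2, df=1))
    else:
        p = fisher_2x2(a, b, c, d)

    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        ror=ror, ci_low=ci_low, ci_high=ci_high,
        chi2=chi2, p=p, test_used=test,
        signal=bool(ci_low > 1.0), degenerate=degenerate,
    )


@dataclass
class RxCResult:
    statistic: float
    df: int
    p: float


def pearson_rxc(table) -> RxCResult:
    """Uncorrected Pearson chi-square for an r x c count table.

    ``statistic = sum (O-E)^2 / E`` over all cells with
    ``df = (r-1)(c-1)``.  Rows or columns summing to zero are dropped
    before computation (they carry no information and would make E = 0).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return RxCResult(float("nan"), 0, float("nan"))
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return RxCResult(float(stat), int(df), float(p))
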