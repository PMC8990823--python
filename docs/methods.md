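# Methods

This note documents the statistical procedures, the design choices made
where the conventions of the field leave room, and what the synthetic data
do and do not establish.

## Data model and ingestion

FAERS quarters are seven `$`-delimited ASCII tables with one header line
and no quoting, so parsing is an exact split. Column names are matched
case-insensitively against the FAERS vocabulary (with the common aliases
`isr`→`primaryid`, `gndr_cod`→`sex`, `outc_code`→`outc_cod`); unknown
columns are preserved verbatim in an `extras` map so quarters with column
supersets round-trip loss-free. A line whose field count differs from the
header is skipped and counted (`records + skipped == data lines`); a
missing mandatory column (e.g. `caseid` in DEMO) is a hard error. Dates
stay raw strings at ingestion because the validity rules are
stage-specific: deduplication compares possibly-partial strings, while
time-to-onset demands full dates.

Ages convert to years via the FAERS unit codes (DEC ×10, YR ×1, MON ÷12,
WK ×7/365.25, DY ÷365.25, HR ÷8766); anything else is missing. Age bands
are `<18`, `18–44`, `45–64`, `≥65`, `Unknown`, closed on the left (18.0
falls in 18–44, 65.0 in ≥65).

## Deduplication

Three rules in order: (1) byte-identical DEMO rows collapse to one;
(2) per `caseid` only the maximal `fda_dt` survives; (3) ties resolve to
the maximal `primaryid`. `fda_dt` comparison is lexicographic on the
8-digit string — chronological for valid `yyyymmdd` — with partial strings
right-padded with zeros (a partial date sorts as its earliest completion;
no other convention is defensible without more information). `primaryid`
comparison is numeric when both sides parse as integers, since "lower"
is a numeric notion. After rule (3) exactly one record per case remains,
so no further tie-break can be needed. Records with an empty `caseid`
cannot be grouped; they pass through and are flagged rather than dropped.
Child tables are filtered to surviving `primaryid`s afterwards — the
procedure itself touches only DEMO.

## SMQ matching

Preferred terms are a controlled vocabulary, so matching is exact on
trimmed, case-folded text — never substring. A case reporting several
matching terms counts once (set semantics). Narrow-scope queries are a
subset of broad-scope ones by construction of the loader, which gives the
monotonicity property (broad finds at least the narrow cases) for free.
Cases whose *indications* match the event query are excluded from the
cohort: the event predating the drug cannot be treatment-emergent.

The bundled term lists are synthetic placeholders with the cardinalities
of the real v23.1 queries (COVID-19 narrow 18 PTs; AKI narrow 19, broad
52) because MedDRA cannot be redistributed; all behaviour is parameterized
on the lists and licensed users can drop in the real CSVs.

## Cohort and sensitivity variants

Exposure is case-insensitive substring containment of the study-drug
names (`remdesivir`, `veklury`) in either `drugname` or `prod_ai` on rows
with the required role code — substring because free-text drug names carry
dose and salt suffixes. The control group is every remaining disease-cohort
case with some other drug as primary suspect; under the named-control
variant, only the five listed alternatives (`lopinavir` matches the
combination product under either separator). A study-drug-exposed case can
never enter a control group — the groups must partition for the ROR to be
well defined. The three sensitivity variants are: broad event SMQ;
exposure by primary *or* secondary suspect role; and the named five-drug
control.

Multiple serious outcomes per case collapse to the most serious under
DE > LT > HO > DS > CA > RI > OT. The first comparison (death over
hospitalization) is the documented convention; the rest follow the
standard severity ordering of the outcome codes. Missing sex, reporter
type and country map to an explicit `Unknown` level — missingness is
analysed as its own category, never imputed or dropped.

## Contingency statistics

The ROR point estimate is `ad/bc`; the 95% CI is the Woolf log-odds
interval with `z = Φ⁻¹(0.975) = 1.959964`. With two-decimal reporting
this is indistinguishable from the conventional 1.96. The Pearson
chi-square is uncorrected (no Yates continuity correction), which is what
reproduces published two-decimal values in this literature. Fisher's exact
two-sided p (via `scipy.stats.fisher_exact`, verified in the tests against
full hypergeometric enumeration) replaces the chi-square whenever any
expected count is below 5. A zero cell makes the Woolf interval undefined;
the result is then flagged `degenerate` and estimated with the
Haldane–Anscombe +0.5 correction on all cells — the flag matters more than
the number. R×C tables drop all-zero rows/columns before testing.

## Propensity-score matching

The exposure model is a main-effects logistic regression on one-hot
encoded categorical covariates (age band, sex, reporter, country), fitted
by maximum likelihood (statsmodels, L-BFGS); the alphabetically first
level of each covariate is the reference. `Unknown` is an ordinary level.

Matching is 1:1 without replacement under a caliper of 0.001 on the score
scale. "Optimal" is taken literally: among pairings that respect the
caliper, first maximise the number of pairs, then minimise the total
within-pair score distance — solved exactly with rectangular assignment
(`scipy.optimize.linear_sum_assignment`) on a cost matrix whose
caliper-violating entries carry a penalty larger than any admissible total,
which makes the lexicographic objective exact; penalised assignments are
discarded afterwards. With `exact_then_fuzzy` on (the default), cases
agreeing on *all* covariate levels are matched first within their stratum,
and only leftovers enter the global fuzzy phase — mirroring the
exact+fuzzy option pairing of mainstream PSM software. Candidate order is
sorted by caseid, and the assignment solver is deterministic, so the whole
pipeline is reproducible without a seed.

Matching on the propensity score balances covariates; it does not make the
matched odds ratio equal the conditional odds ratio, because the odds
ratio is non-collapsible. The tests therefore assert balance (standardized
differences, post-match chi-square) and the *direction* of the confounding
correction, not numeric equality with the generating odds ratio.

## Time to onset and outcomes

Onset is `EVENT_DT − START_DT` in whole calendar days. Excluded with
reasons: either date partial or non-numeric (`partial_date`), impossible
calendar dates (`invalid_date`), event strictly before start
(`negative_interval`). Same-day onset is 0 days and is kept — only events
*earlier* than the start are implausible. When a case has several therapy
rows for its suspect drug, the earliest valid full start date is used.
Summaries are the mean, the sample SD (n−1), and the cumulative fraction
of onsets by each day. The outcome comparison restricts to cases reporting
at least one outcome, and contrasts each code between event and non-event
cases with the chi-square/Fisher rule above.

## Synthetic data: what it emulates, and what it does not

The generator draws, per case: covariate levels from configurable
frequencies; exposure either as exact planted group sizes or (when
covariate exposure effects are set) from a logistic model whose intercept
is calibrated by bisection so the expected exposed count equals the
target; the event from a logistic model with `logit(baseline) +
ln(true_or)·exposed + covariate effects`; onset days (default
exponential, mean 4.5 days, floored to whole days); outcome codes as
independent Bernoullis conditional on event status (the pipeline's
severity collapse then picks one); and the messiness knobs — a second,
earlier report version (10%), an exact duplicate row (2%), a truncated
event date (30%), the event term among the indications (0.15%), a
broad-scope-only event term on 5% of reports (exercising the broad SMQ
variant without touching the narrow ground truth). Defaults are chosen to
resemble a severe-disease spontaneous-report mix; the bundled
`paper_scale_scenario` fixes 3,991/8,878 cases with baseline 516/8,878 and
odds ratio (589·8,362)/(3,402·516), so its expected 2×2 matches the
remdesivir study's crude-table margins, and its partial-date rate (45%)
and pre-existing-event rate (19/12,888) match that study's attrition.

The generator emulates structure, not realism: there is no reporting-rate
dynamics, no stimulated reporting, no drug-name misspelling, no
correlation between covariates, and country/reporter distributions are
coarse. Passing tests therefore establish that the pipeline's *logic* is
correct on data with the declared statistical structure — they say nothing
about coding quality or duplicate patterns in the real database, and
absolute case counts of the real FAERS cannot be reproduced without the
full extract.

## Problem sizes and tolerances

The test suite runs the end-to-end recovery at 4,000/9,000 cases per
replicate over 200 seeded replicates (mean ROR within 5% of the planted
odds ratio 3), interval coverage on 2,000 simulated binomial tables
(93–97% band), matching oracles up to 8 exposed cases (exhaustive
bitmask search), Fisher enumeration up to margins of 30, and dedup
randomization over 1,000 small inputs. Floating comparisons use relative
tolerances of 1e-9 against enumeration oracles and two-decimal rounding
where published values are two-decimal.
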