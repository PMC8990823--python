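# faersvig

Pharmacovigilance signal detection on FAERS-format spontaneous reports.

The FDA Adverse Event Reporting System (FAERS) publishes post-marketing
adverse-event reports as quarterly `$`-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, RPSR, THER, INDI). `faersvig` implements the full workflow of a
drug–event disproportionality study on that format, with the remdesivir →
acute kidney injury (AKI) association in COVID-19 reports as its worked
case study:

- **Ingestion** of the seven tables into typed records, with loss-free
  round-tripping and parse accounting (`faersvig.faers_io`);
- **Deduplication** of report versions to one row per case: identical rows
  collapse, then the latest `FDA_DT` wins per `CASEID`, then the highest
  `PRIMARYID` (`faersvig.dedup`);
- **Case/event identification** by Standardised MedDRA Query (SMQ)
  preferred-term lists, narrow or broad scope, with multiple matching terms
  per case counted once (`faersvig.smq`);
- **Cohort construction**: indication-defined disease cohort, exclusion of
  cases whose indications already contain the event, split into
  study-drug-as-primary-suspect vs other-primary-suspect groups, covariates
  with explicit `Unknown` levels, most-serious-outcome collapsing, plus
  three sensitivity variants (`faersvig.cohort`);
- **Statistics**: the reporting odds ratio (ROR) with its Woolf 95% CI,
  uncorrected Pearson chi-square, Fisher's exact test and the
  expected-count rule for switching between them (`faersvig.stats`);
- **Propensity-score matching**: main-effects logistic model on the
  categorical demographics, exact-then-fuzzy optimal 1:1 matching under a
  caliper (default 0.001), balance diagnostics (`faersvig.psm`);
- **Time-to-onset and outcomes**: `EVENT_DT − START_DT` in calendar days
  with the date-quality exclusions, cumulative-onset curves, per-outcome
  event vs non-event contrasts (`faersvig.tte`);
- **A synthetic FAERS generator** with known ground truth — planted odds
  ratio, demographic confounding, duplicate versions, partial dates,
  pre-existing events — so the whole pipeline is testable without any
  download (`faersvig.synthetic`).

## The core statistic

On the 2×2 table of deduplicated report counts — `a` drug-of-interest
reports with the event, `b` without, `c`/`d` the same for all comparator
drugs — the reporting odds ratio is

```
ROR = (a/b) / (c/d),   95% CI = exp( ln ROR ± z₀.₉₇₅ · √(1/a + 1/b + 1/c + 1/d) )
```

and a *signal* is declared when the CI's lower bound exceeds 1. The ROR
measures reporting disproportionality, not incidence. Group comparisons
use the uncorrected Pearson chi-square; tables with any expected count
below 5 use Fisher's exact test. Matching pairs each exposed case with the
control case of closest modelled exposure probability (within the caliper),
minimising the total score distance by exact assignment.

## Worked example

```bash
python examples/disproportionality.py
```

```
synthetic quarter:
  flow: 12869 cases found, 17 pre-existing excluded, 3988 exposed / 8864 control
  2x2 = (586, 3402, 491, 8373)   planted = (586, 3402, 491, 8373)
  ROR 2.94  95% CI (2.59, 3.33)  chi2 300.25  signal=True

published remdesivir-AKI counts (589, 3402, 516, 8362):
  ROR 2.81  95% CI (2.48, 3.18)  chi2 280.73
```

The first block generates a study-scale synthetic quarter (12,869 COVID-19
cases, duplicates and partial dates included), runs
dedup → SMQ → cohort → contingency, and recovers the generator's planted
2×2 table exactly; the ROR of 2.94 means AKI appears in the synthetic
study-drug reports at 2.94 times the reporting odds of the comparator
reports, and the CI excluding 1 makes it a signal. The second block applies
the same machinery to the published report counts of the remdesivir–AKI
study and reproduces its headline statistics.

Other examples: `simulate_quarter.py` (what the generator plants),
`propensity_matching.py` (confounded scenario; matching shrinks the worst
standardized difference from 0.31 to 0.006 and pulls the crude ROR 2.03
down to 1.81), `time_to_onset.py` (onset means and within-3/5-day
fractions), `sensitivity_analyses.py` (broad SMQ, PS+SS roles, named
five-drug control). A thin CLI mirrors the stages:
`faersvig simulate | dedup | identify | cohort | signal | psm | tte`.

Note: MedDRA is licensed, so the bundled SMQ term lists
(`src/faersvig/data/smq/*.synthetic.csv`) are size-matched synthetic
placeholders; every function accepts real term lists via
`load_smq_csv`.

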