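"""End-to-end glue: raw quarter -> dedup -> cohort -> disproportionality.

One call runs the whole signal-detection flow on a FAERS table bundle and
returns every intermediate product, so scripts and tests never re-wire the
stages by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import PLANS, FlowCounts, SensitivityPlan, build_cohort, cohort_2x2
from .dedup import DedupReport, deduplicate
from .faers_io import FaersTables
from .smq import SmqQuery, bundled_query
from .stats import ContingencyResult, ror_2x2

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dedup_report: DedupReport
    flow: FlowCounts
    cohort: pd.DataFrame
    contingency: ContingencyResult

    @property
    def ror(self) -> float:
        return self.contingency.ror


def run_pipeline(
    tables: FaersTables,
    covid_query: SmqQuery | None = None,
    aki_query: SmqQuery | None = None,
    plan: SensitivityPlan | str = "main",
) -> PipelineResult:
    """Deduplicate, build the cohort, compute the crude ROR.

    ``covid_query``/``aki_query`` default to the bundled synthetic SMQ
    lists; the event query's scope follows the plan when defaulted.
    """
    if isinstance(plan, str):
        plan = PLANS[plan]
    if covid_query is None:
        covid_query = bundled_query("COVID-19", "narrow")
    if aki_query is None:
        aki_query = bundled_query("Acute kidney injury", plan.event_scope)

    survivors, report = deduplicate(tables.demo)
    keep = {r.primaryid for r in survivors}
    deduped = tables.filter_primaryids(keep)
    deduped.demo = survivors

    cohort, flow = build_cohort(deduped, covid_query, aki_query, plan)
    contingency = ror_2x2(*cohort_2x2(cohort))
    return PipelineResult(
        dedup_report=report, flow=flow, cohort=cohort, contingency=contingency
    )
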