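"""Analysis-cohort construction: exposure groups, event flags, covariates.

Starting from a deduplicated FAERS extract, the cohort stage mirrors the
usual case-identification flow of a drug-event pharmacovigilance study:

1. find cases whose drug *indication* matches the condition of interest
   (here COVID-19, narrow SMQ);
2. exclude cases where the adverse event of interest already appears among
   the indications (the condition pre-dates the drug);
3. split the remainder into the exposed group — the study drug
   (remdesivir/VEKLURY) reported as primary suspect — and the control
   group — any other drug as primary suspect;
4. flag the event (acute kidney injury SMQ on the reactions), attach
   demographics, and collapse multiple serious-outcome codes per case to
   the most serious one.

Three sensitivity variants are supported: broad instead of narrow event
SMQ, primary+secondary suspect roles, and a named five-drug control group.
Missing demographics are kept as an explicit ``Unknown`` level throughout —
they are analysed as their own category, never imputed or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .faers_io import DrugRecord, FaersTables, normalize_age
from .smq import SmqQuery, exclude_preexisting, match_cases

__all__ = [
    "REMDESIVIR_NAMES",
    "NAMED_CONTROL_DRUGS",
    "SensitivityPlan",
    "PLANS",
    "FlowCounts",
    "OUTCOME_SEVERITY",
    "assign_exposure",
    "collapse_outcome",
    "age_band",
    "reporter_category",
    "build_cohort",
    "cohort_2x2",
]

# study-drug identifiers, matched case-insensitively as substrings of
# drugname and prod_ai (free-text names carry dose/salt suffixes)
REMDESIVIR_NAMES = frozenset({"remdesivir", "veklury"})

# the five most-reported alternative primary suspects used as a restricted
# control group in the sensitivity analysis ("lopinavir" covers the
# lopinavir\ritonavir combination under either separator)
NAMED_CONTROL_DRUGS = frozenset(
    {"hydroxychloroquine", "azithromycin", "bamlanivimab", "tocilizumab", "lopinavir"}
)

# most serious first; a case reporting several codes keeps the first hit
OUTCOME_SEVERITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

_HEALTH_PROFESSIONAL = {"MD", "PH", "OT", "HP", "RN"}
_NON_HEALTH_PROFESSIONAL = {"CN", "LW"}

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "Unknown")


@dataclass(frozen=True)
class SensitivityPlan:
    """One analysis variant: event scope, suspect roles, control definition."""

    name: str = "main"
    event_scope: str = "narrow"  # "narrow" | "broad"
    suspect_roles: frozenset = frozenset({"PS"})
    control_mode: str = "all-other-drugs"  # | "named-drug-list"


PLANS = {
    "main": SensitivityPlan("main"),
    "broad-event": SensitivityPlan("broad-event", event_scope="broad"),
    "ps-ss": SensitivityPlan("ps-ss", suspect_roles=frozenset({"PS", "SS"})),
    "named-controls": SensitivityPlan("named-controls", control_mode="named-drug-list"),
}


@dataclass
class FlowCounts:
    """Case counts at each stage of the identification flow."""

    covid_cases: int = 0
    preexisting_excluded: int = 0
    included: int = 0
    no_suspect_drug_dropped: int = 0
    n_exposed: int = 0
    n_control: int = 0
    aki_exposed: int = 0
    aki_control: int = 0


class EmptyCohortError(RuntimeError):
    """The flow emptied at some stage; the message names the stage."""


def _name_match(row: DrugRecord, names: frozenset) -> bool:
    dn = row.drugname.casefold()
    ai = row.prod_ai.casefold()
    return any(n in dn or n in ai for n in names)


def assign_exposure(drug_records, names: frozenset, roles: frozenset) -> set[str]:
    """Primaryids with a drug row in ``roles`` naming one of ``names``.

    Matching is case-insensitive substring containment on both the verbatim
    ``drugname`` and the ``prod_ai`` active-ingredient field.
    """
    return {
        r.primaryid
        for r in drug_records
        if r.role_cod in roles and _name_match(r, names)
    }


def collapse_outcome(outc_codes) -> str | None:
    """Most serious outcome code of a case, or None when none reported.

    Severity order: death > life-threatening > hospitalization >
    disability > congenital anomaly > required intervention > other.
    """
    codes = {c.strip().upper() for c in outc_codes}
    for code in OUTCOME_SEVERITY:
        if code in codes:
            return code
    return None


def age_band(age_years: float | None) -> str:
    """Band an age in years; boundaries are closed on the left."""
    if age_years is None or not age_years == age_years:  # None or NaN
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


def reporter_category(occp_cod: str) -> str:
    code = (occp_cod or "").strip().upper()
    if code in _HEALTH_PROFESSIONAL:
        return "health professional"
    if code in _NON_HEALTH_PROFESSIONAL:
        return "non-health professional"
    return "Unknown"


def build_cohort(
    tables: FaersTables,
    covid_query: SmqQuery,
    aki_query: SmqQuery,
    plan: SensitivityPlan = PLANS["main"],
) -> tuple[pd.DataFrame, FlowCounts]:
    """Build the case-level analysis table from deduplicated tables.

    Parameters
    ----------
    tables
        A :class:`FaersTables` bundle whose DEMO rows are already one per
        case and whose child tables are filtered to the surviving
        primaryids (see :func:`faersvig.pipeline.run_pipeline` for the
        glued version).
    covid_query
        Indication SMQ defining the disease cohort (narrow scope).
    aki_query
        Event SMQ; its scope should agree with ``plan.event_scope``.
    plan
        Sensitivity variant; defaults to the main analysis (narrow event,
        PS-only exposure, all-other-drugs control).

    Returns
    -------
    (cohort, flow)
        ``cohort`` has one row per analysed case with columns ``caseid,
        primaryid, exposure, event, age_band, sex, reporter, country,
        outcome, event_dt, start_dt``.  ``flow`` reports the counts at
        each identification stage.

    Raises
    ------
    EmptyCohortError
        If any stage leaves zero cases; the message names the stage.
    """
    flow = FlowCounts()

    covid_ids = match_cases(tables.indi, covid_query)
    flow.covid_cases = len(covid_ids)
    if not covid_ids:
        raise EmptyCohortError("no cases matched the indication SMQ")

    included = exclude_preexisting(covid_ids, tables.indi, aki_query)
    flow.preexisting_excluded = flow.covid_cases - len(included)
    flow.included = len(included)
    if not included:
        raise EmptyCohortError("all cases excluded as pre-existing events")

    exposed_any = assign_exposure(tables.drug, REMDESIVIR_NAMES, plan.suspect_roles)
    exposed = included & exposed_any

    # control: remaining cases whose own primary suspect is some other drug
    ps_rows: dict[str, list[DrugRecord]] = {}
    for r in tables.drug:
        if r.role_cod == "PS":
            ps_rows.setdefault(r.primaryid, []).append(r)
    candidates = included - exposed
    if plan.control_mode == "named-drug-list":
        control = {
            pid
            for pid in candidates
            if any(_name_match(r, NAMED_CONTROL_DRUGS) for r in ps_rows.get(pid, ()))
        }
    else:
        control = {pid for pid in candidates if pid in ps_rows}
    flow.no_suspect_drug_dropped = len(candidates) - len(control)

    flow.n_exposed, flow.n_control = len(exposed), len(control)
    if not exposed or not control:
        raise EmptyCohortError(
            f"exposure split emptied a group (exposed={len(exposed)}, control={len(control)})"
        )

    events = match_cases(tables.reac, aki_query)

    outc_by_pid: dict[str, list[str]] = {}
    for r in tables.outc:
        outc_by_pid.setdefault(r.primaryid, []).append(r.outc_cod)

    # suspect drug_seqs per case, for locating the therapy start date
    suspect_seqs: dict[str, set[str]] = {}
    for r in tables.drug:
        if r.primaryid in exposed:
            if r.role_cod in plan.suspect_roles and _name_match(r, REMDESIVIR_NAMES):
                suspect_seqs.setdefault(r.primaryid, set()).add(r.drug_seq)
        elif r.primaryid in control and r.role_cod == "PS":
            suspect_seqs.setdefault(r.primaryid, set()).add(r.drug_seq)

    start_by_pid: dict[str, str] = {}
    for r in tables.ther:
        if r.dsg_drug_seq in suspect_seqs.get(r.primaryid, ()):
            dt = r.start_dt.strip()
            if len(dt) == 8 and dt.isdigit():
                prev = start_by_pid.get(r.primaryid)
                if prev is None or dt < prev:  # earliest valid full date
                    start_by_pid[r.primaryid] = dt

    demo_by_pid = {r.primaryid: r for r in tables.demo}
    rows = []
    for pid in sorted(exposed | control):
        demo = demo_by_pid.get(pid)
        if demo is None:
            continue
        rows.append(
            {
                "caseid": demo.caseid,
                "primaryid": pid,
                "exposure": "remdesivir" if pid in exposed else "control",
                "event": pid in events,
                "age_band": age_band(normalize_age(demo.age, demo.age_cod)),
                "sex": demo.sex if demo.sex in ("F", "M") else "Unknown",
                "reporter": reporter_category(demo.occp_cod),
                "country": demo.occr_country.strip() or "Unknown",
                "outcome": collapse_outcome(outc_by_pid.get(pid, ())) or "none",
                "event_dt": demo.event_dt,
                "start_dt": start_by_pid.get(pid, ""),
            }
        )
    cohort = pd.DataFrame(rows)

    flow.aki_exposed = int(((cohort.exposure == "remdesivir") & cohort.event).sum())
    flow.aki_control = int(((cohort.exposure == "control") & cohort.event).sum())
    return cohort, flow


def cohort_2x2(cohort: pd.DataFrame) -> tuple[int, int, int, int]:
    """(a, b, c, d) counts: exposed/control x event/no-event."""
    exp = cohort.exposure == "remdesivir"
    ev = cohort.event.astype(bool)
    return (
        int((exp & ev).sum()),
        int((exp & ~ev).sum()),
        int((~exp & ev).sum()),
        int((~exp & ~ev).sum()),
    )
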