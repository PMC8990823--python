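"""Case deduplication for spontaneous reports.

A FAERS case accumulates report versions over time; analyses must keep one
row per case.  The FDA-recommended reduction, applied to the DEMO table:

1. collapse byte-identical DEMO rows to one;
2. within a ``caseid``, keep only the versions with the latest ``fda_dt``
   (the date FDA received the version);
3. if several versions share that latest date, keep the highest
   ``primaryid``.

After step 3 exactly one row per case survives.  Child tables (DRUG, REAC,
OUTC, THER, INDI, RPSR) are not deduplicated themselves; they are filtered
to the surviving ``primaryid`` set afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .faers_io import DemoRecord

__all__ = ["DedupReport", "deduplicate"]


@dataclass
class DedupReport:
    """Accounting of one deduplication pass.

    Invariant: ``output_count == input_count - exact_duplicates_removed -
    versions_collapsed``.
    """

    input_count: int = 0
    exact_duplicates_removed: int = 0
    versions_collapsed: int = 0
    output_count: int = 0
    ungroupable: list = field(default_factory=list)  # primaryids with empty caseid


def _row_key(r: DemoRecord) -> tuple:
    """Full row content; two records with equal keys are the same DEMO row."""
    return (
        r.primaryid,
        r.caseid,
        r.fda_dt,
        r.event_dt,
        r.age,
        r.age_cod,
        r.sex,
        r.occp_cod,
        r.occr_country,
        tuple(sorted(r.extras.items())),
    )


def _fda_dt_key(fda_dt: str) -> str:
    # partial yyyymmdd strings sort as their earliest completion
    return (fda_dt or "").ljust(8, "0")


def _primaryid_key(primaryid: str) -> tuple:
    # numeric when possible ("lower primaryid" is numeric order), else text
    s = primaryid or ""
    try:
        return (1, int(s), "")
    except ValueError:
        return (0, 0, s)


def deduplicate(demo_records: list[DemoRecord]) -> tuple[list[DemoRecord], DedupReport]:
    """Reduce DEMO report versions to one record per case.

    Returns the surviving records (input order preserved) and a
    :class:`DedupReport`.  Records with an empty ``caseid`` cannot be
    grouped; they pass through unchanged and are flagged in the report.
    """
    report = DedupReport(input_count=len(demo_records))

    # step 1: identical rows collapse to their first occurrence
    seen: set = set()
    unique: list[DemoRecord] = []
    for r in demo_records:
        k = _row_key(r)
        if k in seen:
            report.exact_duplicates_removed += 1
            continue
        seen.add(k)
        unique.append(r)

    # steps 2-3: per case keep (max fda_dt, then max primaryid)
    best: dict[str, DemoRecord] = {}
    order: dict[str, int] = {}
    survivors: list[DemoRecord] = []
    for i, r in enumerate(unique):
        if not r.caseid:
            report.ungroupable.append(r.primaryid)
            survivors.append(r)  # placeholder, keeps input order
            continue
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            order[r.caseid] = len(survivors)
            survivors.append(r)
        else:
            report.versions_collapsed += 1
            new_key = (_fda_dt_key(r.fda_dt), _primaryid_key(r.primaryid))
            cur_key = (_fda_dt_key(cur.fda_dt), _primaryid_key(cur.primaryid))
            if new_key > cur_key:
                best[r.caseid] = r
                survivors[order[r.caseid]] = r

    report.output_count = len(survivors)
    return survivors, report
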