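"""Case and event identification via Standardised MedDRA Queries (SMQs).

An SMQ is a curated set of MedDRA preferred terms (PTs) used to retrieve
all reports of a medical condition.  The *narrow* scope contains highly
specific terms; the *broad* scope adds sensitive ones, so narrow ⊆ broad.
COVID-19 cases are found by matching a case's drug indications (INDI
table); adverse events such as acute kidney injury by matching its
reactions (REAC table).  A case reporting several matching PTs counts
once.

MedDRA itself is licensed and cannot be redistributed, so the package
bundles *synthetic placeholder* term lists (see ``data/smq/*.synthetic.csv``)
with the cardinalities of the real SMQ v23.1 queries used in remdesivir
pharmacovigilance work (COVID-19 narrow: 18 PTs; acute kidney injury
narrow: 19 PTs, broad: 52 PTs).  All pipeline behaviour is parameterized
on the lists: users with a MedDRA licence drop in the real CSVs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "SmqQuery",
    "load_smq_csv",
    "load_smq_text",
    "bundled_query",
    "match_cases",
    "exclude_preexisting",
]


def normalize_term(pt: str) -> str:
    """PT comparison key: trimmed, case-folded exact text (no substrings)."""
    return pt.strip().casefold()


@dataclass(frozen=True)
class SmqQuery:
    """A named PT set with a scope.

    ``terms`` are matched case-insensitively after whitespace trimming,
    always as whole terms — MedDRA PTs are a controlled vocabulary.
    """

    name: str
    scope: str  # "narrow" | "broad"
    terms: frozenset[str]

    def __post_init__(self):
        if self.scope not in ("narrow", "broad"):
            raise ValueError(f"scope must be narrow or broad, got {self.scope!r}")
        if not self.terms:
            raise ValueError(f"SMQ {self.name!r}: empty term set")
        object.__setattr__(self, "terms", frozenset(normalize_term(t) for t in self.terms))

    def matches(self, pt: str) -> bool:
        return normalize_term(pt) in self.terms


def load_smq_csv(path, name: str | None = None, scope: str = "narrow") -> SmqQuery:
    """Build a query from a (smq_name, scope, pt) CSV.

    ``scope="narrow"`` keeps only narrow-scope rows; ``scope="broad"``
    keeps narrow and broad rows, so the broad query always contains the
    narrow one.  ``name`` filters when one file holds several SMQs.
    """
    terms: list[str] = []
    smq_name = name
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
            if name is not None and normalize_term(row["smq_name"]) != normalize_term(name):
                continue
            smq_name = smq_name or row["smq_name"]
            if scope == "narrow" and row["scope"] != "narrow":
                continue
            terms.append(row["pt"])
    return SmqQuery(smq_name or "?", scope, frozenset(terms))


def load_smq_text(path, name: str, scope: str = "narrow") -> SmqQuery:
    """Build a query from a one-PT-per-line text file (all terms in scope)."""
    with open(path, encoding="utf-8") as fh:
        terms = [line.strip() for line in fh if line.strip()]
    return SmqQuery(name, scope, frozenset(terms))


_BUNDLED = {"covid-19": "covid19.synthetic.csv", "acute kidney injury": "aki.synthetic.csv"}


def bundled_query(name: str, scope: str = "narrow") -> SmqQuery:
    """One of the bundled synthetic placeholder SMQs.

    ``name`` is ``"COVID-19"`` or ``"Acute kidney injury"``; these are
    stand-ins of the correct size, not the licensed MedDRA term lists.
    """
    try:
        fname = _BUNDLED[name.strip().casefold()]
    except KeyError:
        raise KeyError(f"no bundled SMQ named {name!r}; have {list(_BUNDLED)}") from None
    ref = resources.files("faersvig.data.smq").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_smq_csv(path, name=None, scope=scope)


def bundled_terms(name: str, scope: str = "narrow") -> list[str]:
    """Display-form PT list of a bundled SMQ (original capitalisation).

    Useful for generators that must emit PT strings a query will match.
    """
    try:
        fname = _BUNDLED[name.strip().casefold()]
    except KeyError:
        raise KeyError(f"no bundled SMQ named {name!r}; have {list(_BUNDLED)}") from None
    ref = resources.files("faersvig.data.smq").joinpath(fname)
    terms: list[str] = []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if scope == "narrow" and row["scope"].strip() != "narrow":
                continue
            terms.append(row["pt"].strip())
    return terms


def _term_of(record) -> str:
    # REAC rows carry .pt, INDI rows .indi_pt
    return getattr(record, "pt", None) or getattr(record, "indi_pt", "")


def match_cases(records, query: SmqQuery) -> set[str]:
    """Primaryids of reports with at least one PT in the query.

    Multiple matching PTs in one report count once (the set semantics
    collapse them), and the result is invariant to record order.
    """
    if not query.terms:
        raise ValueError("query has no terms")
    return {r.primaryid for r in records if query.matches(_term_of(r))}


def exclude_preexisting(case_ids: set[str], indi_records, event_query: SmqQuery) -> set[str]:
    """Drop cases whose *indications* already contain the event.

    An event PT among a case's drug indications means the condition was
    present before treatment, so the case cannot inform an onset signal.
    """
    preexisting = match_cases(indi_records, event_query)
    return set(case_ids) - preexisting
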