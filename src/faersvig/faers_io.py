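"""Reading and writing FAERS Quarterly Data Extract ASCII tables.

The FDA Adverse Event Reporting System (FAERS) distributes spontaneous
adverse-event reports as seven ``$``-delimited text tables per quarter:

========  =====================================================
DEMO      one row per report *version* (demographics, dates)
DRUG      drugs per report, with role codes (PS/SS/C/I)
REAC      MedDRA preferred terms of the reported reactions
OUTC      serious-outcome codes (DE/LT/HO/DS/CA/RI/OT)
RPSR      report sources
THER      therapy date ranges per drug
INDI      MedDRA preferred terms of the drug indications
========  =====================================================

Files have a single header line; there is no quoting or escaping in the
dialect, so a plain split on ``$`` is exact.  Column names are matched
case-insensitively and unknown columns are preserved verbatim in each
record's ``extras`` mapping, so quarters with column supersets round-trip
without loss.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

__all__ = [
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "OutcRecord",
    "RpsrRecord",
    "TherRecord",
    "IndiRecord",
    "ParsedTable",
    "FaersTables",
    "read_table",
    "write_table",
    "load_quarter",
    "normalize_age",
    "TABLE_KINDS",
]

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclass
class DemoRecord:
    """One report version from the DEMO table.

    ``primaryid`` identifies a report version, ``caseid`` the underlying
    case; a case may carry several versions until deduplication.  Dates are
    kept as raw yyyymmdd strings (possibly partial or empty): validity is
    resolved only by the stage that needs it.
    """

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str = ""
    age: str = ""
    age_cod: str = ""
    sex: str = ""
    occp_cod: str = ""
    occr_country: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: str
    role_cod: str = ""
    drugname: str = ""
    prod_ai: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class ReacRecord:
    primaryid: str
    pt: str
    extras: dict = field(default_factory=dict)


@dataclass
class OutcRecord:
    primaryid: str
    outc_cod: str
    extras: dict = field(default_factory=dict)


@dataclass
class RpsrRecord:
    primaryid: str
    rpsr_cod: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class TherRecord:
    primaryid: str
    dsg_drug_seq: str
    start_dt: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class IndiRecord:
    primaryid: str
    indi_drug_seq: str = ""
    indi_pt: str = ""
    extras: dict = field(default_factory=dict)


Record = Union[
    DemoRecord, DrugRecord, ReacRecord, OutcRecord, RpsrRecord, TherRecord, IndiRecord
]

# canonical field -> (record class attribute, accepted header aliases)
_SCHEMAS: dict[str, tuple[type, dict[str, tuple[str, ...]]]] = {
    "DEMO": (
        DemoRecord,
        {
            "primaryid": ("primaryid", "isr"),
            "caseid": ("caseid", "case"),
            "fda_dt": ("fda_dt",),
            "event_dt": ("event_dt",),
            "age": ("age",),
            "age_cod": ("age_cod",),
            "sex": ("sex", "gndr_cod"),
            "occp_cod": ("occp_cod",),
            "occr_country": ("occr_country",),
        },
    ),
    "DRUG": (
        DrugRecord,
        {
            "primaryid": ("primaryid", "isr"),
            "drug_seq": ("drug_seq",),
            "role_cod": ("role_cod",),
            "drugname": ("drugname",),
            "prod_ai": ("prod_ai",),
        },
    ),
    "REAC": (ReacRecord, {"primaryid": ("primaryid", "isr"), "pt": ("pt",)}),
    "OUTC": (
        OutcRecord,
        {"primaryid": ("primaryid", "isr"), "outc_cod": ("outc_cod", "outc_code")},
    ),
    "RPSR": (
        RpsrRecord,
        {"primaryid": ("primaryid", "isr"), "rpsr_cod": ("rpsr_cod",)},
    ),
    "THER": (
        TherRecord,
        {
            "primaryid": ("primaryid", "isr"),
            "dsg_drug_seq": ("dsg_drug_seq", "drug_seq"),
            "start_dt": ("start_dt",),
        },
    ),
    "INDI": (
        IndiRecord,
        {
            "primaryid": ("primaryid", "isr"),
            "indi_drug_seq": ("indi_drug_seq", "drug_seq"),
            "indi_pt": ("indi_pt",),
        },
    ),
}

# columns whose absence is a hard error rather than an empty default
_MANDATORY: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drug_seq"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "RPSR": ("primaryid",),
    "THER": ("primaryid", "dsg_drug_seq"),
    "INDI": ("primaryid",),
}


class MissingColumnError(ValueError):
    """A mandatory FAERS column is absent from the header."""


@dataclass
class ParsedTable(Sequence):
    """Records parsed from one table plus a parse accounting.

    Satisfies ``len(records) + skipped == data lines`` — a well-formed line
    is never silently dropped.
    """

    table_kind: str
    records: list
    skipped: int = 0
    bad_lines: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator:
        return iter(self.records)


def _check_kind(table_kind: str) -> str:
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    return kind


def read_table(path: str | os.PathLike, table_kind: str) -> ParsedTable:
    """Parse one FAERS ASCII table into typed records.

    Parameters
    ----------
    path
        File with a ``$``-delimited header line followed by data lines.
    table_kind
        One of ``DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI``.

    Returns
    -------
    ParsedTable
        One record per well-formed data line; lines with a field count
        different from the header are skipped and counted.  Unknown columns
        land in ``record.extras``.

    Raises
    ------
    MissingColumnError
        If a mandatory column for the table kind is missing.
    """
    kind = _check_kind(table_kind)
    cls, aliases = _SCHEMAS[kind]

    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        header = [h.strip().lower() for h in header_line.split(DELIMITER)]

        col_for_field: dict[str, int] = {}
        for fieldname, names in aliases.items():
            for alias in names:
                if alias in header:
                    col_for_field[fieldname] = header.index(alias)
                    break
        for mandatory in _MANDATORY[kind]:
            if mandatory not in col_for_field:
                raise MissingColumnError(
                    f"{kind} table at {path} is missing mandatory column {mandatory!r}"
                )
        known_cols = set(col_for_field.values())
        extra_cols = [(i, header[i]) for i in range(len(header)) if i not in known_cols]

        records: list = []
        skipped = 0
        bad_lines: list[int] = []
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split(DELIMITER)
            if len(parts) != n_fields:
                skipped += 1
                bad_lines.append(lineno)
                continue
            kwargs = {f: parts[i].strip() for f, i in col_for_field.items()}
            extras = {name: parts[i].strip() for i, name in extra_cols}
            records.append(cls(**kwargs, extras=extras))

    return ParsedTable(kind, records, skipped, bad_lines)


def write_table(records: Sequence[Record], path: str | os.PathLike, table_kind: str) -> None:
    """Write typed records back to the FAERS ASCII dialect.

    The header contains the canonical columns for the table kind followed by
    the union of ``extras`` keys (sorted); ``read_table`` on the output
    reproduces the records exactly.
    """
    kind = _check_kind(table_kind)
    _, aliases = _SCHEMAS[kind]
    fields = list(aliases)
    extra_keys = sorted({k for r in records for k in r.extras})

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(DELIMITER.join(fields + extra_keys) + "\n")
        for r in records:
            vals = [getattr(r, f) for f in fields]
            vals += [r.extras.get(k, "") for k in extra_keys]
            fh.write(DELIMITER.join(vals) + "\n")


@dataclass
class FaersTables:
    """The seven tables of one quarter (or of a merged extract)."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    rpsr: list[RpsrRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    indi: list[IndiRecord] = field(default_factory=list)

    def write(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        for kind in TABLE_KINDS:
            write_table(
                getattr(self, kind.lower()),
                os.path.join(directory, f"{kind}.txt"),
                kind,
            )

    def filter_primaryids(self, keep: set) -> "FaersTables":
        """Restrict every table to the given report versions (post-dedup)."""
        out = FaersTables()
        for kind in TABLE_KINDS:
            name = kind.lower()
            setattr(out, name, [r for r in getattr(self, name) if r.primaryid in keep])
        return out


def load_quarter(directory: str | os.PathLike) -> FaersTables:
    """Read ``DEMO.txt`` … ``INDI.txt`` from a directory into a bundle.

    Missing files yield empty tables (real quarters always ship all seven,
    but partial fixtures are convenient).
    """
    tables = FaersTables()
    for kind in TABLE_KINDS:
        path = os.path.join(directory, f"{kind}.txt")
        if os.path.exists(path):
            setattr(tables, kind.lower(), list(read_table(path, kind)))
    return tables


# FAERS age unit codes -> factor converting to years
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (24.0 * 365.25),
}


def normalize_age(age: str | float, age_cod: str) -> float | None:
    """Convert a FAERS (age, age_cod) pair to years.

    Recognized unit codes: DEC decades, YR years, MON months, WK weeks,
    DY days, HR hours.  An empty or unrecognized code, or a non-numeric
    age, yields ``None`` (unknown).
    """
    code = (age_cod or "").strip().upper()
    if code not in _AGE_FACTORS:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    return value * _AGE_FACTORS[code]
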