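import pytest

from faersvig.cohort import (
    PLANS,
    REMDESIVIR_NAMES,
    age_band,
    assign_exposure,
    build_cohort,
    cohort_2x2,
    collapse_outcome,
)
from faersvig.faers_io import (
    DemoRecord,
    DrugRecord,
    FaersTables,
    IndiRecord,
    ReacRecord,
)
from faersvig.pipeline import run_pipeline
from faersvig.smq import bundled_query

PS_ONLY = frozenset({"PS"})


def drug(pid, name, role="PS", ai="", seq="1"):
    return DrugRecord(primaryid=pid, drug_seq=seq, role_cod=role, drugname=name, prod_ai=ai)


class TestAssignExposure:
    @pytest.mark.parametrize(
        "name,ai,role,expected",
        [
            ("VEKLURY", "", "PS", True),
            ("REMDESIVIR 100MG", "", "PS", True),  # substring containment
            ("", "REMDESIVIR", "PS", True),  # active-ingredient column
            ("remdesivir", "", "C", False),  # concomitant not suspect
            ("HYDROXYCHLOROQUINE", "", "PS", False),
        ],
    )
    def test_name_and_role_rules(self, name, ai, role, expected):
        got = assign_exposure([drug("1", name, role, ai)], REMDESIVIR_NAMES, PS_ONLY)
        assert (got == {"1"}) is expected

    def test_secondary_suspect_under_ps_ss(self):
        rows = [drug("1", "VEKLURY", "SS")]
        assert assign_exposure(rows, REMDESIVIR_NAMES, PS_ONLY) == set()
        assert assign_exposure(rows, REMDESIVIR_NAMES, frozenset({"PS", "SS"})) == {"1"}


class TestCollapseOutcome:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (["DE", "HO"], "DE"),  # death beats hospitalization
            (["OT"], "OT"),
            (["LT", "HO", "OT"], "LT"),
            (["RI", "CA", "DS"], "DS"),
            ([], None),
        ],
    )
    def test_most_serious_kept(self, codes, expected):
        assert collapse_outcome(codes) == expected


class TestAgeBand:
    @pytest.mark.parametrize(
        "age,band",
        [
            (17.9, "<18"),
            (18.0, "18-44"),  # closed on the left
            (44.9, "18-44"),
            (45.0, "45-64"),
            (65.0, ">=65"),
            (None, "Unknown"),
            (float("nan"), "Unknown"),
        ],
    )
    def test_boundaries(self, age, band):
        assert age_band(age) == band


def tiny_tables():
    """Three COVID cases: remdesivir-PS, hydroxychloroquine-PS, and one
    case that is both remdesivir-PS and on the named control list."""
    t = FaersTables()
    for pid in "123":
        t.demo.append(DemoRecord(primaryid=pid, caseid=f"C{pid}", fda_dt="20200601"))
        t.indi.append(IndiRecord(pid, "1", "COVID-19"))
    t.drug += [
        drug("1", "VEKLURY"),
        drug("2", "HYDROXYCHLOROQUINE"),
        drug("3", "REMDESIVIR", seq="1"),
        drug("3", "TOCILIZUMAB", seq="2"),
    ]
    t.reac += [ReacRecord(pid, "Pyrexia") for pid in "123"]
    t.reac.append(ReacRecord("1", "Acute kidney injury"))
    return t


class TestBuildCohort:
    def test_exposed_case_never_in_named_control_group(self):
        cohort, _ = build_cohort(
            tiny_tables(),
            bundled_query("COVID-19"),
            bundled_query("Acute kidney injury"),
            PLANS["named-controls"],
        )
        by_case = cohort.set_index("caseid")["exposure"]
        assert by_case["C3"] == "remdesivir"  # remdesivir-PS wins over named list
        assert by_case["C2"] == "control"

    def test_groups_partition_included_cases(self, small_quarter):
        res = run_pipeline(small_quarter.tables)
        flow = res.flow
        assert len(res.cohort) == flow.n_exposed + flow.n_control
        assert flow.included == flow.covid_cases - flow.preexisting_excluded
        assert set(res.cohort["exposure"]) == {"remdesivir", "control"}
        assert res.cohort["caseid"].is_unique

    def test_clean_generator_recovers_planted_table(self, clean_quarter):
        res = run_pipeline(clean_quarter.tables)
        t = clean_quarter.truth
        assert cohort_2x2(res.cohort) == (t.a, t.b, t.c, t.d)
        assert (res.flow.n_exposed, res.flow.n_control) == (t.n_exposed, t.n_control)

    def test_messy_generator_recovers_ledger_table(self, small_quarter):
        # dedup + pre-existing exclusions handled, the ledger 2x2 remains exact
        res = run_pipeline(small_quarter.tables)
        t = small_quarter.truth
        assert cohort_2x2(res.cohort) == (t.a, t.b, t.c, t.d)
        assert res.flow.preexisting_excluded == t.n_preexisting

    def test_broad_event_counts_never_decrease(self, small_quarter):
        narrow = run_pipeline(small_quarter.tables, plan="main")
        broad = run_pipeline(small_quarter.tables, plan="broad-event")
        assert broad.flow.aki_exposed >= narrow.flow.aki_exposed
        assert broad.flow.aki_control >= narrow.flow.aki_control

    def test_every_categorical_has_explicit_unknown_level(self, small_quarter):
        cohort = run_pipeline(small_quarter.tables).cohort
        for col in ("age_band", "sex", "reporter", "country"):
            assert "Unknown" in set(cohort[col])
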