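"""Synthetic FAERS quarter generator with known ground truth.

No public spontaneous-report corpus ships with this package, so every
pipeline stage is exercised on generated quarters that emulate the
statistical structure of a drug-event disproportionality study:

* a binary exposure (study drug vs other primary suspects) with
  configurable group sizes;
* a binary adverse event whose odds ratio given exposure is set exactly
  (``true_or`` acting on the control-arm baseline odds);
* categorical demographics (age band, sex, reporter type, country), each
  with an explicit Unknown level, optionally confounded: shared log-odds
  effects on both the exposure and the event logits;
* the messiness that drives the cleaning stages — duplicate case
  versions, byte-identical duplicate rows, partial dates, event terms
  already present among the indications;
* serious-outcome codes drawn conditionally on event status, and onset
  days from a configurable distribution.

Everything planted is recorded in a :class:`GroundTruth` ledger so tests
can compare pipeline output against the construction, and generation is
bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .faers_io import (
    DemoRecord,
    DrugRecord,
    FaersTables,
    IndiRecord,
    OutcRecord,
    ReacRecord,
    RpsrRecord,
    TherRecord,
)
from .smq import bundled_terms

__all__ = [
    "ConfounderSpec",
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticQuarter",
    "generate",
    "paper_scale_scenario",
    "confounded_scenario",
    "null_scenario",
    "scenario_from_yaml",
]

_EXPOSED_DRUGNAMES = ("REMDESIVIR", "VEKLURY", "REMDESIVIR 100MG")
_CONTROL_DRUGS = (
    ("HYDROXYCHLOROQUINE", "HYDROXYCHLOROQUINE SULFATE"),
    ("AZITHROMYCIN", "AZITHROMYCIN"),
    ("BAMLANIVIMAB", "BAMLANIVIMAB"),
    ("TOCILIZUMAB", "TOCILIZUMAB"),
    ("LOPINAVIR/RITONAVIR", "LOPINAVIR\\RITONAVIR"),
    ("DEXAMETHASONE", "DEXAMETHASONE"),
    ("ACETAMINOPHEN", "ACETAMINOPHEN"),
)
_GENERIC_PTS = ("Pyrexia", "Dyspnoea", "Cough", "Fatigue", "Headache", "Nausea")

_AGE_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 90)}
_REPORTER_CODES = {
    "health professional": ("MD", "PH", "OT"),
    "non-health professional": ("CN",),
    "Unknown": ("",),
}


@dataclass(frozen=True)
class ConfounderSpec:
    """One categorical covariate and its role in the data-generating model.

    ``probs`` are population level frequencies; ``exposure_logodds`` and
    ``event_logodds`` are per-level additive effects on the exposure and
    event logits (first entry is the reference, conventionally 0).
    """

    levels: tuple
    probs: tuple
    exposure_logodds: tuple = ()
    event_logodds: tuple = ()

    def __post_init__(self):
        k = len(self.levels)
        if len(self.probs) != k:
            raise ValueError("probs must align with levels")
        if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"level probabilities must sum to 1, got {sum(self.probs)}")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ValueError("level probabilities must lie in [0, 1]")
        for name in ("exposure_logodds", "event_logodds"):
            v = getattr(self, name)
            if v and len(v) != k:
                raise ValueError(f"{name} must align with levels")


# outcome probabilities conditional on event status, loosely shaped like a
# severe-disease spontaneous-report mix (death/other dominate; disability,
# congenital anomaly and required-intervention are rare)
_DEFAULT_OUTCOME_PROBS = {
    "event": {"DE": 0.34, "LT": 0.09, "HO": 0.20, "DS": 0.006, "CA": 0.001, "RI": 0.012, "OT": 0.32},
    "no_event": {"DE": 0.24, "LT": 0.06, "HO": 0.24, "DS": 0.004, "CA": 0.001, "RI": 0.005, "OT": 0.42},
}


def _default_confounders() -> dict[str, ConfounderSpec]:
    return {
        "age_band": ConfounderSpec(
            levels=("<18", "18-44", "45-64", ">=65", "Unknown"),
            probs=(0.017, 0.139, 0.310, 0.396, 0.138),
        ),
        "sex": ConfounderSpec(levels=("F", "M", "Unknown"), probs=(0.334, 0.559, 0.107)),
        "reporter": ConfounderSpec(
            levels=("health professional", "non-health professional", "Unknown"),
            probs=(0.880, 0.063, 0.057),
        ),
        "country": ConfounderSpec(
            levels=("US", "ES", "FR", "IT", "JP", "Unknown"),
            probs=(0.550, 0.109, 0.080, 0.076, 0.016, 0.169),
        ),
    }


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic quarter.

    ``true_or`` is the conditional odds ratio of event given exposure at
    reference covariate levels; ``baseline_event_prob`` is the control-arm
    event probability at reference levels (equal to the marginal
    control-arm probability when no ``event_logodds`` are set).  When any
    ``exposure_logodds`` are set, exposure is drawn case-by-case from the
    logistic model with the intercept calibrated so the *expected* exposed
    count is ``n_exposed``; otherwise arm sizes are exact.
    """

    n_exposed: int = 1000
    n_control: int = 2000
    true_or: float = 2.0
    baseline_event_prob: float = 0.06
    confounders: dict = field(default_factory=_default_confounders)
    dup_version_prob: float = 0.10
    exact_dup_prob: float = 0.02
    partial_date_prob: float = 0.30
    preexisting_event_prob: float = 0.0015
    outcome_probs: dict = field(default_factory=lambda: _DEFAULT_OUTCOME_PROBS)
    outcome_report_prob: float = 0.87
    multi_pt_prob: float = 0.30
    broad_only_pt_prob: float = 0.05
    onset_dist: tuple = ("exponential", {"scale": 4.5})
    seed: int = 0

    def __post_init__(self):
        if self.n_exposed <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 < self.baseline_event_prob < 1:
            raise ValueError("baseline_event_prob must lie strictly in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        p1 = _odds_transform(self.baseline_event_prob, self.true_or)
        if not 0 < p1 < 1:
            raise ValueError(
                f"exposed-arm event probability {p1} derived from true_or and "
                "baseline_event_prob is outside (0, 1)"
            )
        for probs in (
            [self.dup_version_prob, self.exact_dup_prob, self.partial_date_prob,
             self.preexisting_event_prob, self.outcome_report_prob, self.multi_pt_prob,
             self.broad_only_pt_prob]
            + [p for d in self.outcome_probs.values() for p in d.values()]
        ):
            if not 0 <= probs <= 1:
                raise ValueError(f"probability {probs} outside [0, 1]")


def _odds_transform(p0: float, odds_ratio: float) -> float:
    odds = odds_ratio * p0 / (1 - p0)
    return odds / (1 + odds)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GroundTruth:
    """Everything planted by the generator, for test bookkeeping.

    The 2x2 counts (a, b, c, d) refer to unique cases after removing the
    planted pre-existing-event cases — the table an ideal pipeline should
    recover exactly.
    """

    n_cases: int = 0
    n_preexisting: int = 0
    n_exposed: int = 0  # excluding pre-existing
    n_control: int = 0
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0
    n_dup_versions: int = 0
    n_exact_dups: int = 0
    onset_days: dict = field(default_factory=dict)  # caseid -> int, full-date event cases
    cases: pd.DataFrame | None = None  # one row per case: caseid, exposed, event, ...


@dataclass
class SyntheticQuarter:
    tables: FaersTables
    truth: GroundTruth
    config: ScenarioConfig

    def write(self, directory) -> None:
        self.tables.write(directory)


def generate(config: ScenarioConfig) -> SyntheticQuarter:
    """Generate one synthetic quarter from a scenario.

    Deterministic given ``config.seed``: identical configs produce
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_exposed + config.n_control
    conf = config.confounders

    # covariate level index per case, per covariate
    levels_ix = {
        name: rng.choice(len(spec.levels), size=n, p=np.asarray(spec.probs))
        for name, spec in conf.items()
    }

    # exposure: exact arm sizes unless exposure effects are in play
    exp_effects = {
        name: np.asarray(spec.exposure_logodds)[levels_ix[name]]
        for name, spec in conf.items()
        if spec.exposure_logodds and any(spec.exposure_logodds)
    }
    if exp_effects:
        eta = sum(exp_effects.values())
        lo, hi = -30.0, 30.0
        for _ in range(100):  # calibrate intercept: E[#exposed] == n_exposed
            mid = (lo + hi) / 2
            if _sigmoid(eta + mid).sum() > config.n_exposed:
                hi = mid
            else:
                lo = mid
        exposed = rng.random(n) < _sigmoid(eta + (lo + hi) / 2)
    else:
        exposed = np.zeros(n, dtype=bool)
        exposed[rng.permutation(n)[: config.n_exposed]] = True

    # event: logistic in exposure and covariate effects
    ev_eta = np.full(n, _logit(config.baseline_event_prob))
    ev_eta += math.log(config.true_or) * exposed
    for name, spec in conf.items():
        if spec.event_logodds and any(spec.event_logodds):
            ev_eta += np.asarray(spec.event_logodds)[levels_ix[name]]
    event = rng.random(n) < _sigmoid(ev_eta)

    preexisting = rng.random(n) < config.preexisting_event_prob
    dup_version = rng.random(n) < config.dup_version_prob
    exact_dup = rng.random(n) < config.exact_dup_prob
    partial_ev_dt = rng.random(n) < config.partial_date_prob
    multi_pt = rng.random(n) < config.multi_pt_prob
    # a broad-scope-only event term on some reports: never changes the
    # narrow-scope ground truth, but makes broad > narrow case finding
    broad_only = rng.random(n) < config.broad_only_pt_prob
    has_outcome = rng.random(n) < config.outcome_report_prob

    dist, params = config.onset_dist
    if dist == "exponential":
        onset = np.floor(rng.exponential(params["scale"], size=n)).astype(int)
    elif dist == "lognormal":
        onset = np.floor(rng.lognormal(params["mean"], params["sigma"], size=n)).astype(int)
    elif dist == "uniform":
        onset = rng.integers(params["low"], params["high"] + 1, size=n)
    else:
        raise ValueError(f"unknown onset distribution {dist!r}")

    start_base = pd.DatetimeIndex(
        pd.Timestamp("2020-05-01") + pd.to_timedelta(rng.integers(0, 120, size=n), unit="D")
    )
    fda_base = start_base + pd.to_timedelta(rng.integers(10, 60, size=n), unit="D")
    # vectorised date strings (per-row strftime dominates generation time)
    start_strs = start_base.strftime("%Y%m%d")
    event_strs = (start_base + pd.to_timedelta(onset, unit="D")).strftime("%Y%m%d")
    fda_strs = fda_base.strftime("%Y%m%d")
    fda_prev_strs = (fda_base - pd.Timedelta(days=7)).strftime("%Y%m%d")

    # outcome draws, vectorised per code and status
    out_draw = {
        status: {
            code: rng.random(n) < p for code, p in config.outcome_probs[status].items()
        }
        for status in ("event", "no_event")
    }

    covid_terms = bundled_terms("COVID-19", "narrow")
    aki_terms = bundled_terms("Acute kidney injury", "narrow")
    broad_terms = sorted(
        set(bundled_terms("Acute kidney injury", "broad")) - set(aki_terms)
    )
    covid_ix = rng.integers(0, len(covid_terms), size=(n, 2))
    aki_ix = rng.integers(0, len(aki_terms), size=(n, 2))
    generic_ix = rng.integers(0, len(_GENERIC_PTS), size=n)
    broad_ix = rng.integers(0, len(broad_terms), size=n)
    exp_name_ix = rng.integers(0, len(_EXPOSED_DRUGNAMES), size=n)
    ctl_name_ix = rng.integers(0, len(_CONTROL_DRUGS), size=n)
    reporter_pick = rng.integers(0, 3, size=n)
    age_jitter = rng.random(n)
    concomitant = rng.random(n) < 0.25

    tables = FaersTables()
    truth = GroundTruth(n_cases=n)
    onset_ledger: dict[str, int] = {}
    case_rows = []

    for i in range(n):
        caseid = str(18_000_000 + i)
        n_versions = 2 if dup_version[i] else 1
        primaryid = f"{caseid}{n_versions}"

        lev = {name: conf[name].levels[levels_ix[name][i]] for name in conf}
        band = lev.get("age_band", "Unknown")
        if band in _AGE_RANGES:
            lo_a, hi_a = _AGE_RANGES[band]
            age = str(int(lo_a + age_jitter[i] * (hi_a - lo_a + 1)))
            age_cod = "YR"
        else:
            age, age_cod = "", ""
        sex = lev.get("sex", "Unknown")
        sex = sex if sex in ("F", "M") else ""
        rep_codes = _REPORTER_CODES[lev.get("reporter", "Unknown")]
        occp = rep_codes[reporter_pick[i] % len(rep_codes)]
        country = lev.get("country", "Unknown")
        country = "" if country == "Unknown" else country

        start_dt = start_strs[i]
        event_dt_full = event_strs[i]
        event_dt = event_dt_full[:6] if partial_ev_dt[i] else event_dt_full

        demo = DemoRecord(
            primaryid=primaryid,
            caseid=caseid,
            fda_dt=fda_strs[i],
            event_dt=event_dt,
            age=age,
            age_cod=age_cod,
            sex=sex,
            occp_cod=occp,
            occr_country=country,
        )
        tables.demo.append(demo)
        if n_versions == 2:
            # an earlier superseded version: lower primaryid, earlier fda_dt
            tables.demo.append(
                replace(demo, primaryid=f"{caseid}1", fda_dt=fda_prev_strs[i])
            )
            truth.n_dup_versions += 1
        if exact_dup[i]:
            tables.demo.append(replace(demo))
            truth.n_exact_dups += 1

        for pid in ([primaryid, f"{caseid}1"] if n_versions == 2 else [primaryid]):
            if exposed[i]:
                dn = _EXPOSED_DRUGNAMES[exp_name_ix[i]]
                ai = "REMDESIVIR"
            else:
                dn, ai = _CONTROL_DRUGS[ctl_name_ix[i]]
            tables.drug.append(DrugRecord(pid, "1", "PS", dn, ai))
            if concomitant[i]:
                tables.drug.append(DrugRecord(pid, "2", "C", "ASPIRIN", "ASPIRIN"))
            tables.ther.append(TherRecord(pid, "1", start_dt))
            tables.indi.append(IndiRecord(pid, "1", covid_terms[covid_ix[i, 0]]))
            if multi_pt[i]:
                other = covid_terms[covid_ix[i, 1]]
                if other != covid_terms[covid_ix[i, 0]]:
                    tables.indi.append(IndiRecord(pid, "1", other))
            if preexisting[i]:
                tables.indi.append(IndiRecord(pid, "1", aki_terms[aki_ix[i, 1]]))
            if event[i]:
                tables.reac.append(ReacRecord(pid, aki_terms[aki_ix[i, 0]]))
                if multi_pt[i]:
                    other = aki_terms[aki_ix[i, 1]]
                    if other != aki_terms[aki_ix[i, 0]]:
                        tables.reac.append(ReacRecord(pid, other))
            tables.reac.append(ReacRecord(pid, _GENERIC_PTS[generic_ix[i]]))
            if broad_only[i]:
                tables.reac.append(ReacRecord(pid, broad_terms[broad_ix[i]]))
            if has_outcome[i]:
                status = "event" if event[i] else "no_event"
                for code, hit in out_draw[status].items():
                    if hit[i]:
                        tables.outc.append(OutcRecord(pid, code))
            tables.rpsr.append(RpsrRecord(pid, "HP" if occp else "CSM"))

        if not preexisting[i]:
            if exposed[i]:
                truth.n_exposed += 1
                truth.a += int(event[i])
                truth.b += int(not event[i])
            else:
                truth.n_control += 1
                truth.c += int(event[i])
                truth.d += int(not event[i])
            if event[i] and not partial_ev_dt[i]:
                onset_ledger[caseid] = int(onset[i])
        else:
            truth.n_preexisting += 1

        case_rows.append(
            {
                "caseid": caseid,
                "primaryid": primaryid,
                "exposed": bool(exposed[i]),
                "event": bool(event[i]),
                "preexisting": bool(preexisting[i]),
                "onset_days": int(onset[i]),
                "event_dt_partial": bool(partial_ev_dt[i]),
                **{name: conf[name].levels[levels_ix[name][i]] for name in conf},
            }
        )

    truth.onset_days = onset_ledger
    truth.cases = pd.DataFrame(case_rows)
    return SyntheticQuarter(tables=tables, truth=truth, config=config)


def paper_scale_scenario(seed: int = 0) -> ScenarioConfig:
    """A scenario at the scale of the remdesivir–AKI study cohort.

    3,991 exposed vs 8,878 control cases; the control-arm event
    probability (516/8,878) and the conditional odds ratio
    ((589x8,362)/(3,402x516) ≈ 2.806) are chosen so the expected 2x2 table
    reproduces the study's crude-table margins.  Covariate distributions
    follow the pooled demographics of that cohort but carry no confounding
    effects, so the crude ROR is the estimand.
    """
    return ScenarioConfig(
        n_exposed=3991,
        n_control=8878,
        true_or=(589 * 8362) / (3402 * 516),
        baseline_event_prob=516 / 8878,
        partial_date_prob=0.45,
        preexisting_event_prob=19 / 12888,
        seed=seed,
    )


def confounded_scenario(seed: int = 0, n_exposed: int = 3000, n_control: int = 7000) -> ScenarioConfig:
    """A scenario with demographic confounding for matching demonstrations.

    Older age and male sex raise both the odds of receiving the study drug
    and the odds of the event, so the crude ROR is biased away from the
    conditional ``true_or`` (=2) and propensity-score matching should move
    the estimate toward it.
    """
    conf = _default_confounders()
    conf["age_band"] = replace(
        conf["age_band"],
        exposure_logodds=(0.0, 0.2, 0.6, 1.0, 0.3),
        event_logodds=(0.0, 0.1, 0.5, 0.9, 0.3),
    )
    conf["sex"] = replace(
        conf["sex"], exposure_logodds=(0.0, 0.4, 0.1), event_logodds=(0.0, 0.35, 0.1)
    )
    return ScenarioConfig(
        n_exposed=n_exposed,
        n_control=n_control,
        true_or=2.0,
        baseline_event_prob=0.05,
        confounders=conf,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_exposed: int = 10_000, n_control: int = 10_000) -> ScenarioConfig:
    """No association (true OR = 1), no confounding: the pipeline's ROR CI
    should cover 1."""
    return ScenarioConfig(
        n_exposed=n_exposed,
        n_control=n_control,
        true_or=1.0,
        baseline_event_prob=0.06,
        seed=seed,
    )


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a scenario from YAML; confounders use the ConfounderSpec fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "confounders" in raw:
        raw["confounders"] = {
            name: ConfounderSpec(
                levels=tuple(spec["levels"]),
                probs=tuple(spec["probs"]),
                exposure_logodds=tuple(spec.get("exposure_logodds", ())),
                event_logodds=tuple(spec.get("event_logodds", ())),
            )
            for name, spec in raw["confounders"].items()
        }
    if "onset_dist" in raw:
        raw["onset_dist"] = (raw["onset_dist"][0], raw["onset_dist"][1])
    return ScenarioConfig(**raw)
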