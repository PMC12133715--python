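"""Synthetic linked registry + claims generator.

Emulates the data structure of a population-based cancer-registry cohort
linked to hospital-discharge (HDD) and outpatient-services (OPS) claims: a
latent illness-death process with constant cause-specific hazards for
recurrence, second primary cancer and death (competing events drawn as
independent exponentials, first occurrence wins), emigration and
administrative censoring, and claims generated from the latent history —
including primary-treatment codes in the initial treatment window that a
recurrence algorithm must not misread as recurrence.

The generator also provides the closed-form cumulative-incidence oracle for
constant hazards, ``analytic_cif``, used to validate the nonparametric
estimator by simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .ascertain import months_to_days, surveillance_start
from .cohort import STAGES, SUBTYPES

TRUTH_EVENTS = ("recurrence", "second_primary", "death", "emigration", "admin_censor")

REGISTRY_COLUMNS = [
    "patient_id", "birth_date", "diagnosis_date", "topography", "stage_tnm",
    "er_status", "pr_status", "her2_status", "histology",
    "prior_cancer_date", "prior_cancer_site", "synchronous_cancer_flag",
    "dco_or_autopsy_flag", "vital_status", "death_date", "emigration_date",
    "second_primary_site", "second_primary_date",
]
HDD_COLUMNS = ["patient_id", "admission_date", "discharge_date", "diagnosis_codes", "procedure_codes"]
OPS_COLUMNS = ["patient_id", "service_date", "service_code"]
TRUTH_COLUMNS = ["patient_id", "true_event", "true_time_days", "true_death_time_days"]

_SECOND_PRIMARY_SITES = ("C18", "C34", "C54", "C56", "C73")
_METASTASIS_CODES = ("1970", "1975", "1977", "1983", "1985")
_HISTOLOGIES = ("ductal", "lobular", "adenocarcinoma", "other")


def default_hazard_table() -> dict[tuple[str, str], dict[str, float]]:
    """Cause-specific constant hazards per year by (subtype, stage).

    Calibrated so 10-year cumulative incidences order as stage III > II > I
    and TN > HER2+ > HR+/HER2-, with overall magnitudes plausible for a
    non-metastatic breast-cancer cohort; exact published values are not a
    generator target.
    """
    rec_by_stage = {"I": 0.015, "II": 0.032, "III": 0.065}
    death_by_stage = {"I": 0.010, "II": 0.015, "III": 0.035}
    mult = {"HR+/HER2-": 1.0, "HER2+": 1.2, "TN": 1.8, "not_available": 1.0}
    table = {}
    for subtype in SUBTYPES:
        for stage in STAGES:
            table[(subtype, stage)] = {
                "recurrence": rec_by_stage[stage] * mult[subtype],
                "second_primary": 0.006,
                "death": death_by_stage[stage],
            }
    return table


@dataclass
class ClaimModel:
    """How claims are generated from the latent event history.

    ``p_indicator_class`` gives the class mix of the first recurrence claim
    (defaults follow the observed breakdown of ascertained recurrences:
    chemotherapy 5.2, radiotherapy 4.1, breast surgery/malignant breast 13.5
    and secondary neoplasm 3.3 shares of a 26.1 % total).
    ``claim_delay_days`` is a constant (degenerate-distribution) delay from
    the true recurrence to its first claim.  ``primary_treatment_claim_months``
    is the HER2-negative primary-treatment window; HER2-positive women emit
    treatment codes for 24 months, mirroring the longer primary treatment.
    """

    p_indicator_class: dict[int, float] = field(
        default_factory=lambda: {1: 0.199, 2: 0.157, 3: 0.518, 4: 0.126}
    )
    claim_delay_days: int = 30
    primary_treatment_claim_months: int = 12
    p_missed_recurrence: float = 0.0


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort.

    All hazards are per year; dates are calendar dates; identical seeds give
    byte-identical output tables.
    """

    n_patients: int = 5825
    seed: int = 0
    diagnosis_start: date = date(2004, 1, 1)
    diagnosis_end: date = date(2010, 12, 31)
    age_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "20-39": 0.055, "40-49": 0.198, "50-59": 0.255, "60-69": 0.360, "70-74": 0.132,
        }
    )
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"I": 0.510, "II": 0.358, "III": 0.132}
    )
    subtype_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "HR+/HER2-": 0.661, "HER2+": 0.145, "TN": 0.078, "not_available": 0.116,
        }
    )
    hazard_table: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=default_hazard_table
    )
    post_recurrence_death_hazard: float = 0.09
    emigration_hazard: float = 0.003
    admin_cutoff: date = date(2021, 12, 31)
    claim_model: ClaimModel = field(default_factory=ClaimModel)

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ValueError("n_patients: must be a nonnegative integer")
        if self.diagnosis_end < self.diagnosis_start:
            raise ValueError("diagnosis_end: before diagnosis_start")
        if self.admin_cutoff <= self.diagnosis_end:
            raise ValueError("admin_cutoff: must be after the diagnosis window")
        for name, dist, domain in (
            ("age_distribution", self.age_distribution, None),
            ("stage_distribution", self.stage_distribution, set(STAGES)),
            ("subtype_distribution", self.subtype_distribution, set(SUBTYPES)),
        ):
            if any(w < 0 for w in dist.values()):
                raise ValueError(f"{name}: negative weight")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: weights must sum to 1")
            if domain is not None and not set(dist) <= domain:
                raise ValueError(f"{name}: unknown category {set(dist) - domain}")
        for key, hazards in self.hazard_table.items():
            for cause, lam in hazards.items():
                if lam < 0:
                    raise ValueError(f"hazard_table[{key}][{cause}]: negative hazard")
        if self.post_recurrence_death_hazard < 0:
            raise ValueError("post_recurrence_death_hazard: negative hazard")
        if self.emigration_hazard < 0:
            raise ValueError("emigration_hazard: negative hazard")
        cm = self.claim_model
        if set(cm.p_indicator_class) != {1, 2, 3, 4} or any(
            w < 0 for w in cm.p_indicator_class.values()
        ):
            raise ValueError("claim_model.p_indicator_class: needs nonnegative weights for classes 1-4")
        if cm.claim_delay_days < 0:
            raise ValueError("claim_model.claim_delay_days: must be nonnegative")
        if not (0.0 <= cm.p_missed_recurrence < 1.0):
            raise ValueError("claim_model.p_missed_recurrence: must be in [0, 1)")
        if cm.primary_treatment_claim_months < 0:
            raise ValueError("claim_model.primary_treatment_claim_months: must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "claim_model" in raw:
            cm = dict(raw["claim_model"])
            if "p_indicator_class" in cm:
                cm["p_indicator_class"] = {int(k): v for k, v in cm["p_indicator_class"].items()}
            raw["claim_model"] = ClaimModel(**cm)
        if "hazard_table" in raw:
            raw["hazard_table"] = {
                (k.split("|")[0], k.split("|")[1]): v for k, v in raw["hazard_table"].items()
            }
        for key in ("diagnosis_start", "diagnosis_end", "admin_cutoff"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["hazard_table"] = {f"{k[0]}|{k[1]}": v for k, v in self.hazard_table.items()}
        for key in ("diagnosis_start", "diagnosis_end", "admin_cutoff"):
            out[key] = out[key].isoformat()
        return out


def analytic_cif(lambda_cause: float, lambda_total: float, t: float) -> float:
    """Closed-form cause-specific CIF under constant competing hazards.

    With independent exponential latent times and total hazard
    ``lambda_total`` of which ``lambda_cause`` is attributable to the cause
    of interest, the probability of failing from that cause by time ``t`` is

        (lambda_cause / lambda_total) * (1 - exp(-lambda_total * t)).
    """
    if not 0 < lambda_cause <= lambda_total:
        raise ValueError("require 0 < lambda_cause <= lambda_total")
    if t < 0:
        raise ValueError("t must be nonnegative")
    return (lambda_cause / lambda_total) * (1.0 - math.exp(-lambda_total * t))


def _exp_days(rng: np.random.Generator, rate_per_year: float) -> float:
    """One exponential latent time in days; inf when the rate is zero."""
    if rate_per_year <= 0:
        return math.inf
    return float(np.floor(rng.exponential(1.0 / rate_per_year) * 365.25)) + 1.0


def _birth_date(rng: np.random.Generator, diagnosis: date, age: int) -> date:
    """A birth date giving exactly `age` completed years at diagnosis."""
    try:
        anniversary = date(diagnosis.year - age, diagnosis.month, diagnosis.day)
    except ValueError:  # Feb 29 diagnosis, non-leap birth year
        anniversary = date(diagnosis.year - age, diagnosis.month, 28)
    return anniversary - timedelta(days=int(rng.integers(0, 360)))


def _markers(rng: np.random.Generator, subtype: str) -> tuple[str, str, str]:
    """ER/PR/HER2 triplet consistent with a surrogate subtype."""
    if subtype == "HR+/HER2-":
        pr = "positive" if rng.random() < 0.8 else "negative"
        return "positive", pr, "negative"
    if subtype == "HER2+":
        er = "positive" if rng.random() < 0.6 else "negative"
        pr = "positive" if rng.random() < 0.5 else "negative"
        return er, pr, "positive"
    if subtype == "TN":
        return "negative", "negative", "negative"
    # not classifiable: HER2 missing blocks every rule
    er = ("positive", "negative", "missing")[int(rng.integers(0, 3))]
    pr = ("positive", "negative", "missing")[int(rng.integers(0, 3))]
    return er, pr, "missing"


def _sample(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    weights = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (registry, HDD claims, OPS claims, truth) tables.

    Each woman gets exactly one truth record: her first latent event among
    recurrence, second primary, death and emigration (independent exponential
    times, minimum wins), or administrative censoring at the cut-off.  Women
    whose first event is a recurrence or second primary draw a post-event
    death time.  Claims are emitted from the truth: primary-treatment codes
    for everyone inside the initial treatment window, and for true
    recurrences a first dated indicator claim after the configured delay
    (unless suppressed by ``p_missed_recurrence``).  No claim postdates death
    or the administrative cut-off.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cm = config.claim_model

    registry_rows: list[dict] = []
    hdd_rows: list[dict] = []
    ops_rows: list[dict] = []
    truth_rows: list[dict] = []

    window_days_total = (config.diagnosis_end - config.diagnosis_start).days

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        diagnosis = config.diagnosis_start + timedelta(days=int(rng.integers(0, window_days_total + 1)))
        band = str(_sample(rng, config.age_distribution))
        lo, hi = (int(x) for x in band.split("-"))
        age = int(rng.integers(lo, hi + 1))
        birth = _birth_date(rng, diagnosis, age)
        stage = str(_sample(rng, config.stage_distribution))
        subtype = str(_sample(rng, config.subtype_distribution))
        er, pr, her2 = _markers(rng, subtype)
        histology = str(_sample(rng, {"ductal": 0.80, "lobular": 0.12, "adenocarcinoma": 0.03, "other": 0.05}))

        hazards = config.hazard_table[(subtype, stage)]
        admin_days = (config.admin_cutoff - diagnosis).days
        latent = {
            "recurrence": _exp_days(rng, hazards["recurrence"]),
            "second_primary": _exp_days(rng, hazards["second_primary"]),
            "death": _exp_days(rng, hazards["death"]),
            "emigration": _exp_days(rng, config.emigration_hazard),
        }
        # first occurrence wins; ties broken by the fixed priority order
        event, event_days = min(
            latent.items(), key=lambda kv: (kv[1], TRUTH_EVENTS.index(kv[0]))
        )
        if event_days > admin_days:
            event, event_days = "admin_censor", float(admin_days)
        event_days = int(event_days)

        # vital status: post-event death for recurrence / second primary
        death_days: Optional[int] = None
        if event == "death":
            death_days = event_days
        elif event in ("recurrence", "second_primary"):
            post = _exp_days(rng, config.post_recurrence_death_hazard)
            if not math.isinf(post) and event_days + post <= admin_days:
                death_days = event_days + int(post)

        emigration_days = event_days if event == "emigration" else None
        second_primary_days = event_days if event == "second_primary" else None
        cap_days = min(
            admin_days,
            death_days if death_days is not None else admin_days,
            emigration_days if emigration_days is not None else admin_days,
        )

        truth_rows.append(
            {
                "patient_id": pid,
                "true_event": event,
                "true_time_days": event_days,
                "true_death_time_days": death_days,
            }
        )

        registry_rows.append(
            {
                "patient_id": pid,
                "birth_date": birth.isoformat(),
                "diagnosis_date": diagnosis.isoformat(),
                "topography": "C50",
                "stage_tnm": stage,
                "er_status": er,
                "pr_status": pr,
                "her2_status": her2,
                "histology": histology,
                "prior_cancer_date": "",
                "prior_cancer_site": "",
                "synchronous_cancer_flag": False,
                "dco_or_autopsy_flag": False,
                "vital_status": "dead" if death_days is not None else "alive",
                "death_date": (diagnosis + timedelta(days=death_days)).isoformat()
                if death_days is not None
                else "",
                "emigration_date": (diagnosis + timedelta(days=emigration_days)).isoformat()
                if emigration_days is not None
                else "",
                "second_primary_site": str(_sample(rng, dict.fromkeys(_SECOND_PRIMARY_SITES, 0.2)))
                if second_primary_days is not None
                else "",
                "second_primary_date": (diagnosis + timedelta(days=second_primary_days)).isoformat()
                if second_primary_days is not None
                else "",
            }
        )

        # --- primary-treatment claims, strictly inside the treatment window
        if her2 == "positive":
            treat_months = max(cm.primary_treatment_claim_months, 24)
        else:
            treat_months = cm.primary_treatment_claim_months
        treat_window = months_to_days(treat_months)
        n_treat = int(rng.integers(2, 6))
        treat_days = sorted(int(d) for d in rng.integers(0, max(treat_window, 1), size=n_treat))
        for day in treat_days:
            if day > cap_days or day >= treat_window:
                continue
            kind = rng.random()
            when = diagnosis + timedelta(days=day)
            if kind < 0.4:  # chemotherapy session (outpatient)
                ops_rows.append({"patient_id": pid, "service_date": when.isoformat(), "service_code": "9925"})
            elif kind < 0.7:  # radiotherapy session (outpatient)
                ops_rows.append({"patient_id": pid, "service_date": when.isoformat(), "service_code": "9229"})
            else:  # primary breast surgery admission
                stay = int(rng.integers(1, 8))
                discharge = min(day + stay, cap_days)
                hdd_rows.append(
                    {
                        "patient_id": pid,
                        "admission_date": when.isoformat(),
                        "discharge_date": (diagnosis + timedelta(days=discharge)).isoformat(),
                        "diagnosis_codes": "1749",
                        "procedure_codes": "8543",
                    }
                )

        # --- recurrence claims
        if event == "recurrence" and rng.random() >= cm.p_missed_recurrence:
            claim_day = min(event_days + cm.claim_delay_days, cap_days)
            cls = int(_sample(rng, cm.p_indicator_class))
            when = diagnosis + timedelta(days=claim_day)
            if cls == 1:
                ops_rows.append({"patient_id": pid, "service_date": when.isoformat(), "service_code": "9925"})
            elif cls == 2:
                ops_rows.append({"patient_id": pid, "service_date": when.isoformat(), "service_code": "9229"})
            elif cls == 3:
                stay = int(rng.integers(1, 10))
                hdd_rows.append(
                    {
                        "patient_id": pid,
                        "admission_date": when.isoformat(),
                        "discharge_date": (diagnosis + timedelta(days=min(claim_day + stay, cap_days))).isoformat(),
                        "diagnosis_codes": "1749",
                        "procedure_codes": "8541",
                    }
                )
            else:
                stay = int(rng.integers(2, 12))
                code = _METASTASIS_CODES[int(rng.integers(0, len(_METASTASIS_CODES)))]
                hdd_rows.append(
                    {
                        "patient_id": pid,
                        "admission_date": when.isoformat(),
                        "discharge_date": (diagnosis + timedelta(days=min(claim_day + stay, cap_days))).isoformat(),
                        "diagnosis_codes": code,
                        "procedure_codes": "",
                    }
                )
            # follow-up treatment claims after the recurrence
            for _ in range(int(rng.integers(0, 3))):
                extra = claim_day + int(rng.integers(30, 200))
                if extra <= cap_days:
                    ops_rows.append(
                        {
                            "patient_id": pid,
                            "service_date": (diagnosis + timedelta(days=extra)).isoformat(),
                            "service_code": "9925",
                        }
                    )

    registry = pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS)
    hdd = pd.DataFrame(hdd_rows, columns=HDD_COLUMNS)
    ops = pd.DataFrame(ops_rows, columns=OPS_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth["true_death_time_days"] = truth["true_death_time_days"].astype("Int64")
    return registry, hdd, ops, truth


def make_exclusion_demo_registry(
    removals: dict[str, int],
    n_clean: int,
    diagnosis: date = date(2005, 6, 15),
) -> pd.DataFrame:
    """A registry table engineered so each eligibility criterion removes a
    chosen number of women.

    Every generated row violates exactly one criterion (and none earlier in
    the cascade order), or none at all for the ``n_clean`` eligible rows;
    useful for demonstrating and testing the exclusion-cascade arithmetic.
    Recognised keys match the cascade labels in :mod:`bcrecur.cohort`.
    """

    def base(pid: int) -> dict:
        return {
            "patient_id": f"D{pid:06d}",
            "birth_date": date(diagnosis.year - 55, 6, 1).isoformat(),
            "diagnosis_date": diagnosis.isoformat(),
            "topography": "C50",
            "stage_tnm": "I",
            "er_status": "positive",
            "pr_status": "negative",
            "her2_status": "negative",
            "histology": "ductal",
            "prior_cancer_date": "",
            "prior_cancer_site": "",
            "synchronous_cancer_flag": False,
            "dco_or_autopsy_flag": False,
            "vital_status": "alive",
            "death_date": "",
            "emigration_date": "",
            "second_primary_site": "",
            "second_primary_date": "",
        }

    tweaks = {
        "prior_cancer": {"prior_cancer_date": date(2000, 1, 1).isoformat(), "prior_cancer_site": "C18"},
        "synchronous_cancer": {"synchronous_cancer_flag": True},
        "dco_or_autopsy": {"dco_or_autopsy_flag": True},
        "no_survival_time": {"vital_status": "dead", "death_date": diagnosis.isoformat()},
        "death_within_6_months": {
            "vital_status": "dead",
            "death_date": (diagnosis + timedelta(days=100)).isoformat(),
        },
        "missing_stage": {"stage_tnm": "missing"},
        "stage_iv": {"stage_tnm": "IV"},
        "age_over_74": {"birth_date": date(diagnosis.year - 80, 6, 1).isoformat()},
    }
    unknown = set(removals) - set(tweaks)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")

    rows: list[dict] = []
    pid = 0
    for label, count in removals.items():
        for _ in range(count):
            row = base(pid)
            row.update(tweaks[label])
            rows.append(row)
            pid += 1
    for _ in range(n_clean):
        rows.append(base(pid))
        pid += 1
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
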