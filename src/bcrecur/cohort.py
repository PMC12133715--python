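"""Cohort construction: eligibility cascade and analysis covariates.

The registry extract is reduced to the analysis cohort by a fixed sequence of
exclusions (prior or synchronous cancer other than non-melanoma skin cancer
C44, death-certificate-only registration, zero or very short survival,
missing stage, de-novo metastatic disease, age over 74), each woman being
removed at the first criterion she matches.  Eligible women then receive the
derived covariates used throughout: surrogate intrinsic subtype from ER/PR/
HER2, age group at diagnosis, and period of diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Callable, Optional

import pandas as pd

SUBTYPES = ("HR+/HER2-", "HER2+", "TN", "not_available")
STAGES = ("I", "II", "III")

#: Table-style five age bands (default) and the coarser four-band grouping
#: used for some stratified incidence curves.
AGE_BANDS_FIVE = ((20, 39), (40, 49), (50, 59), (60, 69), (70, 74))
AGE_BANDS_FOUR = ((20, 39), (40, 49), (50, 69), (70, 74))

#: Diagnosis-period split: years <= PERIOD_SPLIT-1 form the early period.
PERIOD_EARLY = "2004-2006"
PERIOD_LATE = "2007-2010"
PERIOD_SPLIT = 2007

#: Death within six months of diagnosis, as half of 365.25 rounded up.
SIX_MONTHS_DAYS = 183

NON_MELANOMA_SKIN = "C44"


def age_at(birth_date: date, on: date) -> int:
    """Age in completed years (floor) on a given date."""
    return on.year - birth_date.year - ((on.month, on.day) < (birth_date.month, birth_date.day))


def assign_subtype(er: str, pr: str, her2: str) -> str:
    """Surrogate intrinsic subtype from ER/PR/HER2 immunohistochemistry.

    HER2-positive tumours are HER2+ regardless of hormone receptors;
    HER2-negative tumours with ER or PR positivity are HR+/HER2-;
    HER2-negative with both ER and PR negative are triple negative;
    anything else (a marker missing where it matters) is not classifiable.
    Total function over {positive, negative, missing}^3.
    """
    if her2 == "positive":
        return "HER2+"
    if her2 == "negative":
        if er == "positive" or pr == "positive":
            return "HR+/HER2-"
        if er == "negative" and pr == "negative":
            return "TN"
    return "not_available"


@dataclass
class ExclusionLog:
    """Per-criterion removal counts, in application order."""

    initial: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.initial - sum(n for _, n in self.steps)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": label, "removed": n} for label, n in self.steps]
        rows.append({"criterion": "final_cohort", "removed": self.final})
        return pd.DataFrame(rows, columns=["criterion", "removed"])


def _days(later, earlier) -> int:
    return (pd.Timestamp(later) - pd.Timestamp(earlier)).days


def _has(value) -> bool:
    return not (value is None or value == "" or (isinstance(value, float) and pd.isna(value)))


def _flag(value) -> bool:
    """Boolean flag tolerant of CSV round-trips ('True'/'false'/1/'')."""
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value) and not (isinstance(value, float) and pd.isna(value))


# Each criterion: (label, predicate over a registry row as a namedtuple).
# Order is fixed; a woman is removed at the first criterion she matches.
def _crit_prior_cancer(r) -> bool:
    if not _has(r.prior_cancer_date):
        return False
    site = str(getattr(r, "prior_cancer_site", "") or "")
    return not site.startswith(NON_MELANOMA_SKIN)


def _crit_synchronous(r) -> bool:
    return _flag(r.synchronous_cancer_flag)


def _crit_dco_autopsy(r) -> bool:
    return _flag(r.dco_or_autopsy_flag)


def _crit_no_survival(r) -> bool:
    return _has(r.death_date) and _days(r.death_date, r.diagnosis_date) == 0


def _crit_death_6m(r) -> bool:
    return _has(r.death_date) and _days(r.death_date, r.diagnosis_date) < SIX_MONTHS_DAYS


def _crit_missing_stage(r) -> bool:
    return not _has(r.stage_tnm) or str(r.stage_tnm) == "missing"


def _crit_stage_iv(r) -> bool:
    return str(r.stage_tnm) == "IV"


def _crit_age_over_74(r) -> bool:
    return age_at(pd.Timestamp(r.birth_date).date(), pd.Timestamp(r.diagnosis_date).date()) > 74


ELIGIBILITY_CRITERIA: tuple[tuple[str, Callable], ...] = (
    ("prior_cancer", _crit_prior_cancer),
    ("synchronous_cancer", _crit_synchronous),
    ("dco_or_autopsy", _crit_dco_autopsy),
    ("no_survival_time", _crit_no_survival),
    ("death_within_6_months", _crit_death_6m),
    ("missing_stage", _crit_missing_stage),
    ("stage_iv", _crit_stage_iv),
    ("age_over_74", _crit_age_over_74),
)


def apply_eligibility(
    registry: pd.DataFrame,
    reference_end: Optional[date] = None,
    criteria: tuple[tuple[str, Callable], ...] = ELIGIBILITY_CRITERIA,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility cascade; returns (eligible cohort, ExclusionLog).

    Exclusions are sequential: each woman is counted under the first
    criterion she matches, so per-criterion counts depend on the order while
    final membership does not.  ``reference_end`` (end of follow-up) is used
    to validate recorded death dates.  Duplicate patient ids are rejected.
    """
    if registry["patient_id"].duplicated().any():
        dup = registry.loc[registry["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id: {dup}")
    if reference_end is not None:
        for r in registry.itertuples(index=False):
            if _has(r.death_date) and pd.Timestamp(r.death_date).date() > reference_end:
                raise ValueError(
                    f"patient {r.patient_id}: death_date after end of follow-up"
                )

    log = ExclusionLog(initial=len(registry))
    remaining = registry
    for label, predicate in criteria:
        if len(remaining):
            mask = remaining.apply(
                lambda row: bool(predicate(row)), axis=1, result_type="reduce"
            ).to_numpy(dtype=bool)
        else:
            mask = pd.Series([], dtype=bool).to_numpy()
        log.steps.append((label, int(mask.sum())))
        remaining = remaining.loc[~mask]
    return remaining.reset_index(drop=True), log


def _band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def age_group(age: int, bands: str = "five") -> str:
    """Age band label for an age in completed years.

    ``bands`` selects the five-band table grouping (default) or the
    four-band grouping used for stratified incidence curves.
    """
    table = AGE_BANDS_FIVE if bands == "five" else AGE_BANDS_FOUR
    for lo, hi in table:
        if lo <= age <= hi:
            return _band_label(lo, hi)
    raise ValueError(f"age {age} outside 20-74 (should have been excluded)")


def period_label(diagnosis_year: int) -> str:
    return PERIOD_EARLY if diagnosis_year < PERIOD_SPLIT else PERIOD_LATE


def derive_strata(cohort: pd.DataFrame, bands: str = "five") -> pd.DataFrame:
    """Attach derived analysis covariates to an eligible cohort.

    Adds ``age_at_diagnosis``, ``age_group``, ``period``, ``subtype``
    columns; ``stage`` is taken as recorded.  Ages outside 20-74 are
    rejected — such women should have been excluded upstream.
    """
    out = cohort.copy()
    ages, groups, periods, subtypes = [], [], [], []
    for r in out.itertuples(index=False):
        diagnosis = pd.Timestamp(r.diagnosis_date).date()
        a = age_at(pd.Timestamp(r.birth_date).date(), diagnosis)
        ages.append(a)
        groups.append(age_group(a, bands))
        periods.append(period_label(diagnosis.year))
        subtypes.append(assign_subtype(str(r.er_status), str(r.pr_status), str(r.her2_status)))
    out["age_at_diagnosis"] = ages
    out["age_group"] = groups
    out["period"] = periods
    out["subtype"] = subtypes
    out["stage"] = out["stage_tnm"].astype(str)
    return out
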