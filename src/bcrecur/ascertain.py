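"""Claims-based recurrence ascertainment.

Recurrence after breast cancer is operationalised as the earliest of four
indicator classes found in linked administrative claims (hospital discharge
data, HDD, and outpatient services, OPS; both ICD-9-CM coded):

1. restart of chemotherapy,
2. restart of radiotherapy,
3. breast surgery (mastectomy) or admission for a malignant breast neoplasm,
4. admission for a secondary malignant neoplasm (metastasis).

Indicators are only counted from a subtype-specific surveillance start —
12 months after diagnosis for HER2-negative disease, 24 months for
HER2-positive — so that primary-treatment claims are not misread as
recurrence.  Each woman's first event is then resolved against the competing
events recorded in the registry (second primary cancer, death, emigration,
administrative end of follow-up).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Event types, in tie-break priority order (lower index wins on equal dates).
EVENT_TYPES = ("recurrence", "second_primary", "death", "emigration", "admin_censor")

#: ICD-9-CM lexical form after dot-stripping: optional V/E prefix, 2-5 digits.
_CODE_RE = re.compile(r"^[VE]?\d{2,5}$")


def months_to_days(months: int) -> int:
    """Convert whole months to days as round(m * 30.4375).

    Uses Python's round (half-to-even): 12 months -> 365 days,
    24 months -> 730 days.
    """
    return round(months * 30.4375)


def surveillance_start(her2: str, sensitivity_12m: bool = False) -> int:
    """Surveillance-start offset in months for a given HER2 status.

    HER2-positive women start at 24 months (longer primary treatment),
    everyone else — including missing HER2 — at 12 months.  The
    ``sensitivity_12m`` flag forces the uniform 12-month cut-off used in
    sensitivity analyses.
    """
    if sensitivity_12m:
        return 12
    return 24 if her2 == "positive" else 12


def normalize_code(code: str) -> str:
    """Strip dots and whitespace, uppercase (ICD-9-CM '85.41' -> '8541')."""
    return str(code).replace(".", "").replace(" ", "").upper()


@dataclass
class CodeSet:
    """ICD-9-CM code prefixes defining the four recurrence indicator classes.

    Prefixes are matched dot-stripped against both diagnosis and procedure
    codes.  Classes may overlap; reporting always uses the lowest matching
    class number.  The defaults are standard oncology claim codes consistent
    with the indicator definitions; the real lists are configuration, not
    logic, and can be loaded from YAML.
    """

    class1_chemotherapy: list[str] = field(default_factory=lambda: ["9925", "V581"])
    class2_radiotherapy: list[str] = field(default_factory=lambda: ["922", "V580"])
    class3_breast_surgery_or_malignant_breast: list[str] = field(
        default_factory=lambda: ["854", "174"]
    )
    class4_secondary_malignant_neoplasm: list[str] = field(
        default_factory=lambda: ["196", "197", "198"]
    )

    def __post_init__(self) -> None:
        for name, prefixes in self.classes().items():
            if not prefixes or any(not p for p in prefixes):
                raise ValueError(f"code set {name}: prefixes must be non-empty")
        # normalise once
        self.class1_chemotherapy = [normalize_code(p) for p in self.class1_chemotherapy]
        self.class2_radiotherapy = [normalize_code(p) for p in self.class2_radiotherapy]
        self.class3_breast_surgery_or_malignant_breast = [
            normalize_code(p) for p in self.class3_breast_surgery_or_malignant_breast
        ]
        self.class4_secondary_malignant_neoplasm = [
            normalize_code(p) for p in self.class4_secondary_malignant_neoplasm
        ]

    def classes(self) -> dict[str, list[str]]:
        return {
            "class1_chemotherapy": self.class1_chemotherapy,
            "class2_radiotherapy": self.class2_radiotherapy,
            "class3_breast_surgery_or_malignant_breast": self.class3_breast_surgery_or_malignant_breast,
            "class4_secondary_malignant_neoplasm": self.class4_secondary_malignant_neoplasm,
        }

    def by_number(self) -> dict[int, list[str]]:
        return {k + 1: v for k, v in enumerate(self.classes().values())}

    def match_class(self, codes: Iterable[str]) -> Optional[int]:
        """Lowest indicator class matched by any code, or None."""
        best: Optional[int] = None
        for raw in codes:
            code = normalize_code(raw)
            if not _CODE_RE.match(code):
                raise MalformedCode(raw)
            for cls, prefixes in self.by_number().items():
                if best is not None and cls >= best:
                    break
                if any(code.startswith(p) for p in prefixes):
                    best = cls
                    break
        return best

    @classmethod
    def from_yaml(cls, path) -> "CodeSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.classes(), fh, sort_keys=False)


class MalformedCode(ValueError):
    """A claim code not matching the ICD-9-CM lexical form."""


@dataclass(frozen=True)
class ClaimRecord:
    """One dated claim from either linked source.

    For HDD the claim date is the admission date; for OPS the service date.
    """

    patient_id: str
    source: str  # "HDD" | "OPS"
    claim_date: date
    diagnosis_codes: tuple[str, ...] = ()
    procedure_codes: tuple[str, ...] = ()

    @property
    def codes(self) -> tuple[str, ...]:
        return self.diagnosis_codes + self.procedure_codes


@dataclass(frozen=True)
class IndicatorMatch:
    patient_id: str
    claim_date: date
    indicator_class: int
    matched_code: str


@dataclass(frozen=True)
class EventOutcome:
    """A woman's resolved first event after diagnosis."""

    patient_id: str
    event: str  # one of EVENT_TYPES
    time_days: int
    indicator_class: Optional[int] = None  # recurrence only


def match_indicators(
    claims: Sequence[ClaimRecord], code_set: CodeSet, start_date: date
) -> list[IndicatorMatch]:
    """All indicator matches for one patient on/after the surveillance start.

    A claim matches class k if any of its codes begins with a class-k prefix;
    a claim carrying codes of several classes is reported once with the lowest
    class number.  Claims strictly before ``start_date`` never match (the
    surveillance-start boundary is inclusive).  Claims with malformed codes
    are skipped with a warning rather than aborting the patient.
    """
    matches: list[IndicatorMatch] = []
    for claim in claims:
        if claim.claim_date < start_date:
            continue
        try:
            cls = code_set.match_class(claim.codes)
        except MalformedCode as exc:
            logger.warning(
                "patient %s: skipping claim dated %s with malformed code %r",
                claim.patient_id,
                claim.claim_date,
                exc.args[0],
            )
            continue
        if cls is None:
            continue
        prefixes = code_set.by_number()[cls]
        matched = next(
            c for c in claim.codes if any(normalize_code(c).startswith(p) for p in prefixes)
        )
        matches.append(
            IndicatorMatch(claim.patient_id, claim.claim_date, cls, normalize_code(matched))
        )
    matches.sort(key=lambda m: (m.claim_date, m.indicator_class))
    return matches


def ascertain_recurrence(
    diagnosis_date: date,
    her2: str,
    claims: Sequence[ClaimRecord],
    code_set: CodeSet,
    sensitivity_12m: bool = False,
) -> Optional[tuple[date, int]]:
    """Earliest indicator match on/after the surveillance start, if any.

    Returns ``(recurrence_date, indicator_class)`` using the convention that
    the recurrence date is the date of the first qualifying claim; same-day
    multi-class claims report the lowest class.
    """
    offset = months_to_days(surveillance_start(her2, sensitivity_12m))
    start = diagnosis_date + timedelta(days=offset)
    matches = match_indicators(claims, code_set, start)
    if not matches:
        return None
    first = matches[0]
    return first.claim_date, first.indicator_class


def resolve_outcome(
    patient_id: str,
    diagnosis_date: date,
    recurrence: Optional[tuple[date, int]],
    second_primary_date: Optional[date],
    death_date: Optional[date],
    emigration_date: Optional[date],
    admin_cutoff: date,
) -> EventOutcome:
    """First event among recurrence, second primary, death, emigration, cut-off.

    Ties on the same calendar day are broken by the priority
    recurrence > second_primary > death > emigration > admin_censor
    (a recurrence claim on the day of death implies the event preceded death
    within the day's resolution).
    """
    candidates: list[tuple[date, int, str, Optional[int]]] = []
    if recurrence is not None:
        rec_date, rec_class = recurrence
        if rec_date < diagnosis_date:
            raise ValueError(f"patient {patient_id}: recurrence date before diagnosis")
        candidates.append((rec_date, 0, "recurrence", rec_class))
    for d, prio, name in (
        (second_primary_date, 1, "second_primary"),
        (death_date, 2, "death"),
        (emigration_date, 3, "emigration"),
    ):
        if d is not None:
            if d < diagnosis_date:
                raise ValueError(f"patient {patient_id}: {name} date before diagnosis")
            candidates.append((d, prio, name, None))
    if admin_cutoff < diagnosis_date:
        raise ValueError(f"patient {patient_id}: admin_cutoff before diagnosis")
    candidates.append((admin_cutoff, 4, "admin_censor", None))
    when, _, event, cls = min(candidates, key=lambda c: (c[0], c[1]))
    return EventOutcome(patient_id, event, (when - diagnosis_date).days, cls)


# ---------------------------------------------------------------------------
# Cohort-level driver over the three tables
# ---------------------------------------------------------------------------

def claims_from_tables(hdd: pd.DataFrame, ops: pd.DataFrame) -> dict[str, list[ClaimRecord]]:
    """Group HDD + OPS rows into per-patient ClaimRecord lists.

    HDD rows carry pipe-separated diagnosis and procedure code lists and use
    the admission date; OPS rows carry a single service code on the service
    date.
    """

    def _split(value) -> tuple[str, ...]:
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
            return ()
        return tuple(str(value).split("|"))

    out: dict[str, list[ClaimRecord]] = {}
    for row in hdd.itertuples(index=False):
        rec = ClaimRecord(
            patient_id=str(row.patient_id),
            source="HDD",
            claim_date=pd.Timestamp(row.admission_date).date(),
            diagnosis_codes=_split(getattr(row, "diagnosis_codes", "")),
            procedure_codes=_split(getattr(row, "procedure_codes", "")),
        )
        out.setdefault(rec.patient_id, []).append(rec)
    for row in ops.itertuples(index=False):
        rec = ClaimRecord(
            patient_id=str(row.patient_id),
            source="OPS",
            claim_date=pd.Timestamp(row.service_date).date(),
            diagnosis_codes=(str(row.service_code),),
        )
        out.setdefault(rec.patient_id, []).append(rec)
    for claims in out.values():
        claims.sort(key=lambda c: c.claim_date)
    return out


def _opt_date(value) -> Optional[date]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return pd.Timestamp(value).date()


def ascertain_cohort(
    cohort: pd.DataFrame,
    hdd: pd.DataFrame,
    ops: pd.DataFrame,
    code_set: CodeSet,
    admin_cutoff: date,
    sensitivity_12m: bool = False,
) -> pd.DataFrame:
    """Resolve one EventOutcome per cohort member; returns the outcomes table.

    Columns: patient_id, event, time_days, indicator_class.
    """
    claims_by_patient = claims_from_tables(hdd, ops)
    rows = []
    for row in cohort.itertuples(index=False):
        pid = str(row.patient_id)
        diagnosis = pd.Timestamp(row.diagnosis_date).date()
        rec = ascertain_recurrence(
            diagnosis,
            str(row.her2_status),
            claims_by_patient.get(pid, []),
            code_set,
            sensitivity_12m,
        )
        outcome = resolve_outcome(
            pid,
            diagnosis,
            rec,
            _opt_date(getattr(row, "second_primary_date", None)),
            _opt_date(getattr(row, "death_date", None)),
            _opt_date(getattr(row, "emigration_date", None)),
            admin_cutoff,
        )
        rows.append(
            {
                "patient_id": outcome.patient_id,
                "event": outcome.event,
                "time_days": outcome.time_days,
                "indicator_class": outcome.indicator_class,
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "event", "time_days", "indicator_class"])
    out["indicator_class"] = out["indicator_class"].astype("Int64")
    return out
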