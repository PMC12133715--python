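"""Nonparametric competing-risks estimation.

Implements the Aalen-Johansen estimator of the cause-specific cumulative
incidence function (CIF).  With distinct event times t_1 < t_2 < ..., n_j
subjects at risk just before t_j and d_kj events of cause k at t_j, the
overall event-free (Kaplan-Meier) survival is

    S(t_j) = prod_{i <= j} (1 - sum_k d_ki / n_i)

and the cause-k CIF is

    F_k(t) = sum_{t_j <= t} S(t_{j-1}) * d_kj / n_j .

Pointwise variance uses the standard Aalen-type estimator (Aalen 1978; the
Marubini-Valsecchi form) and 95 % confidence intervals the log(-log)
transformation, clamped to [0, 1].  Delayed entry (left truncation) is
supported through per-subject entry times: the risk set at t is
{i : entry_i < t <= time_i}.

Also provides step-function lookup, crude incidence rates per 1000
person-years, conditional CIFs, and stratified estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
CAUSES = ("recurrence", "second_primary", "death")
CENSORED = "censored"

_Z95 = float(norm.ppf(0.975))


@dataclass
class CIFEstimate:
    """Step-function CIF estimates for all causes from one risk set.

    Arrays are aligned on the distinct event times (days since diagnosis).
    ``surv`` is the overall event-free survival S(t_j); ``cif``, ``var``,
    ``ci_low`` and ``ci_high`` map each cause to its per-step values.
    """

    times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    cif: dict[str, np.ndarray]
    var: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    n_subjects: int
    max_follow_up: float

    def step_index(self, t_days: float) -> int:
        """Index of the last step time <= t_days (right-continuous), -1 if none."""
        return int(np.searchsorted(self.times, t_days, side="right")) - 1

    def survival_at(self, t_days: float) -> float:
        j = self.step_index(t_days)
        return 1.0 if j < 0 else float(self.surv[j])


class CIFPoint(NamedTuple):
    point: float
    ci_low: float
    ci_high: float
    beyond_follow_up: bool = False


def _log_log_ci(f: float, v: float) -> tuple[float, float]:
    """95 % CI for a CIF value via the log(-log) transform."""
    if f <= 0.0 or f >= 1.0 or v <= 0.0:
        return f, f
    se = math.sqrt(v) / abs(f * math.log(f))
    g = math.log(-math.log(f))
    lo = math.exp(-math.exp(g + _Z95 * se))
    hi = math.exp(-math.exp(g - _Z95 * se))
    return max(0.0, min(lo, hi)), min(1.0, max(lo, hi))


def aalen_johansen(
    time_days,
    cause,
    entry_days=None,
    causes: tuple[str, ...] = CAUSES,
) -> CIFEstimate:
    """Aalen-Johansen CIF estimate for every cause in ``causes``.

    Parameters
    ----------
    time_days : array-like of nonnegative numbers
        Follow-up time from diagnosis to the first event or censoring.
    cause : array-like of str
        Cause label per subject; ``"censored"`` for censoring.
    entry_days : array-like, optional
        Delayed-entry times (left truncation); subjects are at risk on
        (entry, time].  Default: everyone enters at 0.
    """
    times = np.asarray(time_days, dtype=float)
    labels = np.asarray(cause, dtype=object)
    if times.size == 0:
        raise ValueError("need at least one timeline")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    entries = (
        np.zeros_like(times) if entry_days is None else np.asarray(entry_days, dtype=float)
    )
    if np.any(entries > times):
        raise ValueError("entry_days must not exceed time_days")
    unknown = set(labels) - set(causes) - {CENSORED}
    if unknown:
        raise ValueError(f"unknown cause labels: {sorted(unknown)}")

    is_event = labels != CENSORED
    if not is_event.any() and np.all(times == 0):
        raise ValueError("all timelines censored at time 0")

    event_times = np.unique(times[is_event])
    n = times.size
    if event_times.size == 0:
        empty = np.array([], dtype=float)
        return CIFEstimate(
            times=empty,
            surv=empty,
            n_risk=empty,
            cif={k: empty.copy() for k in causes},
            var={k: empty.copy() for k in causes},
            ci_low={k: empty.copy() for k in causes},
            ci_high={k: empty.copy() for k in causes},
            n_subjects=n,
            max_follow_up=float(times.max()),
        )
    sorted_times = np.sort(times)
    sorted_entries = np.sort(entries)

    # risk set size just before t: #{entry < t} - #{time < t}
    n_risk = (
        np.searchsorted(sorted_entries, event_times, side="left")
        - np.searchsorted(sorted_times, event_times, side="left")
    ).astype(float)

    d_total = np.zeros(event_times.size)
    d_by_cause = {k: np.zeros(event_times.size) for k in causes}
    idx = np.searchsorted(event_times, times)
    for i in range(n):
        if is_event[i]:
            j = idx[i]
            d_total[j] += 1.0
            d_by_cause[labels[i]][j] += 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, d_total / n_risk, 0.0)
    surv = np.cumprod(1.0 - frac)
    surv_prev = np.concatenate([[1.0], surv[:-1]])

    cif: dict[str, np.ndarray] = {}
    var: dict[str, np.ndarray] = {}
    ci_low: dict[str, np.ndarray] = {}
    ci_high: dict[str, np.ndarray] = {}

    # Aalen-type variance, computed in O(J) per cause via cumulative sums:
    # Var[F_k(t)] = sum_{j<=t} (F_k(t)-F_k(t_j))^2 d_j / (n_j (n_j - d_j))
    #             + sum_{j<=t} S(t_{j-1})^2 (n_j - d_kj) d_kj / n_j^3
    #             - 2 sum_{j<=t} (F_k(t)-F_k(t_j)) S(t_{j-1}) d_kj / n_j^2
    safe_n = np.where(n_risk > 0, n_risk, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(
            (n_risk > 0) & (n_risk > d_total),
            d_total / (safe_n * np.maximum(safe_n - d_total, 1.0)),
            0.0,
        )
    for k in causes:
        dk = d_by_cause[k]
        fk = np.cumsum(surv_prev * np.where(n_risk > 0, dk / safe_n, 0.0))
        term2 = surv_prev**2 * (safe_n - dk) * dk / safe_n**3
        c = surv_prev * dk / safe_n**2
        cum_a = np.cumsum(a)
        cum_fa = np.cumsum(fk * a)
        cum_f2a = np.cumsum(fk**2 * a)
        cum_t2 = np.cumsum(term2)
        cum_c = np.cumsum(c)
        cum_fc = np.cumsum(fk * c)
        vk = (
            fk**2 * cum_a
            - 2.0 * fk * cum_fa
            + cum_f2a
            + cum_t2
            - 2.0 * fk * cum_c
            + 2.0 * cum_fc
        )
        vk = np.maximum(vk, 0.0)
        cif[k] = fk
        var[k] = vk
        lo = np.empty_like(fk)
        hi = np.empty_like(fk)
        for j in range(fk.size):
            lo[j], hi[j] = _log_log_ci(float(fk[j]), float(vk[j]))
        ci_low[k] = lo
        ci_high[k] = hi

    return CIFEstimate(
        times=event_times,
        surv=surv,
        n_risk=n_risk,
        cif=cif,
        var=var,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=n,
        max_follow_up=float(times.max()),
    )


def cif_at(estimate: CIFEstimate, cause: str, t_years: float) -> CIFPoint:
    """Right-continuous CIF lookup at ``t_years`` (point, 95 % CI).

    Beyond the last observed follow-up the last value is returned with the
    ``beyond_follow_up`` flag set.
    """
    if t_years < 0:
        raise ValueError("t must be nonnegative")
    t_days = t_years * DAYS_PER_YEAR
    j = estimate.step_index(t_days)
    beyond = t_days > estimate.max_follow_up
    if j < 0:
        return CIFPoint(0.0, 0.0, 0.0, beyond)
    return CIFPoint(
        float(estimate.cif[cause][j]),
        float(estimate.ci_low[cause][j]),
        float(estimate.ci_high[cause][j]),
        beyond,
    )


def crude_rate(n_events: int, person_years: float) -> float:
    """Crude incidence rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * n_events / person_years


def conditional_cif(
    estimate: CIFEstimate, cause: str, t1_years: float, t2_years: float
) -> float:
    """P(cause event in (t1, t2] | event-free at t1).

    Computed as (F_k(t2) - F_k(t1)) / S(t1); returns NaN (undefined) when
    no one is event-free at t1.
    """
    if t1_years >= t2_years:
        raise ValueError("require t1 < t2")
    s1 = estimate.survival_at(t1_years * DAYS_PER_YEAR)
    if s1 <= 0.0:
        logger.warning("conditional CIF undefined: event-free survival is 0 at t1")
        return math.nan
    f1 = cif_at(estimate, cause, t1_years).point
    f2 = cif_at(estimate, cause, t2_years).point
    return (f2 - f1) / s1


def build_timelines(
    outcomes: pd.DataFrame,
    cohort: Optional[pd.DataFrame] = None,
    left_truncation: bool = False,
    sensitivity_12m: bool = False,
) -> pd.DataFrame:
    """Assemble the per-patient event timelines used by the estimator.

    Maps outcome categories to analysis causes (emigration and
    administrative censoring become ``censored``), attaches stratum labels
    from the cohort table when given, and sets delayed-entry times to each
    woman's surveillance-start offset when ``left_truncation`` is enabled
    (default: everyone enters at diagnosis, time origin of all causes).
    """
    from .ascertain import months_to_days, surveillance_start

    tl = outcomes[["patient_id", "time_days", "event"]].copy()
    tl["cause"] = tl["event"].map(
        lambda e: CENSORED if e in ("emigration", "admin_censor") else e
    )
    tl["entry_days"] = 0.0
    if cohort is not None:
        strata = cohort[
            ["patient_id"]
            + [c for c in ("period", "age_group", "subtype", "stage", "her2_status") if c in cohort.columns]
        ]
        tl = tl.merge(strata, on="patient_id", how="left", validate="one_to_one")
    if left_truncation:
        if "her2_status" not in tl.columns:
            raise ValueError("left truncation requires her2_status from the cohort table")
        tl["entry_days"] = [
            float(min(months_to_days(surveillance_start(h, sensitivity_12m)), t))
            for h, t in zip(tl["her2_status"], tl["time_days"])
        ]
    return tl


def stratified_cif(
    timelines: pd.DataFrame, stratum: str, causes: tuple[str, ...] = CAUSES
) -> dict[str, CIFEstimate]:
    """Independent Aalen-Johansen estimates per level of ``stratum``.

    Rows with a missing or unclassifiable stratum label are excluded from
    this stratification only; empty strata are omitted with a warning.
    """
    if stratum not in timelines.columns:
        raise ValueError(f"stratum column {stratum!r} not present")
    out: dict[str, CIFEstimate] = {}
    usable = timelines[
        timelines[stratum].notna() & (timelines[stratum] != "") & (timelines[stratum] != "not_available")
    ]
    for label, group in usable.groupby(stratum, sort=True):
        if group.empty:
            logger.warning("stratum %s=%s is empty; omitted", stratum, label)
            continue
        out[str(label)] = aalen_johansen(
            group["time_days"], group["cause"], group["entry_days"], causes
        )
    return out


def person_years(outcomes: pd.DataFrame) -> float:
    """Total follow-up from diagnosis to each woman's outcome, in years."""
    return float(outcomes["time_days"].sum()) / DAYS_PER_YEAR
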