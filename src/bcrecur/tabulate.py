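"""Follow-up status tabulation.

Classifies every woman into one of six mutually exclusive states at a fixed
horizon (default 10 years since diagnosis): the pathway is her first event
before the horizon (recurrence, second primary tumour, or none), split by
vital status at the horizon.  Events and deaths on/after the horizon are
ignored — a woman dying in year 11 counts as alive at 10 years.  Deaths
without any preceding disease-free recurrence (including early progression)
fall under "dead without recurrence".
"""

from __future__ import annotations

import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .competing import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

STATES = (
    "alive_event_free",
    "alive_after_recurrence",
    "alive_after_second_tumour",
    "dead_without_recurrence",
    "dead_after_recurrence",
    "dead_after_second_tumour",
)

HORIZON_10Y_DAYS = 10 * DAYS_PER_YEAR  # 3652.5; events strictly before count


def round1(x: float) -> float:
    """Round half-up to one decimal (3.65 -> 3.7), matching table precision."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def share(numerator: int, denominator: int) -> float:
    """Percentage share of a count, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round1(100.0 * numerator / denominator)


def status_at(
    event: str,
    time_days: float,
    death_time_days: Optional[float],
    horizon_days: float = HORIZON_10Y_DAYS,
) -> str:
    """Six-state follow-up status at an arbitrary horizon.

    ``event``/``time_days`` describe the woman's resolved first event;
    ``death_time_days`` her death time from diagnosis if she ever died
    (from the registry, regardless of the first-event type).
    """
    dead = death_time_days is not None and not (
        isinstance(death_time_days, float) and math.isnan(death_time_days)
    ) and death_time_days < horizon_days
    pathway = event if (event in ("recurrence", "second_primary") and time_days < horizon_days) else None
    if pathway == "recurrence":
        return "dead_after_recurrence" if dead else "alive_after_recurrence"
    if pathway == "second_primary":
        return "dead_after_second_tumour" if dead else "alive_after_second_tumour"
    return "dead_without_recurrence" if dead else "alive_event_free"


def status_at_10y(
    event: str,
    time_days: float,
    vital_at_10y: bool,
    death_time_days: Optional[float] = None,
) -> str:
    """Status at the 10-year horizon given vital status at that horizon.

    Rejects the inconsistent combination dead-at-10-years without a death
    time.
    """
    if not vital_at_10y and death_time_days is None:
        raise ValueError("dead at 10 years but no death_time_days given")
    death = death_time_days if not vital_at_10y else None
    return status_at(event, time_days, death, HORIZON_10Y_DAYS)


def classify_cohort(
    outcomes: pd.DataFrame,
    death_time_days: pd.Series,
    horizon_days: float = HORIZON_10Y_DAYS,
) -> pd.Series:
    """Vector of six-state statuses, indexed like ``outcomes``.

    ``death_time_days`` must align with ``outcomes`` on patient_id order
    (NaN = never died during follow-up).
    """
    return pd.Series(
        [
            status_at(e, t, None if pd.isna(d) else float(d), horizon_days)
            for e, t, d in zip(outcomes["event"], outcomes["time_days"], death_time_days)
        ],
        index=outcomes.index,
        name="status",
    )


def tabulate_status(
    cohort: pd.DataFrame,
    statuses: pd.Series,
    strata: tuple[str, ...] = ("age_group", "stage", "subtype"),
) -> pd.DataFrame:
    """Stratified counts and percentages of the six follow-up states.

    One row per (stratum variable, stratum level, state); percentages use
    the stratum size as denominator and are rounded half-up to one decimal.
    Includes an ``all`` stratum for the whole cohort.  Empty strata are
    omitted with a warning.
    """
    if len(statuses) != len(cohort):
        raise ValueError("one status per cohort member required")
    frame = cohort.copy()
    frame = frame.assign(status=statuses.to_numpy())
    rows = []

    def _emit(var: str, level: str, group: pd.DataFrame) -> None:
        n = len(group)
        if n == 0:
            logger.warning("stratum %s=%s is empty; omitted", var, level)
            return
        counts = group["status"].value_counts()
        for state in STATES:
            c = int(counts.get(state, 0))
            rows.append(
                {
                    "stratum_var": var,
                    "stratum": level,
                    "state": state,
                    "count": c,
                    "percent": share(c, n),
                }
            )

    _emit("all", "all", frame)
    for var in strata:
        if var not in frame.columns:
            raise ValueError(f"stratum column {var!r} not present")
        for level in sorted(frame[var].dropna().unique()):
            _emit(var, str(level), frame[frame[var] == level])
    return pd.DataFrame(rows, columns=["stratum_var", "stratum", "state", "count", "percent"])


def conditional_alive_with_recurrence(
    outcomes: pd.DataFrame,
    death_time_days: pd.Series,
    t0_years: float,
    t1_years: float,
) -> float:
    """P(alive with a prior recurrence at t1 | alive with recurrence at t0).

    Counts women whose status is ``alive_after_recurrence`` at both horizons
    over those with that status at t0; NaN (flagged undefined) when the
    denominator is zero.
    """
    if t0_years >= t1_years:
        raise ValueError("require t0 < t1")
    s0 = classify_cohort(outcomes, death_time_days, t0_years * DAYS_PER_YEAR)
    s1 = classify_cohort(outcomes, death_time_days, t1_years * DAYS_PER_YEAR)
    at_t0 = s0 == "alive_after_recurrence"
    denom = int(at_t0.sum())
    if denom == 0:
        logger.warning("conditional alive-with-recurrence undefined: empty denominator")
        return math.nan
    num = int((at_t0 & (s1 == "alive_after_recurrence")).sum())
    return num / denom
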