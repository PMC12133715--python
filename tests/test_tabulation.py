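"""Six-state follow-up status classification and stratified tables."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from bcrecur import (
    STATES,
    SimulationConfig,
    classify_cohort,
    conditional_alive_with_recurrence,
    share,
    simulate_cohort,
    status_at,
    status_at_10y,
    tabulate_status,
)
from bcrecur.tabulate import HORIZON_10Y_DAYS, round1

Y = 365.25


class TestStatusAt10y:
    @pytest.mark.parametrize(
        "event, time_y, death_y, expected",
        [
            ("admin_censor", 15.0, None, "alive_event_free"),
            ("recurrence", 3.0, 8.0, "dead_after_recurrence"),
            ("recurrence", 3.0, 11.0, "alive_after_recurrence"),  # death past horizon
            ("recurrence", 11.0, None, "alive_event_free"),  # event past horizon
            ("second_primary", 4.0, None, "alive_after_second_tumour"),
            ("second_primary", 4.0, 9.0, "dead_after_second_tumour"),
            ("death", 2.0, 2.0, "dead_without_recurrence"),
            ("emigration", 6.0, None, "alive_event_free"),
        ],
    )
    def test_pathway_times_vital_status(self, event, time_y, death_y, expected):
        death = None if death_y is None else death_y * Y
        assert status_at(event, time_y * Y, death) == expected

    def test_wrapper_rejects_dead_without_death_time(self):
        with pytest.raises(ValueError):
            status_at_10y("recurrence", 3 * Y, vital_at_10y=False, death_time_days=None)

    def test_wrapper_matches_direct_classification(self):
        assert status_at_10y("recurrence", 3 * Y, False, 8 * Y) == "dead_after_recurrence"
        assert status_at_10y("recurrence", 3 * Y, True, 11 * Y) == "alive_after_recurrence"

    def test_horizon_boundary_strict(self):
        assert status_at("recurrence", HORIZON_10Y_DAYS, None) == "alive_event_free"
        assert status_at("recurrence", HORIZON_10Y_DAYS - 1, None) == "alive_after_recurrence"


class TestTabulateStatus:
    def _frame(self, statuses, stage="I"):
        n = len(statuses)
        cohort = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "age_group": ["40-49"] * n,
                "stage": [stage] * n,
                "subtype": ["TN"] * n,
            }
        )
        return cohort, pd.Series(statuses)

    def test_six_canonical_patients(self):
        cohort, statuses = self._frame(list(STATES))
        table = tabulate_status(cohort, statuses)
        all_rows = table[table["stratum_var"] == "all"]
        assert (all_rows["count"] == 1).all()
        assert (all_rows["percent"] == 16.7).all()

    def test_printed_stratum_percentages(self):
        counts = dict(zip(STATES, [176, 86, 8, 8, 43, 0]))
        statuses = [s for s, c in counts.items() for _ in range(c)]
        cohort, statuses = self._frame(statuses)
        table = tabulate_status(cohort, statuses)
        row = table[(table["stratum_var"] == "age_group")].set_index("state")
        assert row.loc[list(STATES), "percent"].tolist() == [54.8, 26.8, 2.5, 2.5, 13.4, 0.0]
        assert int(row["count"].sum()) == 321

    def test_partition_sums_to_stratum_sizes(self):
        rng = np.random.default_rng(1)
        n = 200
        cohort = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "age_group": rng.choice(["20-39", "40-49"], size=n),
                "stage": rng.choice(["I", "II", "III"], size=n),
                "subtype": rng.choice(["HR+/HER2-", "TN"], size=n),
            }
        )
        statuses = pd.Series(rng.choice(STATES, size=n))
        table = tabulate_status(cohort, statuses)
        for var in ("all", "age_group", "stage", "subtype"):
            sums = table[table["stratum_var"] == var].groupby("stratum")["count"].sum()
            for level, total in sums.items():
                expected = n if var == "all" else (cohort[var] == level).sum()
                assert total == expected

    def test_status_count_mismatch_rejected(self):
        cohort, statuses = self._frame(list(STATES))
        with pytest.raises(ValueError):
            tabulate_status(cohort, statuses.iloc[:-1])


class TestRounding:
    def test_round_half_up_one_decimal(self):
        assert round1(12.35) == 12.4
        assert round1(2.25) == 2.3
        assert round1(2.24) == 2.2

    def test_share_of_printed_integers(self):
        assert share(2971, 5825) == 51.0
        assert share(176, 321) == 54.8
        with pytest.raises(ValueError):
            share(1, 0)


class TestConditionalAliveWithRecurrence:
    def _outcomes(self, rows):
        outcomes = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(rows))],
                "event": [r[0] for r in rows],
                "time_days": [r[1] * Y for r in rows],
            }
        )
        deaths = pd.Series([np.nan if r[2] is None else r[2] * Y for r in rows])
        return outcomes, deaths

    def test_everyone_survives_gives_one(self):
        outcomes, deaths = self._outcomes([("recurrence", 2.0, None)] * 5)
        assert conditional_alive_with_recurrence(outcomes, deaths, 5.0, 10.0) == 1.0

    def test_empty_denominator_undefined(self):
        outcomes, deaths = self._outcomes([("admin_censor", 12.0, None)] * 3)
        assert math.isnan(conditional_alive_with_recurrence(outcomes, deaths, 5.0, 10.0))

    def test_direct_counting(self):
        rows = [("recurrence", 2.0, None)] * 6 + [("recurrence", 2.0, 7.5)] * 4
        outcomes, deaths = self._outcomes(rows)
        assert conditional_alive_with_recurrence(outcomes, deaths, 5.0, 10.0) == 0.6

    def test_rejects_bad_interval(self):
        outcomes, deaths = self._outcomes([("recurrence", 2.0, None)])
        with pytest.raises(ValueError):
            conditional_alive_with_recurrence(outcomes, deaths, 10.0, 5.0)


@pytest.fixture(scope="module")
def run():
    from bcrecur import CodeSet, ascertain_cohort

    cfg = SimulationConfig(n_patients=800, seed=21, emigration_hazard=0.0)
    registry, hdd, ops, truth = simulate_cohort(cfg)
    outcomes = ascertain_cohort(registry, hdd, ops, CodeSet(), cfg.admin_cutoff)
    deaths = pd.Series(
        [
            (pd.Timestamp(d) - pd.Timestamp(g)).days if d else np.nan
            for d, g in zip(registry["death_date"], registry["diagnosis_date"])
        ]
    )
    return registry, outcomes, deaths


class TestSyntheticConsistency:
    def test_partition_over_cohort(self, run):
        registry, outcomes, deaths = run
        statuses = classify_cohort(outcomes, deaths)
        assert statuses.isin(STATES).all()
        assert len(statuses) == len(registry)

    def test_recurrence_pathway_counts_match_ascertainment(self, run):
        # with no emigration, women alive or dead after recurrence at 10y are
        # exactly those with an ascertained recurrence before the horizon
        _, outcomes, deaths = run
        statuses = classify_cohort(outcomes, deaths)
        n_pathway = statuses.isin(["alive_after_recurrence", "dead_after_recurrence"]).sum()
        n_recurrences = (
            (outcomes["event"] == "recurrence") & (outcomes["time_days"] < HORIZON_10Y_DAYS)
        ).sum()
        assert n_pathway == n_recurrences

    def test_horizon_monotonicity_of_alive_counts(self, run):
        _, outcomes, deaths = run
        alive_states = ("alive_event_free", "alive_after_recurrence", "alive_after_second_tumour")
        at_10y = classify_cohort(outcomes, deaths).isin(alive_states).sum()
        at_end = classify_cohort(outcomes, deaths, horizon_days=30 * Y).isin(alive_states).sum()
        assert at_10y >= at_end
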