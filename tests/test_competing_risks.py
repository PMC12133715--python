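"""Aalen-Johansen estimator: hand oracles, invariants, library cross-check."""

from __future__ import annotations

import math

import numpy as np
import pytest

import _oracles
from bcrecur import (
    aalen_johansen,
    cif_at,
    conditional_cif,
    crude_rate,
    stratified_cif,
)

TOL = 1e-10


class TestFourPatientHandOracle:
    """n=4: recurrence day 365, death day 730, censored day 1095, recurrence day 1460."""

    def test_recurrence_cif_steps(self, four_patient_estimate):
        est = four_patient_estimate
        np.testing.assert_allclose(est.cif["recurrence"], [0.25, 0.25, 0.75], atol=TOL)

    def test_death_cif_step(self, four_patient_estimate):
        np.testing.assert_allclose(
            four_patient_estimate.cif["death"], [0.0, 0.25, 0.25], atol=TOL
        )

    def test_survival_hits_zero(self, four_patient_estimate):
        np.testing.assert_allclose(four_patient_estimate.surv, [0.75, 0.5, 0.0], atol=TOL)

    def test_lookup_at_3_years(self, four_patient_estimate):
        point = cif_at(four_patient_estimate, "recurrence", 3.0)
        assert point.point == pytest.approx(0.25, abs=TOL)

    def test_conditional_probability_3y_to_5y(self, four_patient_estimate):
        got = conditional_cif(four_patient_estimate, "recurrence", 3.0, 5.0)
        assert got == pytest.approx((0.75 - 0.25) / 0.5, abs=TOL)


class TestStepLookup:
    def test_before_first_event_is_zero(self, four_patient_estimate):
        assert cif_at(four_patient_estimate, "recurrence", 0.5).point == 0.0

    def test_right_continuous_at_step(self, four_patient_estimate):
        at_step = cif_at(four_patient_estimate, "recurrence", 365 / 365.25)
        assert at_step.point == pytest.approx(0.25, abs=TOL)

    def test_beyond_follow_up_flagged(self, four_patient_estimate):
        point = cif_at(four_patient_estimate, "recurrence", 50.0)
        assert point.beyond_follow_up
        assert point.point == pytest.approx(0.75, abs=TOL)


class TestReductions:
    def test_single_cause_no_censoring_reduces_to_ecdf(self, rng):
        times = rng.integers(1, 50, size=40)
        est = aalen_johansen(times, ["death"] * 40)
        for t in np.unique(times):
            ecdf = (times <= t).mean()
            j = est.step_index(t)
            assert est.cif["death"][j] == pytest.approx(ecdf, abs=TOL)

    def test_single_cause_cif_is_one_minus_km(self, rng):
        times = rng.integers(1, 30, size=30)
        causes = ["recurrence" if x else "censored" for x in rng.integers(0, 2, size=30)]
        if "recurrence" not in causes:
            causes[0] = "recurrence"
        est = aalen_johansen(times, causes)
        np.testing.assert_allclose(est.cif["recurrence"], 1.0 - est.surv, atol=TOL)

    def test_absent_cause_is_zero_with_zero_variance(self):
        est = aalen_johansen([5, 8, 12], ["death", "censored", "death"])
        assert np.all(est.cif["recurrence"] == 0.0)
        assert np.all(est.var["recurrence"] == 0.0)

    def test_all_censored_at_zero_rejected(self):
        with pytest.raises(ValueError):
            aalen_johansen([0, 0], ["censored", "censored"])


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("with_entries", [False, True])
    def test_matches_fraction_oracle_on_small_datasets(self, with_entries):
        rng = np.random.default_rng(4242)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            times, causes, entries = _oracles.random_competing_dataset(rng, n, with_entries)
            if all(c == "censored" for c in causes):
                continue
            expected_times, surv, cif = _oracles.aj_bruteforce(times, causes, entries)
            est = aalen_johansen(times, causes, entries)
            np.testing.assert_allclose(est.times, expected_times)
            np.testing.assert_allclose(est.surv, [float(s) for s in surv], atol=TOL)
            for k in _oracles.CAUSES:
                np.testing.assert_allclose(est.cif[k], [float(f) for f in cif[k]], atol=TOL)

    def test_delayed_entry_hand_example(self):
        # entry 5 keeps the second subject out of the day-10 risk set? No:
        # risk set at t is {entry < t <= time}, so at t=10 both are at risk.
        est = aalen_johansen([10, 12], ["recurrence", "death"], entry_days=[0, 5])
        np.testing.assert_allclose(est.cif["recurrence"], [0.5, 0.5], atol=TOL)
        np.testing.assert_allclose(est.cif["death"], [0.0, 0.5], atol=TOL)
        # entering exactly at the event time does not put you at risk
        est2 = aalen_johansen([10, 12], ["recurrence", "death"], entry_days=[0, 10])
        np.testing.assert_allclose(est2.cif["recurrence"], [1.0, 1.0], atol=TOL)


class TestInvariants:
    def test_additivity_and_monotonicity_random(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            times, causes, _ = _oracles.random_competing_dataset(rng, n)
            if all(c == "censored" for c in causes):
                continue
            est = aalen_johansen(times, causes)
            total = sum(est.cif[k] for k in _oracles.CAUSES)
            np.testing.assert_allclose(total + est.surv, 1.0, atol=TOL)
            for k in _oracles.CAUSES:
                assert np.all(np.diff(est.cif[k]) >= -TOL)
                assert np.all((est.cif[k] >= -TOL) & (est.cif[k] <= 1 + TOL))
                assert np.all(est.ci_low[k] <= est.cif[k] + TOL)
                assert np.all(est.ci_high[k] >= est.cif[k] - TOL)
                assert np.all((est.ci_low[k] >= 0) & (est.ci_high[k] <= 1))
                assert np.all(est.var[k] >= 0)

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)

        def var10y(n):
            t = rng.exponential(8.0, size=n)
            c = np.where(rng.random(n) < 0.5, "recurrence", "death")
            est = aalen_johansen(t, c)
            j = est.step_index(10.0)
            return est.var["recurrence"][j]

        assert var10y(4000) < var10y(100)


class TestLifelinesCrossCheck:
    def test_cif_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        # continuous times: lifelines randomly jitters ties, which would
        # break an exact comparison
        rng = np.random.default_rng(7)
        n = 200
        times = rng.exponential(10.0, size=n)
        codes = rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3])
        labels = np.array(["censored", "recurrence", "death"])[codes]
        est = aalen_johansen(times, labels)
        fitter = lifelines.AalenJohansenFitter(calculate_variance=False)
        fitter.fit(times, codes, event_of_interest=1)
        cif_ll = fitter.cumulative_density_.iloc[:, 0]
        for j, t in enumerate(est.times):
            assert est.cif["recurrence"][j] == pytest.approx(
                float(cif_ll.loc[:t].iloc[-1]), abs=1e-8
            )


class TestRatesAndConditionals:
    def test_crude_rate_arithmetic(self):
        assert crude_rate(10, 5000.0) == pytest.approx(2.0)
        assert crude_rate(0, 100.0) == 0.0
        # cohort-scale worked example: 1522 events over 63,562 person-years
        assert crude_rate(1522, 63562.0) == pytest.approx(23.9, abs=0.05)

    def test_crude_rate_requires_positive_person_years(self):
        with pytest.raises(ValueError):
            crude_rate(1, 0.0)

    def test_conditional_from_zero_equals_cif(self, four_patient_estimate):
        got = conditional_cif(four_patient_estimate, "recurrence", 0.0, 4.0)
        assert got == pytest.approx(cif_at(four_patient_estimate, "recurrence", 4.0).point)

    def test_conditional_no_events_in_window_is_zero(self, four_patient_estimate):
        assert conditional_cif(four_patient_estimate, "death", 2.5, 2.9) == pytest.approx(0.0)

    def test_conditional_rejects_bad_interval(self, four_patient_estimate):
        with pytest.raises(ValueError):
            conditional_cif(four_patient_estimate, "recurrence", 5.0, 3.0)

    def test_conditional_undefined_when_no_survivors(self, four_patient_estimate):
        # survival hits 0 at day 1460 (4.0y); conditioning beyond is undefined
        assert math.isnan(conditional_cif(four_patient_estimate, "recurrence", 4.5, 6.0))


class TestStratified:
    def test_per_stratum_estimates_match_subsets(self, rng):
        import pandas as pd

        n = 120
        times, causes, entries = _oracles.random_competing_dataset(rng, n)
        frame = pd.DataFrame(
            {
                "time_days": times,
                "cause": causes,
                "entry_days": entries,
                "stage": rng.choice(["I", "II", "III"], size=n),
            }
        )
        out = stratified_cif(frame, "stage")
        assert set(out) == {"I", "II", "III"}
        sub = frame[frame["stage"] == "II"]
        direct = aalen_johansen(sub["time_days"], sub["cause"], sub["entry_days"])
        np.testing.assert_allclose(out["II"].cif["recurrence"], direct.cif["recurrence"])

    def test_unclassifiable_rows_excluded(self, rng):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "time_days": [5.0, 6.0, 7.0],
                "cause": ["recurrence", "death", "recurrence"],
                "entry_days": [0.0, 0.0, 0.0],
                "subtype": ["TN", "not_available", "TN"],
            }
        )
        out = stratified_cif(frame, "subtype")
        assert set(out) == {"TN"}
        assert out["TN"].n_subjects == 2
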