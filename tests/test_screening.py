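"""Screening schedules, attendance, test outcomes, and counterfactual
lead-time/overdetection accounting."""

import dataclasses

import numpy as np
import pytest

from bcmicrosim import Scenario, rng_stream
from bcmicrosim.natural_history import NaturalHistory, simulate_natural_history
from bcmicrosim.population import sample_individual
from bcmicrosim.screening import (
    ScreeningStrategy,
    account_screen_detection,
    attend,
    build_schedule,
    calibrate_rescreening,
    run_screening,
)

from test_natural_history import make_individual, make_tumour


def annual_40_49(**kw):
    defaults = dict(start_age=40.0, end_age=49.0, interval=1.0)
    defaults.update(kw)
    return ScreeningStrategy(**defaults)


class TestSchedule:
    def test_annual_40_49_gives_ten_invitations(self):
        ind = make_individual()
        ages = build_schedule(annual_40_49(), ind)
        np.testing.assert_allclose(ages, np.arange(40.0, 50.0))

    def test_invitations_stop_at_death(self):
        ind = make_individual(other_cause_death_age=45.0)
        ages = build_schedule(annual_40_49(), ind)
        assert ages.max() < 45.0 and len(ages) == 5

    def test_biennial_50_69_gives_ten_invitations(self):
        s = ScreeningStrategy(start_age=50, end_age=69, interval=2)
        assert len(build_schedule(s, make_individual())) == 10

    def test_program_calendar_window_intersects(self):
        s = annual_40_49(program_year_lo=1995, program_year_hi=1997)
        ind = make_individual(birth_year=1950)
        ages = build_schedule(s, ind)  # ages 45, 46, 47 only
        np.testing.assert_allclose(ages, [45.0, 46.0, 47.0])

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            ScreeningStrategy(start_age=50, end_age=40)
        with pytest.raises(ValueError):
            ScreeningStrategy(start_age=40, end_age=50, interval=0)


class TestAttendance:
    def test_full_participation_attends_all(self, params):
        s = annual_40_49(participation=1.0, retention=1.0)
        ind = make_individual()
        nh = NaturalHistory(tumours=[])
        records, _ = run_screening(params, s, nh, ind, np.random.default_rng(0))
        assert all(r.attended for r in records) and len(records) == 10

    def test_zero_participation_attends_none(self, params):
        s = annual_40_49(participation=0.0, reentry=0.0)
        records, _ = run_screening(
            params, s, NaturalHistory(tumours=[]), make_individual(), np.random.default_rng(0)
        )
        assert not any(r.attended for r in records)

    def test_attendance_follows_markov_chain(self, params):
        """Attendance fractions per invitation match the two-state chain
        (participation at first; retention after attending; re-entry after
        missing)."""
        s = annual_40_49(participation=0.8, retention=0.9, reentry=0.3)
        ind = make_individual()
        nh = NaturalHistory(tumours=[])
        n = 20_000
        attended = np.zeros(10)
        rng = np.random.default_rng(1)
        for _ in range(n):
            records, _ = run_screening(params, s, nh, ind, rng)
            attended += [r.attended for r in records]
        # oracle: exact chain marginals
        probs = np.zeros(10)
        probs[0] = 0.8
        for j in range(1, 10):
            probs[j] = probs[j - 1] * 0.9 + (1 - probs[j - 1]) * 0.3
        f = attended / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(f - probs) < 3 * se + 1e-9)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            attend(annual_40_49(), "sometimes", 0.5)


class TestScreenResult:
    def test_perfect_sensitivity_detects_tumour(self, params):
        sens = params.sensitivity.copy()
        sens["sensitivity"] = 1.0
        p = dataclasses.replace(params, sensitivity=sens)
        s = annual_40_49(participation=1.0, retention=1.0)
        t = make_tumour(onset_age=41.5)
        nh = NaturalHistory(tumours=[t], counterfactual_clinical_detection_age=70.0)
        records, sd = run_screening(p, s, nh, make_individual(), np.random.default_rng(0))
        assert sd is not None and sd.age == 42.0
        assert records[-1].result == "TP"

    def test_zero_sensitivity_never_detects(self, params):
        s = annual_40_49(participation=1.0, retention=1.0, sensitivity_multiplier=0.0)
        t = make_tumour(onset_age=41.5)
        nh = NaturalHistory(tumours=[t], counterfactual_clinical_detection_age=70.0)
        records, sd = run_screening(params, s, nh, make_individual(), np.random.default_rng(0))
        assert sd is None
        # once the tumour is present, every attended screen misses it
        assert all(r.result == "FN" for r in records if r.attended and r.age >= 41.5)

    def test_false_positive_rate_matches_specificity(self, params):
        """Tumour-free women recall with probability 1 - specificity."""
        spec = params.specificity.copy()
        spec["specificity"] = 0.95
        p = dataclasses.replace(params, specificity=spec)
        s = annual_40_49(participation=1.0, retention=1.0)
        nh = NaturalHistory(tumours=[])
        ind = make_individual()
        rng = np.random.default_rng(2)
        n = 20_000
        fp = total = 0
        for _ in range(n // 10):
            records, _ = run_screening(p, s, nh, ind, rng)
            fp += sum(1 for r in records if r.result == "FP")
            total += sum(1 for r in records if r.attended)
        f = fp / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(f - 0.05) < 3 * se

    def test_tp_exits_schedule_fp_does_not(self, params):
        sens = params.sensitivity.copy()
        sens["sensitivity"] = 1.0
        p = dataclasses.replace(params, sensitivity=sens)
        s = annual_40_49(participation=1.0, retention=1.0)
        t = make_tumour(onset_age=44.5)
        nh = NaturalHistory(tumours=[t], counterfactual_clinical_detection_age=70.0)
        records, sd = run_screening(p, s, nh, make_individual(), np.random.default_rng(0))
        assert records[-1].result == "TP"
        assert records[-1].age == sd.age == 45.0  # no screens after TP


class TestCounterfactualAccounting:
    def test_lead_time_is_simple_subtraction(self):
        nh = NaturalHistory(tumours=[], counterfactual_clinical_detection_age=55.0)
        lead, over = account_screen_detection(nh, make_individual(), 52.0)
        assert lead == pytest.approx(3.0) and not over

    def test_counterfactual_after_death_is_overdetection(self):
        nh = NaturalHistory(tumours=[], counterfactual_clinical_detection_age=80.0)
        ind = make_individual(other_cause_death_age=75.0)
        _, over = account_screen_detection(nh, ind, 70.0)
        assert over

    def test_no_counterfactual_is_overdetection(self):
        nh = NaturalHistory(tumours=[], counterfactual_clinical_detection_age=None)
        ind = make_individual(other_cause_death_age=75.0)
        lead, over = account_screen_detection(nh, ind, 70.0)
        assert over and lead == pytest.approx(5.0)


class TestScreeningInvariants:
    def _cohort_histories(self, params, n, seed, max_age=110.0):
        cohort = Scenario(n=n, birth_year_lo=1950, birth_year_hi=1957, master_seed=seed)
        out = []
        for i in range(n):
            ind = sample_individual(params, cohort, i, rng_stream(seed, i, "population"))
            nh = simulate_natural_history(params, ind, rng_stream(seed, i, "natural_history"))
            out.append((ind, nh))
        return out

    def test_lead_time_nonnegative_and_sizes_shrink(self, params):
        """Screen detection cannot postdate the counterfactual clinical
        event, and the screen-detected size never exceeds the size the
        tumour would have at clinical detection."""
        from bcmicrosim.natural_history import diameter

        s = ScreeningStrategy(start_age=50, end_age=74, interval=2,
                              participation=1.0, retention=1.0)
        seed = 21
        checked = 0
        for i, (ind, nh) in enumerate(self._cohort_histories(params, 400, seed)):
            records, sd = run_screening(params, s, nh, ind, rng_stream(seed, i, "screening"))
            if sd is None:
                continue
            c = nh.counterfactual_clinical_detection_age
            if c is not None:
                assert sd.lead_time >= 0
                lead = nh.tumours[sd.leading_index]
                assert diameter(lead, sd.age) <= diameter(lead, min(c, 1e6)) + 1e-12
            checked += 1
        assert checked > 0

    def test_overdetection_monotone_in_sensitivity(self, params):
        """With coupled draws, raising sensitivity can only add
        screen-detections, so the overdetected count is non-decreasing."""
        seed = 22
        histories = self._cohort_histories(params, 600, seed)
        counts = []
        for mult in (0.25, 0.5, 1.0):
            s = ScreeningStrategy(start_age=60, end_age=78, interval=2,
                                  participation=1.0, retention=1.0,
                                  sensitivity_multiplier=mult)
            c = 0
            for i, (ind, nh) in enumerate(histories):
                _, sd = run_screening(params, s, nh, ind, rng_stream(seed, i, "screening"))
                if sd is not None and sd.overdetected:
                    c += 1
            counts.append(c)
        assert counts == sorted(counts)
        assert counts[-1] > 0  # elderly screening does produce overdetection


class TestCalibration:
    def _mean_at_retention(self, params, cohort, strategy, retention, seed):
        import bcmicrosim.screening as scr

        strat = dataclasses.replace(strategy, retention=retention)
        total = 0
        for i in range(cohort.n):
            ind = sample_individual(params, cohort, i, rng_stream(seed, i, "population"))
            nh = simulate_natural_history(params, ind, rng_stream(seed, i, "natural_history"))
            records, _ = scr.run_screening(params, strat, nh, ind, rng_stream(seed, i, "screening"))
            total += sum(1 for rec in records if rec.attended)
        return total / cohort.n

    def test_boundary_target_returns_retention_one(self, params, trial_cohort):
        s = annual_40_49(participation=0.9, reentry=0.3)
        m_hi = self._mean_at_retention(params, trial_cohort, s, 1.0, trial_cohort.master_seed)
        r, m = calibrate_rescreening(params, s, m_hi, trial_cohort, trial_cohort.master_seed)
        assert r == 1.0 and m == pytest.approx(m_hi)

    def test_unachievable_target_reports_bracket(self, params, trial_cohort):
        s = annual_40_49(participation=0.9, reentry=0.3)
        with pytest.raises(ValueError, match="achievable"):
            calibrate_rescreening(params, s, 25.0, trial_cohort, 1)

    def test_mean_screens_monotone_in_retention(self, params, trial_cohort):
        """Achieved mean screens per woman rises with retention."""
        import bcmicrosim.screening as scr

        s = annual_40_49(participation=0.9, reentry=0.3)
        cohort = dataclasses.replace(trial_cohort, n=800)
        histories = []
        for i in range(cohort.n):
            ind = sample_individual(params, cohort, i, rng_stream(3, i, "population"))
            nh = simulate_natural_history(params, ind, rng_stream(3, i, "natural_history"))
            histories.append((ind, nh))
        means = []
        for r in (0.0, 0.3, 0.6, 0.9):
            strat = dataclasses.replace(s, retention=r)
            total = 0
            for i, (ind, nh) in enumerate(histories):
                records, _ = scr.run_screening(params, strat, nh, ind, rng_stream(3, i, "screening"))
                total += sum(1 for rec in records if rec.attended)
            means.append(total / cohort.n)
        assert means == sorted(means) and means[0] < means[-1]
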