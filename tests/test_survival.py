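"""Onset event extraction, Kaplan-Meier estimation and threshold logic."""
import warnings

import numpy as np
import pytest

import floreyindex as fx
from floreyindex.survival import OnsetEvent, SurvivalCurve
from floreyindex.trajectory import AlignmentModel, AlignmentResult, Convergence

from conftest import km_oracle, make_series


def _ev(times, statuses, endpoint="MCI"):
    return [OnsetEvent(f"P{i}", endpoint, float(t), bool(s))
            for i, (t, s) in enumerate(zip(times, statuses))]


def _truth_alignment(sim):
    """Alignment model built from simulation ground truth (exact shifts)."""
    shifts = [
        AlignmentResult(row.participant_id, float(row.delta_true), 0.0, True, int(row.n_visits))
        for row in sim.truth.itertuples()
    ]
    return AlignmentModel(curve=sim.config.curve, shifts=shifts, ridge=0.0,
                          convergence=Convergence(1, 0.0, True))


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        curve = fx.km_estimate(_ev([77, 79, 81], [1, 1, 1]))
        assert list(curve.grid) == [77.0, 79.0, 81.0]
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_censoring_between_events(self):
        curve = fx.km_estimate(_ev([70, 72, 75], [1, 0, 1]))
        assert list(curve.grid) == [70.0, 75.0]
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0], atol=1e-12)

    def test_single_event_single_drop(self):
        curve = fx.km_estimate(_ev([70, 71, 72, 75], [0, 0, 1, 0]))
        assert len(curve.grid) == 1
        assert (np.diff(curve.survival) <= 0).all()

    def test_no_events_raises(self):
        with pytest.raises(fx.NoEventsError):
            fx.km_estimate(_ev([70, 72], [0, 0]))

    def test_no_censoring_matches_empirical_cdf(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(70, 90, 40)
        curve = fx.km_estimate(_ev(times, np.ones(40)))
        for t, s in zip(curve.grid, curve.survival):
            assert s == pytest.approx(1.0 - (times <= t).mean(), abs=1e-12)

    def test_survival_non_increasing_with_valid_ci(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(70, 90, 60)
        status = rng.random(60) < 0.6
        status[0] = True
        curve = fx.km_estimate(_ev(times, status))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.ci_lower <= curve.survival + 1e-12)
                & (curve.survival <= curve.ci_upper + 1e-12)).all()

    def test_matches_oracle_with_ties(self):
        times = [70, 70, 70, 75, 75, 80]
        status = [1, 0, 1, 1, 0, 1]
        curve = fx.km_estimate(_ev(times, status))
        t_o, s_o = km_oracle(times, status)
        np.testing.assert_allclose(curve.grid, t_o)
        np.testing.assert_allclose(curve.survival, s_o, atol=1e-12)


class TestThreshold:
    def _curve(self, grid, survival):
        g = np.asarray(grid, dtype=float)
        s = np.asarray(survival, dtype=float)
        return SurvivalCurve("MCI", g, s, s, s, np.arange(len(g), 0, -1), len(g), 0)

    def test_threshold_from_hand_computed_curve(self):
        curve = fx.km_estimate(_ev([77, 79, 81], [1, 1, 1]))
        assert fx.threshold_from_curve(curve, 0.5) == 79.0

    def test_first_crossing_wins(self):
        c = self._curve([80.0, 80.5], [0.51, 0.49])
        assert fx.threshold_from_curve(c, 0.5) == 80.5

    def test_non_crossing_raises(self):
        c = self._curve([80.0, 82.0], [0.8, 0.6])
        with pytest.raises(fx.ThresholdUndefinedError):
            fx.threshold_from_curve(c, 0.5)

    def test_threshold_non_decreasing_in_onset_probability(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(70, 95, 50)
        curve = fx.km_estimate(_ev(times, np.ones(50)))
        ps = [0.1, 0.25, 0.5, 0.75, 0.9]
        thetas = [fx.threshold_from_curve(curve, p) for p in ps]
        assert thetas == sorted(thetas)


class TestExtractOnsetEvents:
    def _one(self, diagnoses, shift=0.0, ages=(76.0, 77.5, 79.0)):
        cohort = fx.Cohort([
            make_series("A", list(ages), [0.0] * len(ages), list(diagnoses))
        ])
        am = AlignmentModel(
            curve=fx.calibrated_curve(),
            shifts=[AlignmentResult("A", shift, 0.0, True, len(ages))],
            ridge=0.0, convergence=Convergence(1, 0.0, True),
        )
        return cohort, am

    def test_event_at_first_qualifying_visit(self):
        cohort, am = self._one(["CU", "CU", "MCI"])
        events, rep = fx.extract_onset_events(cohort, am, "MCI")
        assert events[0].observed and events[0].fdi_time == 79.0
        assert rep.n_events == 1

    def test_censored_at_last_visit(self):
        cohort, am = self._one(["CU", "CU", "CU"], shift=2.0)
        events, rep = fx.extract_onset_events(cohort, am, "MCI")
        assert not events[0].observed
        assert events[0].fdi_time == 81.0

    def test_direct_converter_counts_for_both_endpoints(self):
        cohort, am = self._one(["CU", "CU", "AD"])
        mci, _ = fx.extract_onset_events(cohort, am, "MCI")
        ad, _ = fx.extract_onset_events(cohort, am, "AD")
        assert mci[0].observed and mci[0].fdi_time == 79.0
        assert ad[0].observed and ad[0].fdi_time == 79.0

    def test_direct_converter_excludable_by_config(self):
        cohort, am = self._one(["CU", "CU", "AD"])
        events, _ = fx.extract_onset_events(
            cohort, am, "MCI", count_direct_converters=False
        )
        assert not events[0].observed  # censored, never MCI-diagnosed

    def test_prevalent_case_excluded_and_counted(self):
        cohort, am = self._one(["MCI", "MCI", "AD"])
        events, rep = fx.extract_onset_events(cohort, am, "MCI")
        assert events == []
        assert rep.n_prevalent_excluded == 1

    def test_staging_fallback_used_when_diagnosis_missing(self):
        cohort = fx.Cohort([
            make_series("A", [76.0, 79.0], [0.0, 2.0])  # 2.0 stages as MCI
        ])
        am = AlignmentModel(
            curve=fx.calibrated_curve(),
            shifts=[AlignmentResult("A", 0.0, 0.0, True, 2)],
            ridge=0.0, convergence=Convergence(1, 0.0, True),
        )
        events, _ = fx.extract_onset_events(cohort, am, "MCI")
        assert events[0].observed and events[0].fdi_time == 79.0


class TestExhaustiveSmallCases:
    def test_km_matches_oracle_on_all_configurations_up_to_six(self):
        """Product-limit check over every event/censor pattern, n <= 6."""
        from itertools import product

        for n in range(1, 7):
            times = np.arange(1.0, n + 1.0)
            for statuses in product([0, 1], repeat=n):
                if sum(statuses) == 0:
                    continue
                curve = fx.km_estimate(_ev(times, statuses))
                t_o, s_o = km_oracle(times, statuses)
                np.testing.assert_allclose(curve.grid, t_o)
                np.testing.assert_allclose(curve.survival, s_o, atol=1e-12)


class TestStratifiedThresholds:
    def test_recovers_configured_stratum_offset(self):
        sim = fx.simulate_cohort(fx.SimulationConfig(
            n_participants=400, noise_sd=0.5, seed=11,
            covariate_effects={"hypertension": fx.CovariateEffect(0.5, 3.0, 3.0)},
        ))
        am = _truth_alignment(sim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = fx.stratified_thresholds(sim.cohort, am, "MCI", "hypertension")
        t_dis = table.theta("MCI", "hypertension", "disease")
        t_free = table.theta("MCI", "hypertension", "disease-free")
        assert t_dis is not None and t_free is not None
        assert t_dis - t_free == pytest.approx(3.0, abs=1.0)

    def test_null_sex_difference_is_small(self):
        sim = fx.simulate_cohort(fx.SimulationConfig(
            n_participants=400, noise_sd=0.5, seed=12,
        ))
        am = _truth_alignment(sim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = fx.stratified_thresholds(sim.cohort, am, "MCI", "sex")
        assert abs(table.theta("MCI", "sex", "F") - table.theta("MCI", "sex", "M")) < 1.0

    def test_small_stratum_reported_undefined(self):
        sim = fx.simulate_cohort(fx.SimulationConfig(n_participants=30, seed=13))
        am = _truth_alignment(sim)
        with pytest.warns(UserWarning, match="small|threshold undefined"):
            table = fx.stratified_thresholds(
                sim.cohort, am, "MCI", "sex", min_per_stratum=20
            )
        entries = [table.get("MCI", "sex", lev) for lev in ("F", "M")]
        assert any(e is not None and e.theta is None for e in entries)

    def test_unknown_covariate_raises(self, noisy_sim, noisy_alignment):
        with pytest.raises(ValueError, match="not present"):
            fx.stratified_thresholds(
                noisy_sim.cohort, noisy_alignment, "MCI", "no_such_covariate"
            )
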