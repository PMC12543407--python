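"""Mean-curve fitting and time-shift alignment."""
import warnings

import numpy as np
import pytest

import floreyindex as fx
from floreyindex.trajectory import _fit_logistic

from conftest import make_series


@pytest.fixture(scope="module")
def curve():
    return fx.calibrated_curve()


class TestMeanCurve:
    def test_midpoint_value_is_half_ceiling(self, curve):
        assert fx.eval_curve(curve, curve.midpoint, warn_extrapolation=False) == pytest.approx(9.0)

    def test_calibration_anchors(self, curve):
        assert curve(79.0) == pytest.approx(0.5, abs=1e-9)
        assert curve(85.0) == pytest.approx(4.5, abs=1e-9)

    def test_strictly_increasing(self, curve):
        t = np.linspace(40, 120, 400)
        assert np.all(np.diff(curve(t)) > 0)

    def test_inverse_round_trip(self, curve):
        for y in (0.5, 4.5, 9.0, 17.0):
            assert curve(curve.inverse(y)) == pytest.approx(y, abs=1e-10)

    def test_extrapolation_warns(self, curve):
        with pytest.warns(UserWarning, match="outside fit domain"):
            fx.eval_curve(curve, 150.0)


class TestBinMeanTrajectory:
    def test_arithmetic_mean_per_bin(self):
        cohort = fx.Cohort([
            make_series("A", [70.2, 75.0], [1.0, 3.0]),
            make_series("B", [70.7, 76.0], [2.0, 4.0]),
        ])
        binned = fx.bin_mean_trajectory(cohort)
        row = binned[binned["bin_left"] == 70.0].iloc[0]
        assert row["mean_score"] == pytest.approx(1.5)
        assert row["n"] == 2

    def test_empty_bin_flagged_missing_not_zero(self):
        cohort = fx.Cohort([make_series("A", [70.2, 75.0], [1.0, 3.0])])
        binned = fx.bin_mean_trajectory(cohort)
        row = binned[binned["bin_left"] == 95.0].iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["mean_score"])

    def test_bins_cover_requested_range(self):
        cohort = fx.Cohort([make_series("A", [70.2, 75.0], [1.0, 3.0])])
        binned = fx.bin_mean_trajectory(cohort, age_range=(60, 100), width=1.0)
        assert binned["bin_left"].iloc[0] == 60.0
        assert binned["bin_left"].iloc[-1] == 99.0

    def test_noise_free_zero_shift_bins_match_generator_curve(self, curve):
        sim = fx.simulate_cohort(fx.SimulationConfig(
            n_participants=800, noise_sd=0.0, round_to_grid=False,
            shift_sd=0.0, seed=7,
        ))
        binned = fx.bin_mean_trajectory(sim.cohort)
        ages = np.concatenate([s.ages for s in sim.cohort])
        big = binned[binned["n"] >= 20]
        for row in big.itertuples():
            inside = ages[(ages >= row.bin_left) & (ages < row.bin_left + 1.0)]
            # evaluate at the bin's realized mean age: bins hold whatever ages
            # the visit schedule put there, not a symmetric sample
            assert abs(row.mean_score - curve(inside.mean())) < 0.1


class TestFitMeanCurve:
    def test_recovers_exact_logistic(self, curve):
        ages = np.arange(60.5, 100, 1.0)
        binned = __import__("pandas").DataFrame(
            {"bin_left": ages - 0.5, "age": ages, "mean_score": curve(ages),
             "n": np.full(len(ages), 30)}
        )
        fit = fx.fit_mean_curve(binned)
        assert fit.rate == pytest.approx(curve.rate, abs=1e-3)
        assert fit.midpoint == pytest.approx(curve.midpoint, abs=1e-3)

    def test_flat_data_raises_no_rising_signal(self):
        import pandas as pd
        binned = pd.DataFrame(
            {"bin_left": [60, 61, 62], "age": [60.5, 61.5, 62.5],
             "mean_score": [0.0, 0.0, 0.0], "n": [10, 10, 10]}
        )
        with pytest.raises(fx.NoRisingSignalError):
            fx.fit_mean_curve(binned)

    def test_too_few_bins_raises(self):
        import pandas as pd
        binned = pd.DataFrame(
            {"bin_left": [60, 61], "age": [60.5, 61.5],
             "mean_score": [0.5, 1.0], "n": [5, 5]}
        )
        with pytest.raises(ValueError):
            fx.fit_mean_curve(binned)

    def test_recovers_midpoint_under_noise(self, curve):
        rng = np.random.default_rng(42)
        import pandas as pd
        ages = np.arange(60.5, 100, 1.0)
        noisy = curve(ages) + rng.normal(0, 0.2, len(ages))
        binned = pd.DataFrame(
            {"bin_left": ages - 0.5, "age": ages, "mean_score": noisy,
             "n": np.full(len(ages), 50)}
        )
        fit = fx.fit_mean_curve(binned)
        assert abs(fit.midpoint - curve.midpoint) < 0.5

    def test_free_ceiling_stays_bounded(self, curve):
        import pandas as pd
        ages = np.arange(60.5, 100, 1.0)
        binned = pd.DataFrame(
            {"bin_left": ages - 0.5, "age": ages, "mean_score": curve(ages),
             "n": np.full(len(ages), 30)}
        )
        fit = fx.fit_mean_curve(binned, fix_ceiling=False)
        assert 0 < fit.ceiling <= 18.0


def _series_on_curve(pid, curve, fdi_ages, shift):
    """Visits whose scores sit exactly on the curve at index age+shift."""
    ages = np.asarray(fdi_ages, dtype=float) - shift
    return make_series(pid, ages, curve(ages + shift))


class TestAlignParticipant:
    def test_recovers_known_shift_on_rising_region(self, curve):
        # scores generated at index 78..88, stored at ages shifted by -5
        series = _series_on_curve("A", curve, [78, 80, 82, 84, 86, 88], shift=5.0)
        res = fx.align_participant(series, curve)
        assert res.shift == pytest.approx(5.0, abs=1e-2)
        assert res.identifiable

    def test_flat_trajectory_unidentifiable_with_ridge_pull(self, curve):
        series = make_series("flat", [62, 64, 66, 68], [0.0, 0.0, 0.0, 0.0])
        res = fx.align_participant(series, curve)
        assert not res.identifiable
        assert abs(res.shift) < 1.0

    @pytest.mark.parametrize("offset", [-5.0, 3.0, 10.0])
    def test_translation_equivariance(self, curve, offset):
        base = _series_on_curve("A", curve, [78, 80, 82, 84], shift=2.0)
        moved = make_series("A", base.ages + offset, base.scores)
        d0 = fx.align_participant(base, curve).shift
        d1 = fx.align_participant(moved, curve).shift
        assert d1 == pytest.approx(d0 - offset, abs=1e-2)

    def test_requires_two_visits(self, curve):
        series = make_series("A", [80.0], [4.0])
        with pytest.raises(ValueError):
            fx.align_participant(series, curve)

    def test_to_fdi_preserves_spacing(self):
        series = make_series("A", [70.0, 71.5], [0.0, 0.5])
        pairs = fx.to_fdi(series, 8.0)
        assert [f for _, f in pairs] == [78.0, 79.5]
        pairs0 = fx.to_fdi(series, 0.0)
        assert [f for _, f in pairs0] == [70.0, 71.5]


class TestFitAlignmentModel:
    def test_identical_participants_get_zero_shifts(self, curve):
        ages = np.array([76.0, 78.0, 80.0, 82.0, 84.0])
        scores = curve(ages)
        cohort = fx.Cohort([
            make_series(f"P{i}", ages, scores) for i in range(5)
        ])
        model = fx.fit_alignment_model(cohort)
        for r in model.shifts:
            assert abs(r.shift) < 0.01

    def test_objective_non_increasing(self, noisy_alignment):
        h = noisy_alignment.convergence.objective_history
        assert len(h) >= 2
        for a, b in zip(h, h[1:]):
            assert b <= a + 1e-6 * max(1.0, a)

    def test_converged_on_default_cohort(self, noisy_alignment):
        assert noisy_alignment.convergence.converged
        assert noisy_alignment.convergence.final_max_shift_change < 0.01

    def test_noise_free_recovers_curve_parameters(self, clean_alignment, curve):
        assert abs(clean_alignment.curve.rate - curve.rate) / curve.rate < 1e-2
        assert abs(clean_alignment.curve.midpoint - curve.midpoint) / curve.midpoint < 1e-2

    def test_shift_lookup_and_table(self, noisy_alignment, noisy_sim):
        pid = noisy_sim.cohort.participant_ids[0]
        r = noisy_alignment.shift_of(pid)
        table = noisy_alignment.shift_table()
        assert table.set_index("participant_id").loc[pid, "shift"] == r.shift
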