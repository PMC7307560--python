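"""Synthetic microcosm data: schedule, sampling, noise, datasets, fixtures."""

import numpy as np
import pytest

from boombust.model import Trajectory
from boombust.summaries import cycle_metrics
from boombust.synthetic import (
    ExperimentDesign,
    ZERO_OFFSET,
    add_observation_noise,
    fixture_parameter_sets,
    generate_dataset,
    observation_schedule,
    sample_trajectory,
    simulate_design,
)


class TestObservationSchedule:
    def test_default_schedule(self):
        days = observation_schedule(ExperimentDesign())
        assert days.tolist() == [1, 2, 3, 4, 5, 7, 9, 11, 13, 15, 17, 18]

    def test_short_horizon_daily(self):
        days = observation_schedule(ExperimentDesign(horizon=5))
        assert days.tolist() == [1, 2, 3, 4, 5]

    def test_empty_horizon(self):
        assert len(observation_schedule(ExperimentDesign(horizon=0))) == 0

    def test_explicit_days_pass_through(self):
        d = ExperimentDesign(observation_days=(1.0, 4.0, 9.0))
        assert observation_schedule(d).tolist() == [1, 4, 9]

    def test_design_validation(self):
        with pytest.raises(ValueError):
            ExperimentDesign(n_replicates=0)
        with pytest.raises(ValueError):
            ExperimentDesign(dish_volume=0)
        with pytest.raises(ValueError):
            ExperimentDesign(observation_days=(5.0, 3.0))
        with pytest.raises(ValueError):
            ExperimentDesign(observation_days=(1.0, 25.0))


class TestSampleTrajectory:
    def test_exact_grid_times_reproduce_values(self):
        traj = Trajectory(times=[0, 1, 2, 3], R_values=[30, 60, 90, 120], C_values=[1, 2, 4, 8])
        s = sample_trajectory(traj, [0, 1, 2, 3])
        assert np.array_equal(s.R_obs, traj.R_values)
        assert np.array_equal(s.C_obs, traj.C_values)

    def test_constant_trajectory_samples_to_constant(self):
        traj = Trajectory(times=[0, 9, 18], R_values=[7, 7, 7], C_values=[3, 3, 3])
        s = sample_trajectory(traj, [2.5, 11.0])
        assert np.allclose(s.R_obs, 7.0) and np.allclose(s.C_obs, 3.0)

    def test_times_outside_range_rejected(self):
        traj = Trajectory(times=[0, 1], R_values=[1, 1], C_values=[1, 1])
        with pytest.raises(ValueError):
            sample_trajectory(traj, [0.5, 2.0])

    def test_truncation_keeps_three_zero_observations(self):
        # predator positive through day 7, functionally zero afterwards:
        # keep the zeros at 9, 11, 13 and blank 15, 17, 18
        days = np.array([1, 2, 3, 4, 5, 7, 9, 11, 13, 15, 17, 18], dtype=float)
        traj = Trajectory(
            times=days,
            R_values=np.full(len(days), 50.0),
            C_values=np.where(days <= 7, 2.0, 0.0),
        )
        s = sample_trajectory(traj, days, truncate=True)
        assert np.isfinite(s.C_obs[days <= 13]).all()
        assert np.isnan(s.C_obs[days > 13]).all()
        assert np.isfinite(s.R_obs).all()  # prey stayed positive throughout


class TestObservationNoise:
    def _series(self, value=100.0, n=2000):
        traj = Trajectory(
            times=np.arange(n, dtype=float),
            R_values=np.full(n, value),
            C_values=np.full(n, value),
        )
        return sample_trajectory(traj, np.arange(n, dtype=float))

    def test_zero_sigma_is_identity(self):
        s = self._series()
        out = add_observation_noise(s, 0.0, seed=1)
        assert np.array_equal(out.R_obs, s.R_obs)

    def test_seed_reproducibility(self):
        s = self._series()
        a = add_observation_noise(s, 0.1, seed=7)
        b = add_observation_noise(s, 0.1, seed=7)
        assert np.array_equal(a.R_obs, b.R_obs) and np.array_equal(a.C_obs, b.C_obs)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_observation_noise(self._series(), -0.1, seed=0)

    def test_log_noise_law_sd_and_mean(self):
        # 1e4 draws on a constant series: ln-residual SD within 5% of
        # sigma and mean within 3 SEM of zero (mean-preserving on log scale)
        s = self._series(value=100.0, n=5000)
        out = add_observation_noise(s, 0.1, seed=3)
        res = np.log(out.R_obs + ZERO_OFFSET) - np.log(s.R_obs + ZERO_OFFSET)
        res = np.concatenate([res, np.log(out.C_obs + ZERO_OFFSET) - np.log(s.C_obs + ZERO_OFFSET)])
        assert abs(res.std() - 0.1) / 0.1 < 0.05
        assert abs(res.mean()) < 3 * res.std() / np.sqrt(len(res))

    def test_raw_scale_mode(self):
        s = self._series(value=100.0, n=5000)
        out = add_observation_noise(s, 0.5, seed=3, scale="raw")
        res = out.R_obs - s.R_obs
        assert abs(res.std() - 0.5) / 0.5 < 0.1


class TestGenerateDataset:
    def test_structural_counts(self, fixture_sets):
        design = ExperimentDesign(n_replicates=3, seed=11)
        series = generate_dataset(fixture_sets, design)
        assert len(series) == 6 * (3 + 1)
        means = [s for s in series if s.replicate == "mean"]
        assert len(means) == 6

    def test_single_noiseless_replicate_mean_equals_truth(self, fixture_sets):
        design = ExperimentDesign(n_replicates=1, noise_sigma=0.0, seed=0)
        series = generate_dataset({"23": fixture_sets["23"]}, design)
        rep, mean = series
        truth = simulate_design(fixture_sets["23"], design)
        assert np.allclose(mean.R_obs, truth.R_obs, equal_nan=True)
        assert np.allclose(mean.C_obs, truth.C_obs, equal_nan=True)
        finite = np.isfinite(mean.R_se)
        assert np.all(mean.R_se[finite] == 0)

    def test_pure_function_of_seed(self, fixture_sets):
        design = ExperimentDesign(n_replicates=2, seed=5)
        a = generate_dataset(fixture_sets, design)
        b = generate_dataset(fixture_sets, design)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.R_obs, sb.R_obs, equal_nan=True)
            assert np.array_equal(sa.C_obs, sb.C_obs, equal_nan=True)

    def test_empty_parameter_map_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset({}, ExperimentDesign())


class TestFixtureParameterSets:
    def test_shared_fixed_values(self, fixture_sets):
        for p in fixture_sets.values():
            assert p.e == 0.055
            assert p.C_d == 40.0

    def test_six_labels(self, fixture_sets):
        assert list(fixture_sets) == ["17", "20", "23", "25", "27", "31"]

    def test_boom_bust_with_extinction_by_horizon(self, fixture_trajectories, design):
        for label, traj in fixture_trajectories.items():
            m = cycle_metrics(traj, extinction_threshold=design.c_offset)
            assert m.peak_lag > 0, label  # prey boom precedes predator peak
            assert m.pred_extinction_time is not None, label
            assert m.pred_extinction_time <= 18.0, label

    def test_extinction_time_decreases_with_temperature(self, fixture_trajectories, design):
        exts = [
            cycle_metrics(traj, extinction_threshold=design.c_offset).pred_extinction_time
            for traj in fixture_trajectories.values()
        ]
        assert all(x > y for x, y in zip(exts, exts[1:]))
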