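"""Core ODE model: rate functions, derivatives and the integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boombust.model import (
    ModelParams,
    SystemState,
    Trajectory,
    carrying_capacity,
    derivatives,
    functional_response,
    predator_mortality_rate,
    solve_trajectory,
)

from oracles import exponential_decay, logistic_closed_form, rk4_trajectory


def params(**overrides):
    base = dict(r=1.0, r_slope=0.002, a=0.1, h=0.05, m=0.03, e=0.055, d=1.0, C_d=40.0)
    base.update(overrides)
    return ModelParams(**base)


class TestFunctionalResponse:
    @pytest.mark.parametrize(
        "kw, R, C, expected",
        [
            (dict(), 0.0, 5.0, 0.0),  # no prey, no consumption
            (dict(a=2.0, h=0.0, m=0.0), 5.0, 10.0, 10.0),  # type-I limit a*R
            (dict(a=2.0, h=0.5, m=1.0, c_offset=0.167), 1.0, 1.167, 2.0 / 3.0),
        ],
    )
    def test_known_values(self, kw, R, C, expected):
        assert functional_response(params(**kw), R, C) == pytest.approx(expected, rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            functional_response(params(), -1.0, 1.0)
        with pytest.raises(ValueError):
            functional_response(params(), 1.0, -1.0)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            params(a=-0.1)

    @given(
        R1=st.floats(0, 1e4),
        dR=st.floats(0, 1e3),
        C1=st.floats(0, 1e3),
        dC=st.floats(0, 1e2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_prey_and_antitone_in_predators(self, R1, dR, C1, dC):
        p = params()
        assert functional_response(p, R1 + dR, C1) >= functional_response(p, R1, C1)
        assert functional_response(p, R1, C1 + dC) <= functional_response(p, R1, C1)

    def test_saturates_at_inverse_handling_time(self):
        p = params()
        R_large = 1e6 / (p.a * p.h)
        assert functional_response(p, R_large, 0.0) == pytest.approx(1.0 / p.h, rel=0.01)

    def test_interference_clamped_below_one_predator(self):
        # below the one-predator offset the denominator must not shrink
        p = params(m=5.0)
        assert functional_response(p, 10.0, 0.0) == functional_response(p, 10.0, p.c_offset)


class TestPredatorMortality:
    @pytest.mark.parametrize(
        "kw, R, expected",
        [
            (dict(d=1.0), 0.0, 1.0),
            (dict(d=0.0), 123.0, 0.0),
            (dict(d=1.0, C_d=40.0), 0.1, math.exp(-4.0)),
        ],
    )
    def test_known_values(self, kw, R, expected):
        assert predator_mortality_rate(params(**kw), R) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_prey(self):
        p = params(d=2.0, C_d=1.0)
        rates = [predator_mortality_rate(p, R) for R in (0.0, 0.5, 1.0, 5.0)]
        assert all(x > y for x, y in zip(rates, rates[1:]))

    def test_negative_prey_rejected(self):
        with pytest.raises(ValueError):
            predator_mortality_rate(params(), -0.5)


class TestCarryingCapacity:
    @pytest.mark.parametrize(
        "r, r_slope, expected",
        [(1.0, 0.01, 100.0), (0.5, 0.002, 250.0), (0.0, 0.01, 0.0)],
    )
    def test_ratio(self, r, r_slope, expected):
        assert carrying_capacity(params(r=r, r_slope=r_slope)) == expected

    def test_zero_slope_is_unbounded_not_an_error(self):
        assert carrying_capacity(params(r=1.0, r_slope=0.0)) == math.inf


class TestDerivatives:
    def test_prey_absent_predator_decays_at_maximum_mortality(self):
        dR, dC = derivatives(params(d=0.5), SystemState(t=0, R=0.0, C=2.0))
        assert dR == 0.0
        assert dC == pytest.approx(-1.0, rel=1e-12)

    def test_prey_alone_at_carrying_capacity_is_equilibrium(self):
        p = params()
        K = carrying_capacity(p)
        dR, dC = derivatives(p, SystemState(t=0, R=K, C=0.0))
        assert dR == pytest.approx(0.0, abs=1e-9)
        assert dC == 0.0

    def test_joint_extinction_is_absorbing(self):
        assert derivatives(params(), SystemState(t=0, R=0.0, C=0.0)) == (0.0, 0.0)


class TestSolveTrajectory:
    def test_predator_free_prey_matches_logistic_closed_form(self):
        p = params(a=0.0, r=0.8, r_slope=0.002)
        t = np.linspace(0, 18, 50)
        traj = solve_trajectory(p, SystemState(t=0, R=30.0, C=0.0), t)
        expected = logistic_closed_form(p.r, carrying_capacity(p), 30.0, t)
        assert np.max(np.abs(traj.R_values - expected) / expected) < 1e-6

    def test_prey_free_predator_matches_exponential_decay(self):
        p = params(d=0.7, C_d=40.0)
        t = np.linspace(0, 10, 30)
        traj = solve_trajectory(p, SystemState(t=0, R=0.0, C=5.0), t)
        expected = exponential_decay(5.0, p.d, t)
        assert np.max(np.abs(traj.C_values - expected) / expected) < 1e-6

    def test_all_rates_zero_gives_constant_state(self):
        p = params(r=0.0, r_slope=0.0, a=0.0, d=0.0)
        t = np.linspace(0, 18, 10)
        traj = solve_trajectory(p, SystemState(t=0, R=30.0, C=2.0), t)
        assert np.allclose(traj.R_values, 30.0, rtol=1e-9)
        assert np.allclose(traj.C_values, 2.0, rtol=1e-9)

    def test_agrees_with_fixed_step_rk4_oracle(self, fixture_sets, design):
        t = np.linspace(0, 18, 19)
        init = design.initial_state
        for label, p in fixture_sets.items():
            traj = solve_trajectory(p, init, t)
            R_o, C_o = rk4_trajectory(p.to_dict(), init.R, init.C, t, dt=1e-3)
            scale_R = np.maximum(np.maximum(traj.R_values, R_o), 1e-3)
            scale_C = np.maximum(np.maximum(traj.C_values, C_o), 1e-3)
            assert np.max(np.abs(traj.R_values - R_o) / scale_R) < 1e-3, label
            assert np.max(np.abs(traj.C_values - C_o) / scale_C) < 1e-3, label

    def test_fixture_trajectories_are_non_negative(self, fixture_trajectories):
        for label, traj in fixture_trajectories.items():
            assert traj.success, label
            assert np.all(traj.R_values >= 0), label
            assert np.all(traj.C_values >= 0), label

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            solve_trajectory(params(), SystemState(t=0, R=1, C=1), [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            solve_trajectory(params(), SystemState(t=0, R=1, C=1), [1.0, 2.0])

    def test_trajectory_length_consistency_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 1.0], R_values=[1.0], C_values=[1.0, 2.0])


class TestSerialization:
    def test_params_json_roundtrip(self):
        p = params()
        assert ModelParams.from_json(p.to_json()) == p

    def test_one_predator_offset_default(self):
        assert round(params().c_offset, 3) == 0.167
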