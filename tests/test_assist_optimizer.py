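"""Static-optimization QP solver and assistance conditions."""

import numpy as np
import pytest

from exoassist import assist_optimizer as ao
from exoassist import gait_synth as gs
from exoassist import musculotendon as mt
from exoassist.errors import ConfigurationError, InfeasibleError


def make_muscle(gain_sign=+1, fmax=3000.0, arm=0.05, name="m"):
    return mt.MuscleParams(
        name=name, max_isometric_force=fmax, optimal_fiber_length=0.25,
        max_contraction_velocity=10.0, moment_arm_coeffs=(arm,),
        action_sign=gain_sign, muscle_mass=0.3)


def make_problem(muscle_specs, demand, actuators=()):
    """muscle_specs: list of (sign, fmax, arm) at optimal isometric state."""
    muscles = [make_muscle(s, f, r, name=f"m{i}")
               for i, (s, f, r) in enumerate(muscle_specs)]
    states = [mt.MuscleState(1.0, 0.0) for _ in muscles]
    return ao.TimestepProblem(
        muscle_states=states, muscle_params=muscles, angle_deg=0.0,
        net_moment=demand, actuators=list(actuators))


def _grid_pass(problem, grids, tau_step):
    """One brute-force pass over per-muscle activation grids.

    Loops the first muscle, vectorizes the rest; the actuator (if any)
    absorbs the balance residual, snapped to the torque grid, and is
    penalized; infeasible combinations are discarded. Returns the best
    (objective, activations).
    """
    gains = ao._torque_gains(problem)
    n = len(gains)
    k = min(n, 2)
    mesh = np.meshgrid(*grids[n - k:], indexing="ij")
    acts_inner = np.stack([m.ravel() for m in mesh], axis=0)
    inner_obj = np.sum(acts_inner**2, axis=0)
    inner_torque = gains[n - k:] @ acts_inner
    prefixes = [()] if n <= 2 else [(a,) for a in grids[0]]
    spec = problem.actuators[0] if problem.actuators else None
    best, best_acts = np.inf, None
    for prefix in prefixes:
        base_torque = sum(g * a for g, a in zip(gains[: n - k], prefix))
        resid = (problem.net_moment - problem.assist_torque - base_torque
                 - inner_torque)
        obj = inner_obj + sum(a * a for a in prefix)
        if spec is not None:
            tau = np.round(resid / tau_step) * tau_step
            if spec.bounds is not None:
                feasible = (tau >= spec.bounds[0]) & (tau <= spec.bounds[1])
                obj = np.where(feasible, obj + (tau / spec.weight) ** 2,
                               np.inf)
            else:
                obj = obj + (tau / spec.weight) ** 2
        else:
            obj = np.where(np.abs(resid) <= 0.05, obj, np.inf)
        idx = int(np.argmin(obj))
        if obj[idx] < best:
            best = float(obj[idx])
            best_acts = np.array(list(prefix) + list(acts_inner[:, idx]))
    return best, best_acts


def brute_force_objective(problem, a_step=1e-3, tau_step=0.01):
    """Multi-stage grid oracle: full-range grid at ``a_step``, then shrinking
    local grids around the running argmin (the effort landscape is flat along
    the balance manifold, so the coarse argmin can sit ~1e-2 away from the
    optimum; the refinement stages recover it on a pure grid search)."""
    gains = ao._torque_gains(problem)
    full = [np.arange(0.02, 1.0 + a_step / 2, a_step) for _ in gains]
    _, acts = _grid_pass(problem, full, tau_step)
    best = np.inf
    for window, step, tstep in ((12e-3, 5e-5, 1e-4), (1.5e-3, 5e-6, 1e-6)):
        local = [np.clip(np.arange(a - window, a + window + step / 2, step),
                         0.02, 1.0) for a in acts]
        best, acts = _grid_pass(problem, local, tstep)
    return best


class TestSolveTimestep:
    def test_single_muscle_interior_optimum(self):
        # capacity r*Fmax = 150 Nm, demand 75 -> a = 0.5
        problem = make_problem([(+1, 3000.0, 0.05)], 75.0)
        sol = ao.solve_timestep(problem)
        assert sol.activations[0] == pytest.approx(0.5, rel=1e-9)
        assert abs(sol.balance_residual) <= 1e-6

    def test_zero_demand_balanced_pair_rests_at_lower_bound(self):
        # equal-capacity antagonists: a = 0.02 each balances zero demand
        problem = make_problem([(+1, 3000.0, 0.05), (-1, 3000.0, 0.05)], 0.0)
        sol = ao.solve_timestep(problem)
        assert np.allclose(sol.activations, 0.02)
        assert sol.objective == pytest.approx(2 * 0.0004, rel=1e-9)

    def test_ideal_actuator_takes_over(self):
        problem = make_problem([(+1, 3000.0, 0.05)], 75.0,
                               actuators=[ao.ideal_actuator()])
        sol = ao.solve_timestep(problem)
        assert sol.activations[0] == pytest.approx(0.02, abs=1e-6)
        assert sol.actuator_torques[0] == pytest.approx(75.0 - 0.02 * 150.0,
                                                        rel=1e-6)

    @pytest.mark.parametrize("demand", [-40.0, -5.0, 0.0, 20.0, 75.0, 140.0])
    def test_matches_brute_force_oracle_two_muscles(self, demand):
        problem = make_problem(
            [(+1, 3000.0, 0.05), (-1, 1000.0, 0.04)], demand,
            actuators=[ao.reserve_actuator()])
        sol = ao.solve_timestep(problem)
        oracle = brute_force_objective(problem)
        assert sol.objective == pytest.approx(oracle, rel=1e-4, abs=1e-6)
        assert abs(sol.balance_residual) <= 1e-6

    def test_matches_brute_force_with_ideal_actuator(self):
        problem = make_problem([(+1, 2000.0, 0.05), (+1, 1000.0, 0.05)],
                               60.0, actuators=[ao.ideal_actuator()])
        sol = ao.solve_timestep(problem)
        oracle = brute_force_objective(problem)
        assert sol.objective == pytest.approx(oracle, rel=1e-4, abs=1e-9)

    def test_infeasible_demand_raises(self):
        problem = make_problem([(+1, 1000.0, 0.05)], 500.0)
        with pytest.raises(InfeasibleError):
            ao.solve_timestep(problem)

    def test_penalty_weight_controls_actuator_usage(self):
        usages, efforts = [], []
        for w in (1.0, 1e6):
            problem = make_problem([(+1, 3000.0, 0.05)], 75.0,
                                   actuators=[ao.ideal_actuator(w)])
            sol = ao.solve_timestep(problem)
            usages.append(abs(sol.actuator_torques[0]))
            efforts.append(float(np.sum(sol.activations**2)))
        assert usages[1] > usages[0]
        assert efforts[1] < efforts[0]


class TestSolveCycle:
    def test_moment_balance_everywhere(self, subject, cycle_13, muscles):
        for cond in ao.CONDITIONS[:3]:
            sols = ao.solve_cycle(cycle_13, subject, muscles,
                                  ao.ConditionSpec(condition=cond))
            assert len(sols) == 101
            assert max(abs(s.balance_residual) for s in sols) <= 1e-6

    def test_oa_relaxes_activations_elementwise(self, solved_conditions):
        a_no = np.array([s.activations for s in solved_conditions["no_exo"]])
        a_oa = np.array([s.activations for s in solved_conditions["oa"]])
        assert np.all(a_oa <= a_no + 1e-9)

    def test_effort_ordering_across_conditions(self, solved_conditions):
        effort = {c: ao.sum_squared_activation(s)
                  for c, s in solved_conditions.items()}
        assert effort["oa"] <= effort["pa"] <= effort["no_exo"] \
            <= effort["na"]

    def test_na_loads_dorsiflexors_in_swing(self, subject, cycle_13, muscles):
        """The sole's mass must be carried during swing: demand shifts toward
        dorsiflexion and tibialis-anterior activation rises."""
        na = ao.ConditionSpec(condition="na")
        inc = ao.added_mass_moment(na, cycle_13, cycle_13.phase_grid)
        swing = cycle_13.phase_grid > 70
        assert np.all(inc <= 0)
        assert inc[swing].min() < 0
        sols_no = ao.solve_cycle(cycle_13, subject, muscles,
                                 ao.ConditionSpec(condition="no_exo"))
        sols_na = ao.solve_cycle(cycle_13, subject, muscles, na)
        ta_no = np.array([s.activations[2] for s in sols_no])
        ta_na = np.array([s.activations[2] for s in sols_na])
        assert np.all(ta_na[swing] >= ta_no[swing] - 1e-12)
        assert ta_na[swing].max() > ta_no[swing].max()


class TestAddedMass:
    def test_zero_for_no_exo_and_zero_mass(self, cycle_13):
        no_exo = ao.ConditionSpec(condition="no_exo")
        assert ao.added_mass_moment(no_exo, cycle_13, 80.0) == 0.0
        weightless = ao.ConditionSpec(condition="na", sole_mass=0.0)
        inc = ao.added_mass_moment(weightless, cycle_13, cycle_13.phase_grid)
        assert np.all(inc == 0.0)

    def test_linear_in_sole_mass(self, cycle_13):
        single = ao.ConditionSpec(condition="na", sole_mass=0.5)
        double = ao.ConditionSpec(condition="na", sole_mass=1.0)
        inc1 = ao.added_mass_moment(single, cycle_13, cycle_13.phase_grid)
        inc2 = ao.added_mass_moment(double, cycle_13, cycle_13.phase_grid)
        assert np.allclose(inc2, 2.0 * inc1, rtol=1e-12)

    def test_zero_during_stance(self, cycle_13):
        na = ao.ConditionSpec(condition="na")
        inc = ao.added_mass_moment(na, cycle_13, np.arange(0.0, 60.0))
        assert np.all(inc == 0.0)


class TestDeriveOA:
    def test_zero_demand_cycle_gives_near_zero_oa(self, subject):
        flat = gs.GaitCycle(
            subject_id=subject.subject_id, speed=1.0,
            ankle_angle=np.zeros(101), net_moment=np.zeros(101),
            stride_length=1.25, cadence=120.0 / 1.25,
            max_heel_clearance=0.03, duration=1.25)
        oa = ao.derive_oa(flat, subject, mt.default_muscles())
        # only the 0.02 activation-floor tone (~0.07 Nm/kg) is counteracted
        assert np.max(np.abs(oa)) < 0.1

    def test_pf_support_peaks_in_push_off_window(self, subject, cycle_13,
                                                 muscles_with_floor):
        oa = ao.derive_oa(cycle_13, subject, muscles_with_floor)
        assert 40 <= int(np.argmax(oa)) <= 70
        assert 0.6 <= oa.max() <= 1.2  # Nm/kg, normal speed

    def test_condition_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ao.ConditionSpec(condition="flying")
        with pytest.raises(ConfigurationError):
            ao.ConditionSpec(condition="pa")  # missing profile
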