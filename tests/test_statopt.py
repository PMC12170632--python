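"""Static-optimization contracts: closed forms, grid-search oracle, linearity."""

import itertools

import numpy as np
import pytest

from musclesyn import (
    MuscleParams,
    ToyJointTask,
    default_muscle_params,
    default_toy_task,
    muscle_force,
    simulate_model_activations,
    solve_frame,
)
from musclesyn.errors import DomainError, InfeasibleFrameError


def unit_muscles(n):
    return [MuscleParams(f"m{i}", 1.0, 1.0, 1.0, 0.0) for i in range(n)]


class TestMuscleForce:
    def test_zero_activation_zero_force(self):
        p = MuscleParams("x", 1.0, 500.0, 1.0, 10.0)
        assert muscle_force(p, 0.0) == 0.0

    def test_full_activation_no_pennation(self):
        p = MuscleParams("x", 1.0, 100.0, 1.0, 0.0)
        assert muscle_force(p, 1.0) == pytest.approx(100.0)

    def test_medial_deltoid_full_activation(self):
        # Fmax 1103.5 N at 15 degrees pennation
        p = MuscleParams("DELT2", 10.8, 1103.5, 11.0, 15.0)
        assert muscle_force(p, 1.0) == pytest.approx(1103.5 * np.cos(np.deg2rad(15)), abs=0.1)
        assert muscle_force(p, 1.0) == pytest.approx(1065.9, abs=0.1)

    def test_activation_bounds_enforced(self):
        p = MuscleParams("x", 1.0, 100.0, 1.0, 0.0)
        with pytest.raises(DomainError):
            muscle_force(p, 1.5)

    def test_flv_hooks_scale_force(self):
        p = MuscleParams("x", 1.0, 100.0, 1.0, 0.0)
        assert muscle_force(p, 0.5, f_l=0.8, f_v=1.2) == pytest.approx(48.0)


def grid_search_objective(task, t, params, resolution=1e-3):
    """Dense-grid oracle for <=3-muscle, single-joint problems.

    Grids the first n-1 activations at the given resolution and solves the
    last one exactly from the moment-equilibrium constraint, so every
    candidate is exactly feasible; returns the minimal sum of squares.
    """
    gains = (
        task.moment_arms
        * np.array([p.peak_force * np.cos(np.deg2rad(p.pennation_angle)) for p in params])
    )[0]
    b = task.required_moments[0, t]
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    n = len(params)
    if n == 1:
        a_last = b / gains[0]
        return float(a_last**2) if 0 <= a_last <= 1 else np.inf
    free = np.stack(
        [g.ravel() for g in np.meshgrid(*([grid] * (n - 1)), indexing="ij")], axis=0
    )
    a_last = (b - gains[:-1] @ free) / gains[-1]
    ok = (a_last >= 0.0) & (a_last <= 1.0)
    obj = np.sum(free**2, axis=0) + a_last**2
    return float(np.min(obj[ok]))


class TestSolveFrame:
    def test_two_identical_muscles_split_evenly(self):
        task = ToyJointTask([[1.0, 1.0]], [[1.0]])
        a = solve_frame(task, 0, unit_muscles(2))
        assert np.allclose(a, [0.5, 0.5], atol=1e-9)

    def test_single_muscle_half_capacity(self):
        task = ToyJointTask([[2.0]], [[1.0]])
        a = solve_frame(task, 0, unit_muscles(1))
        assert a[0] == pytest.approx(0.5, abs=1e-9)

    def test_three_muscle_closed_form(self):
        # least-norm solution proportional to the moment arms
        task = ToyJointTask([[1.0, 1.0, 2.0]], [[1.0]])
        a = solve_frame(task, 0, unit_muscles(3))
        assert np.allclose(a, [1 / 6, 1 / 6, 1 / 3], atol=1e-9)

    @pytest.mark.parametrize(
        "arms,moment",
        [([[1.0, 1.0]], 1.0), ([[1.0, 2.0]], 1.4), ([[1.0, 1.0, 2.0]], 1.0)],
    )
    def test_matches_grid_search_oracle(self, arms, moment):
        task = ToyJointTask(arms, [[moment]])
        params = unit_muscles(len(arms[0]))
        a = solve_frame(task, 0, params)
        grid_obj = grid_search_objective(task, 0, params, resolution=1e-3)
        assert float(a @ a) == pytest.approx(grid_obj, abs=1e-4)

    def test_bound_active_solution_respects_box(self):
        # one strong + one weak muscle; demand forces the weak one to saturate
        params = [MuscleParams("s", 1, 1.0, 1, 0.0), MuscleParams("w", 1, 0.2, 1, 0.0)]
        task = ToyJointTask([[1.0, 1.0]], [[1.1]])
        a = solve_frame(task, 0, params)
        assert np.all(a >= -1e-12) and np.all(a <= 1.0 + 1e-12)
        gains = np.array([1.0, 0.2])
        assert abs(np.dot(gains, a) - 1.1) < 1e-6

    def test_permutation_equivariance(self):
        task = ToyJointTask([[2.0, 1.0]], [[1.0]])
        a = solve_frame(task, 0, unit_muscles(2))
        task_p = ToyJointTask([[1.0, 2.0]], [[1.0]])
        b = solve_frame(task_p, 0, unit_muscles(2))
        assert np.allclose(a, b[::-1], atol=1e-9)

    def test_infeasible_frame_names_joint_and_shortfall(self):
        task = ToyJointTask([[1.0, 1.0]], [[5.0]], joint_names=["elevation"])
        with pytest.raises(InfeasibleFrameError) as exc:
            solve_frame(task, 0, unit_muscles(2))
        assert exc.value.joint == "elevation"
        assert exc.value.shortfall == pytest.approx(3.0, abs=1e-6)


class TestSimulate:
    def test_zero_moments_zero_activations(self):
        params = default_muscle_params()
        task = ToyJointTask(np.ones((2, 15)) * 0.02, np.zeros((2, 10)))
        m = simulate_model_activations(task, params)
        assert np.allclose(m.values, 0.0, atol=1e-9)

    @staticmethod
    def unconstrained_task(n_time, scale=1.0):
        # two joints actuated by disjoint agonist groups: least-norm
        # solutions are nonnegative and within bounds for these demands,
        # so no box constraint ever activates
        arms = np.array([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0, 1.0, 2.0]])
        t = np.linspace(0, 1, n_time)
        moments = scale * np.vstack(
            [np.exp(-((t - 0.3) ** 2) / 0.02), np.exp(-((t - 0.7) ** 2) / 0.02)]
        )
        return ToyJointTask(arms, moments)

    def test_linearity_when_bounds_inactive(self):
        params = unit_muscles(6)
        full = simulate_model_activations(self.unconstrained_task(30), params)
        halved = simulate_model_activations(self.unconstrained_task(30, 0.5), params)
        assert np.allclose(halved.values, 0.5 * full.values, atol=1e-6)

    def test_rank_bounded_by_joint_count_when_unconstrained(self):
        m = simulate_model_activations(self.unconstrained_task(40), unit_muscles(6))
        sv = np.linalg.svd(m.values, compute_uv=False)
        assert sv[2] < 1e-8 * sv[0]

    def test_equilibrium_satisfied_everywhere(self):
        params = default_muscle_params()
        task = default_toy_task(n_time=25)
        m = simulate_model_activations(task, params)
        gains = np.array(
            [p.peak_force * np.cos(np.deg2rad(p.pennation_angle)) for p in params]
        )
        moments = (task.moment_arms * gains[None, :]) @ m.values
        assert np.max(np.abs(moments - task.required_moments)) < 1e-6
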