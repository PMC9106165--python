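"""Derivative correctness, homeostasis constraints and trajectory integration."""

import numpy as np
import pytest

from osteomac import (
    BASELINE,
    HOMEOSTATIC_BASELINE,
    HypothesisCombination,
    ModelState,
    ParameterSet,
    Trajectory,
    VARIABLES,
    derive_homeostatic_parameters,
    enumerate_combinations,
    evaluate_rhs,
    simulate_trajectory,
)
from osteomac.errors import DomainError, HomeostasisError

from .oracles import rhs_literal, rk4_fixed, rk4_fixed_compiled
from .conftest import balanced


class TestEvaluateRhs:
    def test_matches_literal_transcription_on_random_states(self, table_params):
        """The kernel agrees with an independent hand transcription to 1e-12."""
        rng = np.random.default_rng(7)
        pdict = table_params.to_dict()
        # exercise the pro-inflammatory formation branch of a1/a2 too
        pdict["d_OC2"] = 3.3e-6
        params = ParameterSet.from_dict(pdict)
        for combo in enumerate_combinations():
            for _ in range(5):
                y = rng.uniform(0.0, 100.0, 9)
                state = ModelState(**dict(zip(VARIABLES, y)))
                got = evaluate_rhs(state, params, combo)
                want = rhs_literal(y, pdict, combo.a, combo.b, combo.c)
                np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)

    def test_steady_state_at_homeostatic_baseline(self, best_combo, balanced_params):
        rhs = evaluate_rhs(HOMEOSTATIC_BASELINE, balanced_params, best_combo)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-9)

    def test_no_anti_inflammatory_source_without_pro_cells(self, best_combo, balanced_params):
        # c2: p21 is proportional to M1 + Mo1
        state = BASELINE.replace(M2=500.0)
        rhs = evaluate_rhs(state, balanced_params, best_combo)
        dM2 = rhs[VARIABLES.index("M2")]
        expected = -(balanced_params.depol_2 + balanced_params.delta_M) * 500.0
        assert dM2 == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_state(self, best_combo, table_params):
        with pytest.raises(DomainError):
            ModelState(Mo=-1.0)


class TestHomeostasisDerivation:
    def test_osteoclast_formation_rate_worked_example(self, best_combo, table_params):
        """d_OC from the steady-state rearrangement matches the published value."""
        derived = derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, table_params, best_combo)
        assert derived["d_OC"] == pytest.approx(0.53 * 8.8e4 / (3.1e4 * 2.8e4), rel=1e-12)
        assert derived["d_OC"] == pytest.approx(5.35e-5, rel=0.01)

    def test_bone_apposition_rate_worked_example(self, best_combo, table_params):
        derived = derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, table_params, best_combo)
        assert derived["Pi_B"] == pytest.approx(5.99e-7 * 8.8e4 * 0.3530 / 3.1e4, rel=1e-12)
        assert derived["Pi_B"] == pytest.approx(6.018e-7, rel=0.01)

    def test_replenishment_rates(self, best_combo, table_params):
        derived = derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, table_params, best_combo)
        assert derived["H_Mo"] == pytest.approx(0.45 * 1.4e4, rel=1e-12)
        # macrophage replenishment covers death plus osteoclastogenic outflux
        assert derived["H_M"] == pytest.approx(0.1 * 2.8e4 + 0.53 * 8.8e4, rel=1e-12)

    def test_zero_baseline_raises(self, best_combo, table_params):
        with pytest.raises(HomeostasisError):
            derive_homeostatic_parameters(
                HOMEOSTATIC_BASELINE.replace(OC=0.0), table_params, best_combo)

    def test_injured_baseline_rejected(self, best_combo, table_params):
        with pytest.raises(HomeostasisError):
            derive_homeostatic_parameters(BASELINE, table_params, best_combo)

    @pytest.mark.parametrize("combo", enumerate_combinations(), ids=lambda c: c.name)
    def test_derived_parameters_zero_the_rhs_for_all_models(self, combo, table_params):
        params = balanced(table_params, combo)
        rhs = evaluate_rhs(HOMEOSTATIC_BASELINE, params, combo)
        scale = np.maximum(np.abs(HOMEOSTATIC_BASELINE.to_array()), 1.0)
        np.testing.assert_allclose(rhs / scale, 0.0, atol=1e-12)


class TestSimulation:
    def test_initial_condition_exact(self, best_combo, balanced_params):
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, [0.0, 1.0, 14.0])
        np.testing.assert_array_equal(traj.states[0], BASELINE.to_array())

    def test_homeostatic_run_is_constant(self, best_combo, balanced_params):
        traj = simulate_trajectory(HOMEOSTATIC_BASELINE, balanced_params, best_combo,
                                   np.linspace(0, 14, 15))
        base = HOMEOSTATIC_BASELINE.to_array()
        scale = np.maximum(np.abs(base), 1.0)
        dev = np.abs(traj.states - base) / scale
        assert dev.max() < 1e-6

    def test_injury_decays_monotonically_and_states_nonnegative(self, best_combo, balanced_params):
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo,
                                   np.linspace(0, 14, 141))
        D = traj.get("D")
        assert np.all(np.diff(D) <= 1e-12)
        assert np.all(D >= 0)
        assert np.all(traj.states >= 0)
        assert np.all(traj.get("B") > 0)

    def test_adaptive_matches_fixed_step_rk4(self, best_combo, balanced_params):
        t_grid = np.array([0.0, 1.0, 2.0, 3.0, 7.0, 14.0])
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, t_grid)
        oracle = rk4_fixed(BASELINE.to_array(), t_grid, balanced_params.to_dict(),
                           best_combo.a, best_combo.b, best_combo.c, dt=1e-3)
        scale = np.maximum(np.abs(oracle), 1e-6 * np.maximum(np.abs(oracle).max(axis=0), 1.0))
        rel = np.abs(traj.states - oracle) / scale
        assert rel.max() < 1e-4

    def test_compiled_oracle_matches_pure_python_oracle(self, best_combo, balanced_params):
        """Same transcription, two implementations: results must coincide."""
        t_grid = np.array([0.0, 1.0, 3.0])
        slow = rk4_fixed(BASELINE.to_array(), t_grid, balanced_params.to_dict(),
                         best_combo.a, best_combo.b, best_combo.c, dt=1e-3)
        fast = rk4_fixed_compiled(BASELINE.to_array(), t_grid,
                                  balanced_params.to_dict(),
                                  best_combo.a, best_combo.b, best_combo.c, dt=1e-3)
        scale = np.maximum(np.abs(slow), 1.0)
        assert (np.abs(slow - fast) / scale).max() < 1e-12

    def test_adaptive_matches_scipy_solve_ivp(self, best_combo, balanced_params):
        """Independent library cross-check of the in-package integrator."""
        from scipy.integrate import solve_ivp

        t_grid = np.array([0.0, 1.0, 3.0, 7.0, 14.0])
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, t_grid)

        def f(t, y):
            return evaluate_rhs(ModelState(**dict(zip(VARIABLES, np.maximum(y, 0.0)))),
                                balanced_params, best_combo)

        sol = solve_ivp(f, (0.0, 14.0), BASELINE.to_array(), method="RK45",
                        t_eval=t_grid, rtol=1e-8, atol=1e-8)
        assert sol.success
        ref = sol.y.T
        scale = np.maximum(np.abs(ref), 1e-6 * np.maximum(np.abs(ref).max(axis=0), 1.0))
        assert (np.abs(traj.states - ref) / scale).max() < 1e-3

    @pytest.mark.parametrize("combo", enumerate_combinations(), ids=lambda c: c.name)
    def test_stiff_solver_agrees_with_explicit_solver(self, combo, table_params):
        """Rosenbrock 2(3) and Dormand-Prince agree across the model space."""
        params = balanced(table_params, combo)
        t_grid = np.linspace(0, 14, 29)
        a = simulate_trajectory(BASELINE, params, combo, t_grid, method="dopri45")
        b = simulate_trajectory(BASELINE, params, combo, t_grid,
                                method="rosenbrock23")
        scale = np.maximum(np.abs(a.states), 1.0)
        # the Rosenbrock method is 2nd order: global error ~ rtol^(2/3)
        assert (np.abs(a.states - b.states) / scale).max() < 0.05

    def test_stiff_solver_matches_fixed_step_rk4(self, best_combo, balanced_params):
        t_grid = np.array([0.0, 1.0, 3.0, 7.0, 14.0])
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, t_grid,
                                   method="rosenbrock23", rtol=1e-8, atol=1e-10)
        oracle = rk4_fixed(BASELINE.to_array(), t_grid, balanced_params.to_dict(),
                           best_combo.a, best_combo.b, best_combo.c, dt=1e-3)
        scale = np.maximum(np.abs(oracle), 1e-6 * np.maximum(np.abs(oracle).max(axis=0), 1.0))
        assert (np.abs(traj.states - oracle) / scale).max() < 1e-3

    def test_unknown_method_rejected(self, best_combo, balanced_params):
        with pytest.raises(DomainError):
            simulate_trajectory(BASELINE, balanced_params, best_combo,
                                [0.0, 1.0], method="euler")

    def test_bad_grid_rejected(self, best_combo, balanced_params):
        with pytest.raises(DomainError):
            simulate_trajectory(BASELINE, balanced_params, best_combo, [1.0, 2.0])
        with pytest.raises(DomainError):
            simulate_trajectory(BASELINE, balanced_params, best_combo, [0.0, 2.0, 1.0])

    def test_trajectory_frame_round_trip(self, best_combo, balanced_params):
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, [0.0, 7.0, 14.0])
        back = Trajectory.from_frame(traj.to_frame(), best_combo)
        np.testing.assert_array_equal(back.states, traj.states)
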