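"""Objectives, residuals, AIC, optimizer contracts and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from osteomac import (
    BASELINE,
    FitResult,
    HypothesisCombination,
    OptimizerSettings,
    ParameterSet,
    compute_aic,
    count_residuals_below_one,
    fit_model,
    objective_J2,
    objective_Jinf,
    rank_models,
    residual_matrix,
    simulate_trajectory,
)
from osteomac.dataset import TimeCourseDataset
from osteomac.errors import ConfigurationError
from osteomac.hypotheses import ParameterManifest, parameter_manifest
from osteomac.state import OBSERVED_VARIABLES, VARIABLES


def _dataset_from_trajectory(traj, cv=0.05):
    """Summary dataset whose means are the trajectory itself (perfect model)."""
    cols = list(OBSERVED_VARIABLES)
    idx = [VARIABLES.index(v) for v in cols]
    means = pd.DataFrame(traj.states[:, idx], index=traj.times, columns=cols)
    sds = np.maximum(means.abs() * cv, 1e-6)
    return TimeCourseDataset(means=means, sds=sds)


class TestResiduals:
    def test_perfect_model_gives_zero_matrix(self, best_combo, balanced_params):
        t = np.array([0.0, 1.0, 2.0, 3.0, 7.0, 14.0])
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, t)
        ds = _dataset_from_trajectory(traj)
        r = residual_matrix(traj, ds)
        np.testing.assert_allclose(r.to_numpy(), 0.0, atol=1e-12)
        assert r.shape == (5, 8)

    def test_hand_computed_standardization(self, best_combo, balanced_params):
        t = np.array([0.0, 1.0, 2.0])
        traj = simulate_trajectory(BASELINE, balanced_params, best_combo, t)
        ds = _dataset_from_trajectory(traj)
        # shift one variable's data by known amounts with known sigmas
        ds.means.loc[1.0, "OB"] = traj.get("OB")[1] - 2.0
        ds.sds.loc[1.0, "OB"] = 1.0
        ds.means.loc[2.0, "OB"] = traj.get("OB")[2] + 3.0
        ds.sds.loc[2.0, "OB"] = 3.0
        r = residual_matrix(traj, ds)
        assert r.loc[1.0, "OB"] == pytest.approx(2.0, abs=1e-9)
        assert r.loc[2.0, "OB"] == pytest.approx(-1.0, abs=1e-9)

    def test_default_design_has_forty_cells(self, synthetic_dataset):
        assert synthetic_dataset.n_residual_cells == 40


class TestObjectives:
    def test_hand_computed_values(self):
        r = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.0]])  # 3 times x 2 vars
        assert objective_J2(r) == pytest.approx(14.0)
        assert objective_Jinf(r) == pytest.approx(9.0)

    def test_zero_matrix(self):
        r = np.zeros((5, 8))
        assert objective_J2(r) == 0.0
        assert objective_Jinf(r) == 0.0
        assert count_residuals_below_one(r) == 40

    def test_single_variable_reduces_to_weighted_ssr(self):
        r = np.array([[0.5], [1.5], [-2.0]])
        assert objective_J2(r) == pytest.approx(0.25 + 2.25 + 4.0)

    @given(arrays(np.float64, (5, 8), elements=st.floats(-50, 50)))
    @settings(max_examples=200, deadline=None)
    def test_j2_dominates_jinf(self, r):
        assert objective_J2(r) >= objective_Jinf(r) >= 0.0

    def test_aic_formula(self):
        assert compute_aic(6.5, 13) == 39.0
        assert compute_aic(0.0, 0) == 0.0

    def test_aic_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            compute_aic(-1.0, 3)
        with pytest.raises(ConfigurationError):
            compute_aic(1.0, -2)

    def test_count_is_strict(self):
        r = np.array([[0.5, 1.0, 1.5, 0.99]])
        assert count_residuals_below_one(r) == 2


class TestFitModel:
    def test_zero_free_parameters_short_circuits(self, best_combo, synthetic_dataset):
        manifest = ParameterManifest(combo=best_combo, free=(),
                                     fixed=("delta_Mo", "delta_M", "delta_OC"),
                                     derived=("H_Mo", "H_M", "H_OB", "d_OC", "Pi_B"))
        res = fit_model(best_combo, synthetic_dataset, manifest, "J2",
                        OptimizerSettings(seed=1))
        assert res.p == 0
        assert res.AIC_J2 == pytest.approx(2 * res.J2)
        assert len(res.trace) == 1

    def test_two_parameter_recovery_smoke(self, best_combo, balanced_params, synthetic_dataset):
        manifest = ParameterManifest(
            combo=best_combo, free=("gamma_OB", "delta_D"),
            fixed=("delta_Mo", "delta_M", "delta_OC"),
            derived=("H_Mo", "H_M", "H_OB", "d_OC", "Pi_B"))
        res = fit_model(best_combo, synthetic_dataset, manifest, "J2",
                        OptimizerSettings(seed=3, restarts=2, maxiter=200),
                        start=balanced_params)
        assert res.p == 2
        assert np.isfinite(res.J2)
        assert res.AIC_J2 == pytest.approx(2 * 2 + 2 * res.J2)
        # best-so-far trace is non-increasing by construction
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))
        assert res.J2 >= res.J_inf

    def test_same_seed_bitwise_reproducible(self, best_combo, balanced_params, synthetic_dataset):
        manifest = ParameterManifest(
            combo=best_combo, free=("gamma_OB", "delta_D"),
            fixed=("delta_Mo", "delta_M", "delta_OC"),
            derived=("H_Mo", "H_M", "H_OB", "d_OC", "Pi_B"))
        kwargs = dict(settings=OptimizerSettings(seed=11, restarts=2, maxiter=60),
                      start=balanced_params)
        r1 = fit_model(best_combo, synthetic_dataset, manifest, "J2", **kwargs)
        r2 = fit_model(best_combo, synthetic_dataset, manifest, "J2", **kwargs)
        assert r1.params.to_dict() == r2.params.to_dict()
        assert r1.J2 == r2.J2


class TestRanking:
    def _fit(self, name, aic_j2, n_lt1, p=3):
        combo = HypothesisCombination.from_name(name)
        J2 = (aic_j2 - 2 * p) / 2
        r = np.zeros((5, 8))
        r[0, 0] = np.sqrt(J2)
        res = FitResult.from_residuals(combo, ParameterSet(),
                                       pd.DataFrame(r), p, "J2", [J2], 0)
        res.n_below_one = n_lt1  # override for tie-break scenarios
        return res

    def test_sorted_ascending_by_aic(self):
        fits = [self._fit("a1b1c1", 45, 10), self._fit("a3b2c2", 39, 25),
                self._fit("a2b1c3", 42, 15)]
        table = rank_models(fits)
        assert list(table["combo"]) == ["a3b2c2", "a2b1c3", "a1b1c1"]

    def test_tie_breaks_by_residual_count_then_name(self):
        fits = [self._fit("a1b1c1", 40, 15), self._fit("a1b2c1", 40, 25),
                self._fit("a1b1c2", 40, 15)]
        table = rank_models(fits)
        assert list(table["combo"]) == ["a1b2c1", "a1b1c1", "a1b1c2"]

    def test_duplicate_combo_rejected(self):
        fits = [self._fit("a1b1c1", 40, 15), self._fit("a1b1c1", 41, 15)]
        with pytest.raises(ConfigurationError):
            rank_models(fits)

    def test_aic_identity_holds_for_every_fit(self):
        fits = [self._fit("a1b1c1", 45, 10), self._fit("a3b2c2", 39, 25)]
        for f in fits:
            assert f.AIC_J2 == pytest.approx(2 * f.p + 2 * f.J2)
            assert f.AIC_Jinf == pytest.approx(2 * f.p + 2 * f.J_inf)
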