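import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcmap import apc_crv
from apcmap.apc_crv import (APCEffects, APCGrid, build_apc_grid, curvatures,
                            drift_reallocate, fit_apc_reference, net_drift,
                            poisson_deviance, relative_variation, solve_crv)
from apcmap.core_tables import ValidationError
from apcmap.synthetic import generate_crv_grid


def _tables_for_grid():
    """Banded incidence/person-years tables covering 30-84 x 1997-2016."""
    rows_i, rows_p = [], []
    for a in range(11):
        for y in range(1997, 2017):
            rows_p.append({"sex": "male", "area_id": "x", "year": y,
                           "age_group": a, "person_years": 10_000.0})
            rows_i.append({"sex": "male", "histology": "adenocarcinoma",
                           "area_id": "x", "year": y, "age_group": a,
                           "count": 3})
    return pd.DataFrame(rows_i), pd.DataFrame(rows_p)


class TestGridConstruction:
    def test_standard_design_44_cells_14_cohorts(self):
        inc, py = _tables_for_grid()
        grid = build_apc_grid(inc, py)
        assert grid.counts.size == 44
        assert grid.n_cohorts == 14
        years = grid.cohort_median_years
        assert np.allclose(years, np.arange(1917, 1983, 5))

    def test_oldest_cell_maps_to_1917_cohort(self):
        inc, py = _tables_for_grid()
        grid = build_apc_grid(inc, py)
        c = grid.cohort_index(a=10, p=0)  # ages 80-84, period 1997-2001
        assert grid.cohort_median_years[c] == pytest.approx(1999 - 82)

    def test_single_cell_grid_has_one_cohort(self):
        inc, py = _tables_for_grid()
        grid = build_apc_grid(inc, py, age_range=(30, 34),
                              period_range=(1997, 2001))
        assert grid.counts.shape == (1, 1) and grid.n_cohorts == 1

    def test_out_of_range_records_excluded(self):
        inc, py = _tables_for_grid()
        extra = pd.DataFrame([{"sex": "male", "histology": "adenocarcinoma",
                               "area_id": "x", "year": 2030, "age_group": 3,
                               "count": 99}])
        grid = build_apc_grid(pd.concat([inc, extra]), py)
        assert grid.counts.sum() == inc["count"].sum()

    def test_empty_grid_rejected(self):
        inc, py = _tables_for_grid()
        with pytest.raises(ValidationError, match="empty"):
            build_apc_grid(inc.iloc[:0], py.iloc[:0])


def _pure_age_grid():
    """Noise-free counts from an age-only model (expected values as counts)."""
    A, P = 11, 4
    alpha = np.linspace(-1.5, 1.5, A)
    alpha -= alpha.mean()
    N = np.full((A, P), 1e6)
    mu = np.log(50e-5)
    O = N * np.exp(mu + alpha[:, None])
    return APCGrid(counts=O, person_years=N,
                   age_midpoints=np.arange(32, 85, 5.0),
                   period_midpoints=np.arange(1999, 2015, 5.0))


class TestReferenceFit:
    def test_pure_age_model_has_null_period_cohort_effects(self):
        eff = fit_apc_reference(_pure_age_grid())
        assert np.abs(eff.pi).max() < 1e-6
        assert np.abs(eff.gamma).max() < 1e-6
        assert np.abs(curvatures(eff.pi)).max() < 1e-6

    def test_saturated_2x2_fit_matches_observed_and_irls_free_oracle(self, rng):
        """On a 2x2 grid the model is saturated: fitted counts equal the
        observed ones, which a direct per-cell solve confirms."""
        N = np.array([[1e4, 2e4], [3e4, 1.5e4]])
        O = rng.poisson(N * 40e-5).astype(float)
        grid = APCGrid(counts=O, person_years=N,
                       age_midpoints=np.array([32.0, 37.0]),
                       period_midpoints=np.array([1999.0, 2004.0]))
        eff = fit_apc_reference(grid)
        fitted = N * np.exp(eff.fitted_log_rates())
        # saturated-model oracle: each cell's Poisson MLE is O itself
        assert np.allclose(fitted, O, rtol=1e-6)
        assert poisson_deviance(grid, eff) < 1e-8

    def test_zero_person_years_cell_rejected(self):
        grid = _pure_age_grid()
        grid.person_years[0, 0] = 0.0
        with pytest.raises(ValidationError):
            fit_apc_reference(grid)


@pytest.fixture(scope="module")
def fitted():
    grid, _ = generate_crv_grid(person_years_per_cell=1e6, seed=3)
    return grid, fit_apc_reference(grid)


class TestDriftReallocation:
    def test_identity_at_zero(self, fitted):
        _, eff = fitted
        out = drift_reallocate(eff, 0.0)
        assert np.allclose(out.alpha, eff.alpha)
        assert np.allclose(out.pi, eff.pi)
        assert np.allclose(out.gamma, eff.gamma)

    @pytest.mark.parametrize("delta", [-0.1, -0.01, 0.02, 0.3])
    def test_fitted_rates_invariant(self, fitted, delta):
        _, eff = fitted
        out = drift_reallocate(eff, delta)
        assert np.abs(out.fitted_log_rates() - eff.fitted_log_rates()).max() < 1e-10

    @pytest.mark.parametrize("delta", [-0.05, 0.02, 0.2])
    def test_deviance_flat_along_reallocation(self, fitted, delta):
        grid, eff = fitted
        d0 = poisson_deviance(grid, eff)
        d1 = poisson_deviance(grid, drift_reallocate(eff, delta))
        assert abs(d1 - d0) < 1e-8

    def test_involution(self, fitted):
        _, eff = fitted
        back = drift_reallocate(drift_reallocate(eff, 0.07), -0.07)
        assert np.allclose(back.alpha, eff.alpha, atol=1e-12)
        assert np.allclose(back.gamma, eff.gamma, atol=1e-12)

    def test_curvatures_invariant_exactly(self, fitted):
        _, eff = fitted
        out = drift_reallocate(eff, 0.11)
        assert np.allclose(curvatures(out.pi), curvatures(eff.pi), atol=1e-12)
        assert np.allclose(curvatures(out.gamma), curvatures(eff.gamma), atol=1e-12)

    def test_zero_sum_preserved(self, fitted):
        _, eff = fitted
        out = drift_reallocate(eff, 0.13)
        assert abs(out.pi.sum()) < 1e-10 and abs(out.gamma.sum()) < 1e-10


class TestRelativeVariation:
    def test_null_effects_have_zero_rv(self):
        assert relative_variation(np.zeros(5)) == 0.0

    def test_hand_computed_cv(self):
        # exp(effects) = {1, 3}: population SD 1, mean 2 -> CV 0.5
        assert relative_variation(np.log([1.0, 3.0])) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-3, 3))
    def test_shift_invariance(self, c):
        v = np.array([0.0, 0.2, -0.4, 0.1])
        assert relative_variation(v + c) == pytest.approx(
            relative_variation(v), rel=1e-9)

    def test_needs_two_effects(self):
        with pytest.raises(ValidationError):
            relative_variation(np.array([0.3]))


class TestSolveCRV:
    def test_recovery_under_crv_condition(self):
        grid, truth = generate_crv_grid(person_years_per_cell=1e8, seed=0)
        res = solve_crv(grid)
        assert np.abs(res.effects.alpha - truth.alpha).max() < 0.02
        assert np.abs(res.effects.pi - truth.pi).max() < 0.02
        assert np.abs(res.effects.gamma - truth.gamma).max() < 0.02
        # balanced by construction
        assert relative_variation(res.effects.pi) == pytest.approx(
            relative_variation(res.effects.gamma), abs=1e-7)

    def test_bracket_endpoints_have_opposite_rv_gaps(self):
        grid, _ = generate_crv_grid(person_years_per_cell=1e8, seed=4)
        ref = fit_apc_reference(grid)
        nu = net_drift(ref)
        gap = lambda d: (relative_variation(drift_reallocate(ref, d).pi)
                         - relative_variation(drift_reallocate(ref, d).gamma))
        lo, hi = sorted((0.0, nu))
        assert gap(lo) * gap(hi) < 0

    def test_pure_age_model_is_degenerate_null(self):
        res = solve_crv(_pure_age_grid())
        assert res.delta_star == pytest.approx(0.0, abs=1e-8)
        assert np.abs(res.effects.pi).max() < 1e-6
        assert np.abs(res.effects.gamma).max() < 1e-6

    def test_profile_diagnostic_shape(self):
        grid, _ = generate_crv_grid(person_years_per_cell=1e6, seed=5)
        res = solve_crv(grid)
        assert set(res.profile.columns) == {"delta", "rv_period", "rv_cohort"}
        assert len(res.profile) > 10


def test_bootstrap_bands_cover_point_estimates():
    grid, _ = generate_crv_grid(person_years_per_cell=1e7, seed=6)
    res = solve_crv(grid)
    bands = apc_crv.bootstrap_bands(grid, res, n_boot=30, seed=1)
    assert bands["n_used"][0] > 20
    inside = np.mean((bands["gamma_low"] <= res.effects.gamma)
                     & (res.effects.gamma <= bands["gamma_high"]))
    assert inside > 0.8
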