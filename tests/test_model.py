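"""Grid, trajectory recurrence, aging rate and the reference series."""

import numpy as np
import pytest

from cardioage.model import (AgingModel, GridSpec, build_trajectories,
                             exact_series, grid_from_profile,
                             load_trajectories, rhs, rhs_nodes)
from conftest import make_model, toy_set


class TestGridSpec:
    def test_profiles(self):
        fine = grid_from_profile("fine_dx")
        assert (fine.dt, fine.dx, fine.n_steps) == (0.01, 0.001, 100)
        coarse = grid_from_profile("coarse_dx")
        assert (coarse.dt, coarse.dx, coarse.n_steps) == (0.01, 0.01, 100)
        with pytest.raises(KeyError, match="unknown grid profile"):
            grid_from_profile("nope")

    def test_validation(self):
        with pytest.raises(ValueError, match="dt"):
            GridSpec(dt=1.5, n_steps=100, interval=(0, 150))
        with pytest.raises(ValueError, match="N\\*dt"):
            GridSpec(dt=0.01, n_steps=99)
        with pytest.raises(ValueError, match="dx"):
            GridSpec(dx=-0.01)

    def test_times(self):
        g = GridSpec(dt=0.25, dx=0.0, n_steps=4)
        assert np.allclose(g.times(), [0, 0.25, 0.5, 0.75, 1.0])


class TestBuildTrajectories:
    def test_step_index_unrolls_by_hand(self):
        # P(n) = P(n-1) + n*dx: 1, 1.01, 1.03, 1.06 at dx = 0.01
        g = GridSpec(dt=1 / 3, dx=0.01, n_steps=3)
        t = build_trajectories(g, ["P"], increment_rule="step_index")
        assert np.allclose(t.values["P"], [1.0, 1.01, 1.03, 1.06],
                           atol=1e-15)

    def test_unit_rule_linear(self, default_grid):
        t = build_trajectories(default_grid, ["P"], increment_rule="unit")
        n = np.arange(101)
        assert np.allclose(t.values["P"], 1.0 + 0.001 * n, atol=1e-15)

    def test_zero_dx_constant_one(self, constant_grid):
        t = build_trajectories(constant_grid, ["P", "Q"])
        for v in t.values.values():
            assert np.all(v == 1.0)

    def test_boundary_value(self, default_grid):
        for rule in ("unit", "step_index"):
            t = build_trajectories(default_grid, ["P"], rule)
            assert t.values["P"][0] == 1.0

    def test_errors(self, default_grid):
        with pytest.raises(ValueError, match="non-empty"):
            build_trajectories(default_grid, [])
        with pytest.raises(ValueError, match="increment_rule"):
            build_trajectories(default_grid, ["P"], "quadratic")

    def test_csv_round_trip(self, tmp_path, default_grid):
        t = build_trajectories(default_grid, ["P", "Q"], "step_index")
        path = tmp_path / "traj.csv"
        t.save(path)
        back = load_trajectories(path, default_grid)
        assert back.construction == "external"
        for name in ("P", "Q"):
            assert np.allclose(back.values[name], t.values[name], atol=0)


class TestRHS:
    def test_unit_trajectories_give_coefficient_sum(self, constant_model):
        # all trajectory values 1: rate = 0.39+0.37+0.36+0.32+0.29+0.30
        for n in (0, 50, 100):
            assert rhs(constant_model, n) == pytest.approx(2.03, abs=1e-12)

    def test_zero_coefficients(self, constant_grid):
        m = make_model(toy_set([0.0, 0.0]), constant_grid)
        assert all(rhs(m, n) == 0.0 for n in range(101))

    def test_zero_trajectories_annihilate(self, all_fixture_sets,
                                          constant_grid):
        iset = all_fixture_sets[(1, "A")]
        traj = build_trajectories(constant_grid, iset.parameter_names())
        for v in traj.values.values():
            v[:] = 0.0
        m = AgingModel(iset, traj)
        assert rhs(m, 0) == 0.0
        assert np.all(rhs_nodes(m) == 0.0)

    def test_index_out_of_range(self, constant_model):
        with pytest.raises(IndexError):
            rhs(constant_model, 101)
        with pytest.raises(IndexError):
            rhs(constant_model, -1)

    def test_missing_trajectory_rejected(self, all_fixture_sets,
                                         constant_grid):
        traj = build_trajectories(constant_grid, ["BMI"])
        with pytest.raises(ValueError, match="without trajectories"):
            AgingModel(all_fixture_sets[(1, "A")], traj)


class TestExactSeries:
    def test_starts_at_zero(self, default_model):
        for ref in ("integral", "product", "cumulative_left"):
            assert exact_series(default_model, reference=ref).values[0] == 0.0

    def test_constant_trajectories_linear_terminal_value(self,
                                                         constant_model):
        # rate constant at 2.03; integral over [0,1] = 2.03
        s = exact_series(constant_model)
        assert s.values[-1] == pytest.approx(2.03, abs=1e-12)
        # exactly linear in n: vanishing second differences
        assert np.all(np.abs(np.diff(s.values, 2)) < 1e-15)
        assert s.method == "exact"

    def test_zero_coefficients_zero_series(self, constant_grid):
        m = make_model(toy_set([0.0, 0.0, 0.0]), constant_grid)
        for ref in ("integral", "product", "cumulative_left"):
            assert np.all(exact_series(m, reference=ref).values == 0.0)

    def test_product_reference_formula(self, default_model):
        s = exact_series(default_model, reference="product")
        b = rhs_nodes(default_model)
        n = np.arange(101)
        assert np.allclose(s.values, 0.01 * n * b, atol=0)

    def test_cumulative_left_reference(self, default_model):
        s = exact_series(default_model, reference="cumulative_left")
        b = rhs_nodes(default_model)
        manual = np.concatenate([[0.0], np.cumsum(0.01 * b[:-1])])
        assert np.allclose(s.values, manual, atol=0)

    def test_integral_matches_closed_form_polynomial(self, default_model):
        """Against an independently derived closed form: with the unit rule
        every trajectory is p(t) = 1 + (dx/dt) t, so the integral of
        S p(t)^2 is S[(1+ct)^3 - 1]/(3c)."""
        S = 2.03
        c = 0.001 / 0.01
        t = default_model.grid.times()
        closed = S * ((1 + c * t) ** 3 - 1) / (3 * c)
        s = exact_series(default_model)
        assert np.allclose(s.values, closed, atol=1e-13)

    def test_unknown_reference(self, default_model):
        with pytest.raises(ValueError, match="reference"):
            exact_series(default_model, reference="riemann")
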