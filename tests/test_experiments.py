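"""Tests for parameter sweeps, regional trends, convergence timing and
disparity profiles."""

import math
from dataclasses import replace

import numpy as np
import pytest

from twopatch import (
    ConservedTotal,
    SweepConfig,
    SystemState,
    covary_disparity_minimum,
    disparity_profile,
    regional_resource_trend,
    run_sweep,
    simulate,
    time_to_equilibrium,
)
from twopatch.equilibria import equilibrium_no_demography
from twopatch.experiments import (
    SWEEP_COLUMNS,
    build_grid,
    default_convergence_init,
)


@pytest.fixture(scope="module")
def fig1_table(presets):
    return run_sweep(presets["fig1"].sweep_config())


@pytest.fixture(scope="module")
def fig3_table(presets):
    return run_sweep(presets["fig3"].sweep_config())


@pytest.fixture(scope="module")
def fig4_table(presets):
    return run_sweep(presets["fig4"].sweep_config())


@pytest.fixture(scope="module")
def fig5_table(presets):
    return run_sweep(presets["fig5"].sweep_config())


class TestPresets:
    def test_all_scenarios_shipped(self, presets):
        assert set(presets) == {
            "fig1", "fig2_solid", "fig2_dashed", "fig2_dotted",
            "fig3", "fig4", "fig5",
        }

    def test_fig1_is_demography_free_with_total_15(self, presets):
        p = presets["fig1"]
        assert p.params.p == 0
        assert p.total == ConservedTotal(15.0)

    def test_level_values(self, presets):
        assert presets["fig3"].levels == (0.1, 10.0, 1000.0)
        assert presets["fig4"].levels == (0.01, 0.1, 1.0)
        assert presets["fig5"].levels == (0.1, 1.0, 10.0)
        assert presets["fig3"].params.p == 1

    def test_shared_demographic_core(self, presets):
        p = presets["fig3"].params
        assert (p.high.r, p.low.r, p.high.K, p.low.K) == (2, 1, 100, 50)
        assert (p.alpha, p.c, p.mu) == (0.05, 0.05, 0.1)


class TestSweepMechanics:
    def test_table_shape_and_header(self, fig3_table, presets):
        p = presets["fig3"]
        assert list(fig3_table.columns) == SWEEP_COLUMNS
        assert len(fig3_table) == len(p.grid) * len(p.levels)

    def test_rows_ordered_by_level_then_grid(self, fig3_table):
        key = list(zip(fig3_table.level_value, fig3_table.swept_value))
        assert key == sorted(key)

    def test_all_rows_positive_and_stable(self, fig3_table, fig4_table, fig5_table):
        for table in (fig3_table, fig4_table, fig5_table):
            assert table.stable.all()
            assert (table[["R_H", "R_L", "C_H", "C_L"]].to_numpy() >= 0).all()
            assert (table.residual < 1e-8).all()

    def test_zero_mobility_rows_match_closed_form(self, fig3_table):
        first = fig3_table[fig3_table.swept_value == 0.0]
        assert len(first) == 3  # one per lambda level
        for _, row in first.iterrows():
            assert row.R_H == pytest.approx(40.0, rel=1e-10)
            assert row.C_H == pytest.approx(24.0, rel=1e-10)
            assert row.C_L == pytest.approx(4.0, rel=1e-10)

    def test_scenario_requires_matching_demography(self, presets):
        with pytest.raises(ValueError, match="p = 0"):
            SweepConfig(
                scenario="vary_lambda_p0",
                base_params=presets["fig3"].params,  # p = 1
                grid=np.array([0.0, 1.0]),
                fixed_levels=(1.0,),
                total=ConservedTotal(15.0),
            )
        with pytest.raises(ValueError, match="C_T"):
            SweepConfig(
                scenario="vary_lambda_p0",
                base_params=presets["fig1"].params,
                grid=np.array([0.0, 1.0]),
                fixed_levels=(1.0,),
            )

    def test_grid_must_increase(self, presets):
        with pytest.raises(ValueError, match="increasing"):
            SweepConfig(
                scenario="covary_p1",
                base_params=presets["fig5"].params,
                grid=np.array([1.0, 1.0, 2.0]),
                fixed_levels=(1.0,),
            )

    def test_build_grid_spacings(self):
        lin = build_grid(0.0, 10.0, 50)
        assert lin.size == 50 and lin[0] == 0.0 and lin[-1] == 10.0
        log = build_grid(0.01, 20.0, 50, spacing="log", include_zero=True)
        assert log.size == 51 and log[0] == 0.0 and log[-1] == pytest.approx(20.0)
        with pytest.raises(ValueError):
            build_grid(0.0, 1.0, 10, spacing="log")


class TestFig1Reproduction:
    def test_mean_consumer_density_conserved(self, fig1_table):
        assert fig1_table.mean_C.to_numpy() == pytest.approx(15.0, abs=1e-10)

    def test_zero_sensitivity_intercept(self, fig1_table):
        row = fig1_table[fig1_table.swept_value == 0.0].iloc[0]
        assert row.C_H == pytest.approx(15.0, abs=1e-9)
        assert row.C_L == pytest.approx(15.0, abs=1e-9)

    def test_consumers_accumulate_in_high_patch_with_sensitivity(self, fig1_table):
        t = fig1_table.sort_values("swept_value")
        assert np.all(np.diff(t.C_H) >= -1e-10)
        assert np.all(np.diff(t.C_L) <= 1e-10)
        # plateau: the local slope dC_H/dlam collapses across the grid
        lam = t.swept_value.to_numpy()
        CH = t.C_H.to_numpy()
        slope_start = (CH[1] - CH[0]) / (lam[1] - lam[0])
        slope_end = (CH[-1] - CH[-2]) / (lam[-1] - lam[-2])
        assert slope_end < 0.1 * slope_start


class TestFig2RegionalTrichotomy:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("fig2_solid", "constant"),
            ("fig2_dashed", "increasing"),
            ("fig2_dotted", "decreasing"),
        ],
    )
    def test_r_over_K_classification(self, presets, name, expected):
        assert regional_resource_trend(presets[name].params) == expected

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("fig2_solid", "constant"),
            ("fig2_dashed", "increasing"),
            ("fig2_dotted", "decreasing"),
        ],
    )
    def test_mean_resource_column_matches_prediction(self, presets, name, expected):
        table = run_sweep(presets[name].sweep_config()).sort_values("swept_value")
        mr = table.mean_R.to_numpy()
        if expected == "constant":
            assert mr.max() - mr.min() < 1e-6
        elif expected == "increasing":
            assert np.all(np.diff(mr) > 0)
        else:
            assert np.all(np.diff(mr) < 0)

    def test_demographic_parameters_rejected(self, presets):
        with pytest.raises(ValueError):
            regional_resource_trend(presets["fig3"].params)


class TestFig3Fig4Directions:
    def test_mobility_homogenizes_consumers(self, fig3_table):
        for _, sub in fig3_table.groupby("level_value"):
            dC = (sub.sort_values("swept_value").C_H
                  - sub.sort_values("swept_value").C_L).to_numpy()
            assert np.all(np.diff(dC) <= 1e-10)

    def test_sensitivity_segregates_consumers(self, fig4_table):
        for _, sub in fig4_table.groupby("level_value"):
            dC = (sub.sort_values("swept_value").C_H
                  - sub.sort_values("swept_value").C_L).to_numpy()
            assert np.all(np.diff(dC) >= -1e-10)

    def test_sensitivity_effect_grows_with_mobility(self, fig4_table):
        # the lambda-induced change in C_H between grid endpoints widens
        # as the mobility level increases
        shifts = {}
        for level, sub in fig4_table.groupby("level_value"):
            sub = sub.sort_values("swept_value")
            shifts[level] = sub.C_H.iloc[-1] - sub.C_H.iloc[0]
        levels = sorted(shifts)
        assert shifts[levels[0]] < shifts[levels[1]] < shifts[levels[2]]


class TestFig5Unimodality:
    def test_consumer_disparity_has_interior_minimum(self, fig5_table):
        prof = disparity_profile(fig5_table)
        for level, frame in prof.series.items():
            grid = frame.swept_value.to_numpy()
            i = int(np.argmin(frame.dC.to_numpy()))
            # the dip is not at the right edge: disparity recovers at
            # high movement (for gamma=10 it sits at the smallest beta
            # sampled, with the true turning point below it)
            assert grid[i] < grid[-1]
            assert frame.dC.iloc[-1] > frame.dC.min()

    def test_consumers_and_resources_move_oppositely(self, fig5_table):
        prof = disparity_profile(fig5_table)
        ex = prof.extrema.set_index(["level_value", "series"])
        for level in (0.1, 1.0):
            # where the consumer disparity bottoms out, the resource
            # disparity peaks (same interior grid location)
            assert (ex.loc[(level, "dC"), "argmin_swept"]
                    == ex.loc[(level, "dR"), "argmax_swept"])

    def test_refined_minimum_location_decreases_with_gamma(self, presets):
        params = presets["fig5"].params
        locs = {g: covary_disparity_minimum(params, g)[0] for g in (0.1, 1.0, 10.0)}
        assert locs[10.0] < locs[1.0] < locs[0.1]
        # stronger coupling turns the system back toward fitness-directed
        # behaviour sooner
        assert locs[10.0] <= 2.0


class TestConvergenceTime:
    def test_zero_at_the_equilibrium_itself(self, fig1_params, fig1_total):
        params = replace(fig1_params, beta=1.0, lam=1.0)
        eq = equilibrium_no_demography(params, fig1_total).state
        assert time_to_equilibrium(params, eq, fig1_total) == 0.0

    def test_faster_convergence_at_higher_mobility(self, fig1_params, fig1_total):
        times = []
        for beta in (0.1, 1.0, 10.0):
            params = replace(fig1_params, beta=beta, lam=1.0)
            init = default_convergence_init(params, fig1_total)
            times.append(time_to_equilibrium(params, init, fig1_total))
        assert times[0] > times[1] > times[2]
        assert all(math.isfinite(t) for t in times)

    @pytest.mark.parametrize("beta", [0.5, 1.0])
    def test_random_movement_gap_decays_at_rate_2beta(self, fig1_params, beta):
        # with lam = 0 the consumer subsystem decouples from the
        # resources: d(C_H - C_L)/dt = -2 beta (C_H - C_L), so the gap
        # follows the closed form g0 * exp(-2 beta t) exactly
        params = replace(fig1_params, beta=beta, lam=0.0)
        init = SystemState(50.0, 25.0, 27.0, 3.0)
        t_eval = np.linspace(0.0, 3.0, 7)
        sol = simulate(params, init, 3.0, t_eval=t_eval)
        gap = sol.y[2] - sol.y[3]
        expected = 24.0 * np.exp(-2.0 * beta * t_eval)
        assert gap == pytest.approx(expected, rel=1e-7)

    def test_epsilon_validated(self, fig1_params, fig1_total):
        params = replace(fig1_params, beta=1.0, lam=1.0)
        init = default_convergence_init(params, fig1_total)
        with pytest.raises(ValueError):
            time_to_equilibrium(params, init, fig1_total, epsilon=0.0)
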