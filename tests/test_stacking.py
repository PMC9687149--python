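"""Dimensional stacking: coordinates, objective, axis-order optimization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alternanspop.ionic import CHANNELS, LEVELS, ScenarioCode
from alternanspop.stacking import (
    AxisOrder,
    build_grid,
    map_objective,
    optimize_axis_order,
    stack_coordinates,
)
from alternanspop.synthetic import PlantedFieldSpec, synth_scalar_field


FULL_ORDER = AxisOrder(CHANNELS)


class TestStackCoordinates:
    def test_all_low_maps_to_origin(self):
        code = ScenarioCode.from_levels([0.5] * 10)
        assert stack_coordinates(code, FULL_ORDER) == (0, 0)

    def test_innermost_x_channel_has_stride_one(self):
        base = {ch: 0.5 for ch in CHANNELS}
        x0, y0 = stack_coordinates(base, FULL_ORDER)
        bumped = dict(base)
        bumped[FULL_ORDER.x_channels[-1]] = 1.0
        x1, y1 = stack_coordinates(bumped, FULL_ORDER)
        assert (x1 - x0, y1 - y0) == (1, 0)

    def test_outermost_strides(self):
        base = {ch: 0.5 for ch in CHANNELS}
        for chans, expect in [
            (FULL_ORDER.x_channels, (81, 0)),
            (FULL_ORDER.y_channels, (0, 81)),
        ]:
            bumped = dict(base)
            bumped[chans[0]] = 1.0
            assert stack_coordinates(bumped, FULL_ORDER) == expect

    def test_bijection_over_full_factorial(self):
        # every scenario owns exactly one pixel of the 243x243 grid
        digits = np.indices((3,) * 10).reshape(10, -1).T
        levels = np.array(LEVELS)[digits]
        xs = np.zeros(len(levels), dtype=int)
        ys = np.zeros(len(levels), dtype=int)
        x_idx = [CHANNELS.index(ch) for ch in FULL_ORDER.x_channels]
        y_idx = [CHANNELS.index(ch) for ch in FULL_ORDER.y_channels]
        for k in x_idx:
            xs = xs * 3 + digits[:, k]
        for k in y_idx:
            ys = ys * 3 + digits[:, k]
        flat = ys * 243 + xs
        assert len(np.unique(flat)) == 59049
        # spot-check agreement with the scalar implementation
        for row in (0, 31, 59048):
            code = ScenarioCode.from_levels(levels[row])
            assert stack_coordinates(code, FULL_ORDER) == (xs[row], ys[row])


class TestBuildGrid:
    def test_constant_table_gives_constant_grid(self):
        spec = PlantedFieldSpec(weights=(1.0, 2.0), level_effects=(0, 0, 0))
        df = synth_scalar_field(spec)
        df["value"] = 7.5
        order = AxisOrder(spec.channel_names)
        grid = build_grid(df, order, "value")
        assert grid.values.shape == (3, 3)
        assert np.all(grid.values == 7.5)
        assert not grid.sentinel.any()

    def test_two_channel_placement_follows_strides(self):
        names = ("g_Ks", "g_Kr")
        rows = []
        for a, b in itertools.product(LEVELS, repeat=2):
            rows.append(
                {"level_g_Ks": a, "level_g_Kr": b, "value": 10 * LEVELS.index(a) + LEVELS.index(b)}
            )
        grid = build_grid(pd.DataFrame(rows), AxisOrder(names), "value")
        # g_Ks is the (only) x channel, g_Kr the y channel
        for (a, b) in itertools.product(range(3), repeat=2):
            assert grid.values[b, a] == 10 * a + b

    def test_missing_cells_error(self):
        spec = PlantedFieldSpec(weights=(1.0, 2.0))
        df = synth_scalar_field(spec).iloc[:-2]
        with pytest.raises(ValueError, match="missing"):
            build_grid(df, AxisOrder(spec.channel_names), "value")

    def test_full_design_cell_count(self):
        spec = PlantedFieldSpec(weights=tuple(2.0**k for k in range(10)))
        grid = build_grid(synth_scalar_field(spec), FULL_ORDER, "value")
        assert grid.n_cells == 59049
        assert grid.values.shape == (243, 243)


class TestMapObjective:
    def test_constant_grid_is_zero(self):
        assert map_objective(np.full((9, 9), 3.3)) == 0.0

    def test_hand_enumerated_2x2(self):
        # [[0,1],[2,3]]: per-cell neighbor sums 3+3+3+3 = 12
        assert map_objective(np.array([[0.0, 1.0], [2.0, 3.0]])) == 12.0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(7)
        g = rng.normal(size=(27, 27))
        assert map_objective(g) == pytest.approx(map_objective(g.T))

    def test_positive_unless_constant(self):
        g = np.zeros((3, 3))
        g[1, 1] = 1.0
        assert map_objective(g) > 0.0


class TestOptimizeAxisOrder:
    def test_swap_symmetry_of_objective(self):
        spec = PlantedFieldSpec(weights=(8.0, 4.0, 2.0, 1.0))
        df = synth_scalar_field(spec)
        order = AxisOrder(spec.channel_names)
        g1 = build_grid(df, order, "value")
        g2 = build_grid(df, order.swapped(), "value")
        assert np.array_equal(g2.values, g1.values.T)
        assert map_objective(g1) == pytest.approx(map_objective(g2))

    def test_single_active_channel_goes_outermost(self):
        spec = PlantedFieldSpec(weights=(0.01, 5.0, 0.02))
        df = synth_scalar_field(spec)
        order, _ = optimize_axis_order(df, "value", method="exhaustive")
        assert order.channels[0] == spec.true_ranking[0]

    def test_exhaustive_recovers_planted_ranking_even_design(self):
        # square (even-channel) stacking with a unique optimal pairing
        # (w1 > 2*w3, w2 > 2*w4, but w1 < 2*w2 and w2 < 2*w3) recovers
        # the weight ranking exactly
        spec = PlantedFieldSpec(weights=(9.0, 5.0, 4.0, 2.0))
        df = synth_scalar_field(spec)
        order, obj = optimize_axis_order(df, "value", method="exhaustive")
        assert order.channels == spec.true_ranking
        assert obj > 0

    def test_ranking_recovery_shuffled_weights(self):
        # same weight structure, shuffled over channels: the optimum is
        # the planted ranking up to the x/y-group mirror
        spec = PlantedFieldSpec(weights=(4.0, 9.0, 2.0, 5.0))
        df = synth_scalar_field(spec)
        order, _ = optimize_axis_order(df, "value", method="exhaustive")
        mirror = AxisOrder(spec.true_ranking).swapped().channels
        assert order.channels in (spec.true_ranking, mirror)

    @pytest.mark.parametrize("d", [3, 5])
    def test_heaviest_outermost_odd_designs(self, d):
        # rectangular (odd-channel) grids still place the dominant
        # channel outermost and beat the naive alternating ranking
        weights = tuple((9.0, 3.7, 1.4, 0.45, 0.2)[:d])
        spec = PlantedFieldSpec(weights=weights)
        df = synth_scalar_field(spec)
        order, obj = optimize_axis_order(df, "value", method="exhaustive")
        assert order.channels[0] == spec.true_ranking[0]
        naive = map_objective(
            build_grid(df, AxisOrder(spec.true_ranking), "value")
        )
        assert obj <= naive + 1e-9

    def test_heuristic_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            w = rng.normal(size=4) * (1 + rng.random(4) * 4)
            while len(set(np.round(np.abs(w), 9))) < 4:
                w = rng.normal(size=4)
            spec = PlantedFieldSpec(
                weights=tuple(w),
                level_effects=tuple(np.sort(rng.normal(size=3))),
                noise_sd=0.3,
                seed=trial,
            )
            df = synth_scalar_field(spec)
            _, obj_ex = optimize_axis_order(df, "value", method="exhaustive")
            _, obj_h = optimize_axis_order(
                df, "value", method="heuristic", seed=trial, anneal_steps=300, restarts=2
            )
            assert obj_h == pytest.approx(obj_ex, rel=1e-12), f"trial {trial}"

    def test_exhaustive_refuses_large_designs(self):
        spec = PlantedFieldSpec(weights=tuple(float(k + 1) for k in range(8)))
        df = synth_scalar_field(spec)
        with pytest.raises(ValueError, match="exhaustive"):
            optimize_axis_order(df, "value", method="exhaustive")

    def test_heuristic_is_seed_deterministic(self):
        spec = PlantedFieldSpec(weights=(3.0, 9.0, 1.0), noise_sd=0.5, seed=5)
        df = synth_scalar_field(spec)
        r1 = optimize_axis_order(df, "value", method="heuristic", seed=11)
        r2 = optimize_axis_order(df, "value", method="heuristic", seed=11)
        assert r1 == r2
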