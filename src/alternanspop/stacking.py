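"""Dimensional stacking of the factorial sweep into a 2-D population map.

A d-channel, 3-level factorial is embedded in a 2-D pixel grid by
splitting the channels between the x- and y-axes and nesting them from
outermost (largest stride) to innermost (stride 1).  For the full
10-channel design each axis carries 5 channels, giving a 243 × 243 map
in which every one of the 59,049 scenarios owns exactly one pixel.

The axis ordering is chosen to minimize the total absolute difference
between every pixel and its four lattice neighbors: orderings that place
the most influential conductances outermost produce large coherent
blocks and a small objective.  The global x/y-group exchange transposes
the grid and leaves the objective unchanged, so only half of the d!
orderings are distinct.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ionic import CHANNELS, LEVELS, ScenarioCode

__all__ = [
    "AxisOrder",
    "PopulationGrid",
    "stack_coordinates",
    "build_grid",
    "map_objective",
    "optimize_axis_order",
]


@dataclass(frozen=True)
class AxisOrder:
    """Channels ranked most → least influential, assigned alternately.

    Rank 1 becomes the outermost x-axis scale, rank 2 the outermost
    y-axis scale, rank 3 the second x scale, and so on; within each axis
    the outermost channel has the largest stride and the innermost has
    stride 1.
    """

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("axis order must not repeat channels")

    @property
    def x_channels(self) -> tuple[str, ...]:
        return self.channels[0::2]

    @property
    def y_channels(self) -> tuple[str, ...]:
        return self.channels[1::2]

    def swapped(self) -> "AxisOrder":
        """Exchange the x- and y-group assignments (transposes the grid)."""
        out: list[str] = []
        for a, b in itertools.zip_longest(self.y_channels, self.x_channels):
            if a is not None:
                out.append(a)
            if b is not None:
                out.append(b)
        return AxisOrder(tuple(out))


@dataclass
class PopulationGrid:
    """Stacked scalar field with its generating axis order.

    ``values[y, x]``; non-alternans scenarios carry the value 0 and are
    flagged in ``sentinel`` (rendered gray, but they remain real pixels
    of the map and contribute to the objective).
    """

    values: np.ndarray
    order: AxisOrder
    value_name: str
    sentinel: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.values.size)

    def to_image(self, path, cmap: str = "viridis") -> None:
        """Raster export; non-alternans (sentinel) pixels rendered gray.

        Requires matplotlib (the ``plot`` extra).
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy.ma as ma

        fig, ax = plt.subplots(figsize=(6, 6))
        cm = plt.get_cmap(cmap).copy()
        cm.set_bad(color="0.6")
        masked = ma.masked_where(self.sentinel, self.values)
        im = ax.imshow(masked, cmap=cm, origin="lower", interpolation="nearest")
        fig.colorbar(im, ax=ax, label=self.value_name)
        ax.set_xlabel(" / ".join(self.order.x_channels) + " (outer to inner)")
        ax.set_ylabel(" / ".join(self.order.y_channels) + " (outer to inner)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def to_csv(self, path, sidecar=None) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")
        if sidecar is not None:
            nx = len(self.order.x_channels)
            ny = len(self.order.y_channels)
            lines = [f"value: {self.value_name}"]
            lines.append("rank order (most->least influential): " + ",".join(self.order.channels))
            for axis, chans, n in (("x", self.order.x_channels, nx), ("y", self.order.y_channels, ny)):
                for i, ch in enumerate(chans):
                    lines.append(f"{axis} stride {3 ** (n - 1 - i)}: {ch}")
            Path(sidecar).write_text("\n".join(lines) + "\n")


def _digits(levels: Sequence[float]) -> list[int]:
    try:
        return [LEVELS.index(lv) for lv in levels]
    except ValueError:
        raise ValueError(f"levels must be drawn from {LEVELS}") from None


def stack_coordinates(
    code: ScenarioCode | Mapping[str, float], order: AxisOrder
) -> tuple[int, int]:
    """Pixel (x, y) of one scenario under an axis ordering.

    Mixed-radix encoding: within each axis group the outermost channel
    has stride ``3**(k-1)`` (k channels on that axis) down to stride 1
    innermost; level 0.5 → digit 0, 1.0 → 1, 1.5 → 2.
    """
    levels = code.as_dict() if isinstance(code, ScenarioCode) else dict(code)

    def axis_coord(chans: tuple[str, ...]) -> int:
        coord = 0
        for ch in chans:
            coord = coord * 3 + LEVELS.index(levels[ch])
        return coord

    return axis_coord(order.x_channels), axis_coord(order.y_channels)


def _value_tensor(
    table: pd.DataFrame, channels: tuple[str, ...], value_col: str
) -> np.ndarray:
    """Dense (3,)*d tensor of the scalar field, axes in channel order."""
    d = len(channels)
    level_cols = [f"level_{ch}" for ch in channels]
    missing_cols = [c for c in level_cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks level columns: {missing_cols}")
    digits = np.stack(
        [
            np.searchsorted(np.array(LEVELS), table[c].to_numpy())
            for c in level_cols
        ],
        axis=1,
    )
    flat = np.zeros(3**d, dtype=float)
    seen = np.zeros(3**d, dtype=bool)
    idx = np.zeros(len(table), dtype=np.int64)
    for k in range(d):
        idx = idx * 3 + digits[:, k]
    flat[idx] = table[value_col].to_numpy()
    seen[idx] = True
    if not seen.all():
        absent = np.flatnonzero(~seen)
        raise ValueError(
            f"table does not cover the full factorial: {absent.size} "
            f"missing scenario cells (first few indices: {absent[:5].tolist()})"
        )
    return flat.reshape((3,) * d)


def _grid_from_tensor(tensor: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    """Reorder tensor axes per the ranked permutation and flatten to 2-D."""
    d = tensor.ndim
    x_axes = list(perm[0::2])
    y_axes = list(perm[1::2])
    t = np.transpose(tensor, axes=y_axes + x_axes)
    return t.reshape(3 ** len(y_axes), 3 ** len(x_axes))


def build_grid(
    table: pd.DataFrame | "SweepTable",
    order: AxisOrder,
    value: str = "aocl_ms",
) -> PopulationGrid:
    """Fill the stacked grid from a full-factorial sweep table.

    ``value`` is the column holding the scalar (AOCL or AO meanAPD);
    zeros mark non-alternans scenarios and set the sentinel mask.
    Raises if any factorial cell is absent.
    """
    df = getattr(table, "df", table)
    tensor = _value_tensor(df, order.channels, value)
    d = tensor.ndim
    grid = _grid_from_tensor(tensor, list(range(d)))
    return PopulationGrid(
        values=grid,
        order=order,
        value_name=value,
        sentinel=(grid == 0.0),
    )


def map_objective(grid: PopulationGrid | np.ndarray) -> float:
    """Sum over all cells of absolute differences to the 4 lattice
    neighbors (terms for neighbors outside the grid are omitted).

    Each adjacent pair is counted from both of its cells, i.e. twice.
    Zero iff the grid is constant.
    """
    values = grid.values if isinstance(grid, PopulationGrid) else np.asarray(grid)
    horiz = np.abs(np.diff(values, axis=1)).sum()
    vert = np.abs(np.diff(values, axis=0)).sum()
    return float(2.0 * (horiz + vert))


def _objective_of_perm(tensor: np.ndarray, perm: Sequence[int]) -> float:
    return map_objective(_grid_from_tensor(tensor, perm))


def _total_variation_ranking(tensor: np.ndarray) -> list[int]:
    """Channels ranked by the field's total variation along each axis."""
    d = tensor.ndim
    tv = [float(np.abs(np.diff(tensor, axis=k)).sum()) for k in range(d)]
    return sorted(range(d), key=lambda k: (-tv[k], k))


def _hill_climb(tensor: np.ndarray, perm: list[int]) -> tuple[list[int], float]:
    """Greedy pairwise-swap descent to a local optimum."""
    d = len(perm)
    best = _objective_of_perm(tensor, perm)
    improved = True
    while improved:
        improved = False
        for i in range(d - 1):
            for j in range(i + 1, d):
                cand = perm.copy()
                cand[i], cand[j] = cand[j], cand[i]
                obj = _objective_of_perm(tensor, cand)
                if obj < best - 1e-12:
                    perm, best = cand, obj
                    improved = True
    return perm, best


def optimize_axis_order(
    table: pd.DataFrame | "SweepTable",
    value: str = "aocl_ms",
    method: str = "heuristic",
    *,
    channels: tuple[str, ...] | None = None,
    seed: int = 0,
    exhaustive_limit: int = 7,
    force_exhaustive: bool = False,
    anneal_steps: int = 4000,
    restarts: int = 4,
) -> tuple[AxisOrder, float]:
    """Axis ordering minimizing the neighbor-difference objective.

    ``exhaustive`` enumerates all orderings modulo the x/y-group swap
    symmetry and returns the global minimizer (ties broken toward the
    lexicographically smallest permutation); it refuses designs above
    ``exhaustive_limit`` channels unless ``force_exhaustive`` is set
    (10 channels means 10!/2 = 1,814,400 grid evaluations).
    ``heuristic`` seeds from the total-variation ranking plus random
    restarts, runs seeded simulated annealing and finishes with a
    pairwise-swap descent; it is deterministic for a given seed.
    """
    df = getattr(table, "df", table)
    if channels is None:
        level_cols = [c for c in df.columns if c.startswith("level_")]
        channels = tuple(
            ch for ch in CHANNELS if f"level_{ch}" in level_cols
        ) or tuple(c[len("level_") :] for c in level_cols)
    tensor = _value_tensor(df, channels, value)
    d = tensor.ndim

    if method == "exhaustive":
        if d > exhaustive_limit and not force_exhaustive:
            raise ValueError(
                f"exhaustive search over {d} channels needs "
                f"{math.factorial(d) // 2:,} grid evaluations; pass "
                "force_exhaustive=True to run it anyway"
            )
        best_perm = None
        best_obj = np.inf
        even = d % 2 == 0
        for perm in itertools.permutations(range(d)):
            if even:
                swapped = tuple(
                    perm[i + 1] if i % 2 == 0 else perm[i - 1]
                    for i in range(d)
                )
                if swapped < perm:
                    continue  # its mirror was (or will be) visited first
            obj = _objective_of_perm(tensor, perm)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_perm = list(perm)
        perm, obj = best_perm, float(best_obj)
    elif method == "heuristic":
        rng = np.random.default_rng(seed)
        seeds = [_total_variation_ranking(tensor)] + [
            list(rng.permutation(d)) for _ in range(max(0, restarts - 1))
        ]
        perm, obj = None, np.inf
        for start in seeds:
            cand, cand_obj = _anneal(tensor, list(start), rng, anneal_steps)
            cand, cand_obj = _hill_climb(tensor, cand)
            if cand_obj < obj - 1e-12:
                perm, obj = cand, cand_obj
    else:
        raise ValueError("method must be 'exhaustive' or 'heuristic'")

    order = AxisOrder(tuple(channels[k] for k in perm))
    return order, float(obj)


def _anneal(
    tensor: np.ndarray,
    perm: list[int],
    rng: np.random.Generator,
    steps: int,
) -> tuple[list[int], float]:
    """Simulated annealing over pairwise swaps with geometric cooling."""
    d = len(perm)
    if d < 2 or steps <= 0:
        return perm, _objective_of_perm(tensor, perm)
    cur = perm
    cur_obj = _objective_of_perm(tensor, cur)
    best, best_obj = cur, cur_obj
    # temperature scale set from the objective magnitude
    t0 = max(cur_obj * 0.05, 1e-9)
    alpha = (1e-3) ** (1.0 / steps)
    temp = t0
    for _ in range(steps):
        i, j = rng.choice(d, size=2, replace=False)
        cand = cur.copy()
        cand[i], cand[j] = cand[j], cand[i]
        obj = _objective_of_perm(tensor, cand)
        if obj <= cur_obj or rng.random() < np.exp((cur_obj - obj) / temp):
            cur, cur_obj = cand, obj
            if cur_obj < best_obj:
                best, best_obj = cur, cur_obj
        temp *= alpha
    return best, best_obj
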