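"""Synthetic fixtures with analytically known ground truth.

Three generators, each seed-deterministic and emitting its ground truth
alongside the data, so every downstream stage (APD extraction, alternans
biomarkers, axis-order optimization, population aggregation) can be
tested without integrating the ionic model:

* :func:`synth_ap_train` — an analytic action-potential train whose
  per-beat APD90 values are planted exactly (the template's
  90%-repolarization time is placed in closed form, not simulated).
* :func:`synth_scalar_field` — a separable scalar field on a 3-level
  factorial with a planted channel-sensitivity ranking.
* :func:`synth_summary_table` — a sweep-shaped summary table with a
  planted AOCL–AO meanAPD relation and non-alternans fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ionic import CHANNELS, LEVELS
from .pacing import BeatRecord

__all__ = [
    "APTrainSpec",
    "PlantedFieldSpec",
    "synth_ap_train",
    "synth_scalar_field",
    "synth_summary_table",
]


@dataclass(frozen=True)
class APTrainSpec:
    """Analytic action-potential train with planted per-beat APD90s.

    Each beat rises from ``v_rest`` to ``v_peak`` over ``upstroke_ms``
    (half-sine-squared rise, so the maximum upstroke sits at its
    midpoint), holds a plateau, and repolarizes along a logistic fall of
    width ``repol_shape`` ms whose 90%-repolarization crossing is placed
    exactly ``apd90s[i]`` ms after the maximum upstroke.
    """

    apd90s: tuple[float, ...]
    cycle_length: float
    v_rest: float = -85.0
    v_peak: float = 35.0
    upstroke_ms: float = 2.0
    repol_shape: float = 6.0
    sample_dt: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if self.repol_shape <= 0:
            raise ValueError("repol_shape must be positive")
        for apd in self.apd90s:
            if apd >= self.cycle_length:
                raise ValueError(
                    f"planted APD {apd} must be below the cycle length"
                )
            if apd <= self.upstroke_ms:
                raise ValueError("planted APD must exceed the upstroke")


_LN9 = float(np.log(9.0))


def _beat_template(spec: APTrainSpec, apd: float, t: np.ndarray) -> np.ndarray:
    """One beat, t relative to the stimulus at 0."""
    amp = spec.v_peak - spec.v_rest
    t_us = 0.5 * spec.upstroke_ms  # maximum upstroke of the sin^2 rise
    # logistic fall placed so V crosses rest + 0.1*amp at t_us + apd
    t_half = t_us + apd - spec.repol_shape * _LN9
    v = np.empty_like(t)
    rising = t < spec.upstroke_ms
    v[rising] = (
        spec.v_rest
        + amp * np.sin(0.5 * np.pi * t[rising] / spec.upstroke_ms) ** 2
    )
    after = ~rising
    v[after] = spec.v_rest + amp / (
        1.0 + np.exp((t[after] - t_half) / spec.repol_shape)
    )
    return v


def synth_ap_train(
    spec: APTrainSpec,
) -> tuple[np.ndarray, np.ndarray, list[BeatRecord]]:
    """Generate the voltage trace and its ground-truth beat records.

    Returns ``(time, voltage, records)``; ``time`` spans
    ``len(apd90s) * cycle_length`` at ``sample_dt`` resolution, stimuli
    at ``i * cycle_length``.  Additive Gaussian noise (``noise_sd`` mV)
    is drawn from a generator seeded with ``seed``.
    """
    n_beats = len(spec.apd90s)
    n_per_beat = int(round(spec.cycle_length / spec.sample_dt))
    t_beat = np.arange(n_per_beat) * spec.sample_dt
    segments = []
    records = []
    for i, apd in enumerate(spec.apd90s):
        v = _beat_template(spec, apd, t_beat)
        segments.append(v)
        stim = i * spec.cycle_length
        records.append(
            BeatRecord(
                beat_index=i,
                stim_time=stim,
                t_upstroke=stim + 0.5 * spec.upstroke_ms,
                v_peak=float(v.max()),
                v_rest=spec.v_rest,
                apd90=float(apd),
                captured=True,
            )
        )
    voltage = np.concatenate(segments)
    time = np.arange(voltage.size) * spec.sample_dt
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        voltage = voltage + rng.normal(0.0, spec.noise_sd, size=voltage.size)
    return time, voltage, records


@dataclass(frozen=True)
class PlantedFieldSpec:
    """Separable scalar field on a 3-level factorial.

    ``value(code) = sum_k w_k * f(level_k) + noise`` with per-channel
    weights of distinct magnitude, so the ground-truth sensitivity
    ranking is the ``|w_k|`` ordering.
    """

    weights: tuple[float, ...]
    level_effects: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    noise_sd: float = 0.0
    seed: int = 0
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.weights) < 2:
            raise ValueError("need at least 2 channels")
        mags = sorted(abs(w) for w in self.weights)
        if any(abs(a - b) < 1e-12 for a, b in zip(mags, mags[1:])):
            raise ValueError("weight magnitudes must be distinct")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.channels is not None:
            return self.channels
        return CHANNELS[: len(self.weights)]

    @property
    def true_ranking(self) -> tuple[str, ...]:
        """Channels from most to least influential (by |weight|)."""
        pairs = sorted(
            zip(self.channel_names, self.weights),
            key=lambda p: -abs(p[1]),
        )
        return tuple(name for name, _ in pairs)


def synth_scalar_field(spec: PlantedFieldSpec) -> pd.DataFrame:
    """Full-factorial table of the planted field (sweep-table layout).

    Columns: ``level_<ch>`` per channel plus ``value``; one row per cell
    of the 3^d factorial, enumerated lexicographically.
    """
    names = spec.channel_names
    d = len(names)
    rows = []
    effects = dict(zip(LEVELS, spec.level_effects))
    for combo in itertools.product(LEVELS, repeat=d):
        value = sum(
            w * effects[lv] for w, lv in zip(spec.weights, combo)
        )
        rows.append(dict(zip([f"level_{ch}" for ch in names], combo), value=value))
    df = pd.DataFrame(rows)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        df["value"] = df["value"] + rng.normal(0.0, spec.noise_sd, len(df))
    return df


def synth_summary_table(
    n_rows: int,
    *,
    slope: float = 0.9,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    zero_fraction: float = 0.0,
    schedule_cls: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep-shaped summary table with a planted AOCL relation.

    Alternans-positive rows draw AOCL from the schedule and set
    ``ao_mean_apd = slope * aocl + intercept + noise``; a
    ``zero_fraction`` of rows are non-alternans (both biomarkers 0).
    With ``noise_sd = 0`` the population Pearson correlation over
    positive rows is exactly 1 (for ``slope > 0``).
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    from .pacing import PacingSchedule

    cls_ = tuple(schedule_cls or PacingSchedule.default().cycle_lengths)
    rng = np.random.default_rng(seed)
    n_zero = int(round(zero_fraction * n_rows))
    aocl = np.concatenate(
        [
            np.zeros(n_zero),
            rng.choice(cls_, size=n_rows - n_zero, replace=True),
        ]
    )
    ao = np.where(
        aocl > 0,
        slope * aocl + intercept + rng.normal(0.0, noise_sd, n_rows),
        0.0,
    )
    df = pd.DataFrame(
        {
            "scenario_id": np.arange(n_rows),
            "aocl_ms": aocl,
            "ao_mean_apd_ms": ao,
            "quality": "ok",
        }
    )
    return df
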