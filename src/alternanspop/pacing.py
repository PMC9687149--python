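"""Descending cycle-length pacing protocol.

The clinical alternans-provocation protocol: the cell is brought to a
paced steady state at the starting cycle length, then driven through a
strictly decreasing schedule of cycle lengths (default 750 ms down to
350 ms in 50 ms decrements, then to 180 ms in 10 ms decrements) with a
fixed number of stimuli per cycle length (default 74).  State carries
over continuously between cycle lengths — there is no re-initialization
mid-protocol, as in a standard dynamic restitution protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _tt04
from .biomarkers import (
    ALTERNANS_WINDOW,
    CycleLengthResult,
    cycle_length_result,
)
from .ionic import (
    CellState,
    ConductanceSet,
    IntegratorConfig,
    NumericalInstabilityError,
    ScenarioCode,
)

__all__ = [
    "PacingSchedule",
    "BeatRecord",
    "ProtocolRun",
    "build_schedule",
    "steady_state_init",
    "run_protocol",
]


@dataclass(frozen=True)
class PacingSchedule:
    """Strictly decreasing cycle lengths with a fixed beat count each."""

    cycle_lengths: tuple[float, ...]
    beats_per_cl: int = 74

    def __post_init__(self) -> None:
        cls_ = self.cycle_lengths
        if not cls_:
            raise ValueError("schedule must contain at least one cycle length")
        if any(b >= a for a, b in zip(cls_, cls_[1:])):
            raise ValueError("cycle lengths must be strictly decreasing")
        if self.beats_per_cl < ALTERNANS_WINDOW:
            raise ValueError(
                f"need at least {ALTERNANS_WINDOW} beats per cycle length"
            )

    def __len__(self) -> int:
        return len(self.cycle_lengths)

    @classmethod
    def default(cls) -> "PacingSchedule":
        return build_schedule()


def build_schedule(
    start_cl: float = 750.0,
    coarse_step: float = 50.0,
    switch_cl: float = 350.0,
    fine_step: float = 10.0,
    end_cl: float = 180.0,
    beats_per_cl: int = 74,
) -> PacingSchedule:
    """Two-stage descending schedule including both endpoints.

    Defaults give 750, 700, …, 350 then 340, 330, …, 180 ms: 26 entries.
    """
    if not (start_cl > switch_cl > end_cl):
        raise ValueError("require start_cl > switch_cl > end_cl")
    if coarse_step <= 0 or fine_step <= 0:
        raise ValueError("steps must be positive")
    coarse = np.arange(start_cl, switch_cl - 1e-9, -coarse_step)
    if abs(coarse[-1] - switch_cl) > 1e-9:
        raise ValueError("coarse step does not land on switch_cl")
    fine = np.arange(switch_cl - fine_step, end_cl - 1e-9, -fine_step)
    if abs(fine[-1] - end_cl) > 1e-9:
        raise ValueError("fine step does not land on end_cl")
    return PacingSchedule(
        tuple(float(c) for c in np.concatenate([coarse, fine])),
        beats_per_cl=beats_per_cl,
    )


@dataclass(frozen=True)
class BeatRecord:
    """Per-beat metrics; APD90 is NaN when the beat is unmeasurable."""

    beat_index: int
    stim_time: float
    t_upstroke: float
    v_peak: float
    v_rest: float
    apd90: float
    captured: bool


@dataclass
class ProtocolRun:
    """Output of one descending-protocol run for one scenario."""

    scenario: ScenarioCode | None
    schedule: PacingSchedule
    beats: dict[float, list[BeatRecord]]  # cycle length -> 74 records
    final_state: CellState
    prepace_beats: int
    traces: dict[float, np.ndarray] = field(default_factory=dict)
    trace_dt: float | None = None
    failure: str | None = None

    def cycle_results(self) -> list[CycleLengthResult]:
        """Per-cycle-length biomarkers from the trailing 11 beats."""
        out = []
        for cl, records in self.beats.items():
            if len(records) < self.schedule.beats_per_cl:
                continue  # cycle length not completed (failure mid-way)
            tail = records[-ALTERNANS_WINDOW:]
            apds = [
                r.apd90 if (r.captured and np.isfinite(r.apd90)) else np.nan
                for r in tail
            ]
            out.append(cycle_length_result(cl, apds))
        return out

    def metrics_frame(self) -> "pd.DataFrame":
        """Per-beat metrics as a tidy table."""
        import pandas as pd

        rows = []
        sid = self.scenario.index if self.scenario is not None else -1
        for cl, records in self.beats.items():
            for r in records:
                rows.append(
                    (
                        sid,
                        cl,
                        r.beat_index,
                        r.apd90,
                        r.v_peak,
                        r.v_rest,
                        r.captured,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "scenario_id",
                "cl_ms",
                "beat_index",
                "apd90_ms",
                "peak_vm_mv",
                "rest_vm_mv",
                "capture",
            ],
        )


def _relative_change(y_new: np.ndarray, y_old: np.ndarray) -> float:
    return float(np.max(np.abs(y_new - y_old) / (np.abs(y_old) + 1e-12)))


def steady_state_init(
    g: ConductanceSet,
    cl: float,
    cfg: IntegratorConfig | None = None,
    *,
    tol: float = 1e-6,
    max_beats: int = 8000,
    start: CellState | None = None,
) -> tuple[CellState, int]:
    """Pace at a fixed cycle length until beat-to-beat convergence.

    The state is sampled at stimulus times; pacing stops when the
    maximum relative change of any state variable between successive
    beats falls below ``tol`` (slow Na+/K+ accumulation makes this take
    thousands of beats for some conductance sets), or at ``max_beats``.
    Returns the end state and the number of beats paced.
    """
    cfg = cfg or IntegratorConfig()
    if cl <= cfg.stim_duration:
        raise ValueError("cycle length must exceed the stimulus duration")
    y = (start or CellState.reference_initial()).as_array()
    p = g.as_array()
    empty = np.empty(0, dtype=np.float64)
    prev = y.copy()
    beats = 0
    for beats in range(1, max_beats + 1):
        res = _tt04.integrate(
            y, p, cl, cfg.dt, cfg.stim_amplitude, cfg.stim_duration, 0, empty
        )
        if res < 0:
            raise NumericalInstabilityError("v", beats * cl)
        if _relative_change(y, prev) < tol:
            break
        prev[:] = y
    return CellState.from_array(y, time=0.0), beats


def _beat_metrics(t: np.ndarray, v: np.ndarray, stim_time: float, idx: int) -> BeatRecord:
    """Extract per-beat metrics from a beat-relative trace."""
    v_rest = float(v[0])
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    dv = np.diff(v)
    i_up = int(np.argmax(dv[: max(i_peak, 1)]))
    t_up = 0.5 * (t[i_up] + t[i_up + 1])
    apd = np.nan
    # capture = a real regenerative upstroke; an amplitude criterion is
    # used because genuine short-cycle-length APs can peak below 0 mV,
    # while failed (subthreshold) responses stay within ~25 mV of rest
    captured = (v_peak - v_rest) >= 30.0
    if captured:
        threshold = v_rest + 0.1 * (v_peak - v_rest)
        below = np.flatnonzero(v[i_peak:] < threshold)
        if below.size:
            k = i_peak + int(below[0])
            t_cross = t[k - 1] + (t[k] - t[k - 1]) * (v[k - 1] - threshold) / (
                v[k - 1] - v[k]
            )
            apd = float(t_cross - t_up)
        else:
            captured = False  # incomplete repolarization within the window
    return BeatRecord(
        beat_index=idx,
        stim_time=stim_time,
        t_upstroke=float(stim_time + t_up),
        v_peak=v_peak,
        v_rest=v_rest,
        apd90=apd,
        captured=captured,
    )


def run_protocol(
    g: ConductanceSet,
    schedule: PacingSchedule | None = None,
    cfg: IntegratorConfig | None = None,
    *,
    early_stop: bool = False,
    scenario: ScenarioCode | None = None,
    store_traces: bool = False,
    sample_dt: float = 0.1,
    prepace_tol: float = 1e-6,
    prepace_max_beats: int = 8000,
    init_state: CellState | None = None,
) -> ProtocolRun:
    """Drive the myocyte through the descending protocol.

    The cell is first brought to a paced steady state at the schedule's
    first cycle length (skipped when ``init_state`` is supplied), then
    paced ``beats_per_cl`` times at every cycle length with continuous
    state carry-over.  Per-beat APD90 and capture metrics are recorded
    from traces sampled every ``sample_dt`` ms; 90% crossings are
    interpolated, so the sampling rate is not accuracy-limiting.

    With ``early_stop`` the run halts after the first cycle length
    classified as alternans (ANM > 0.05 from the trailing 11 beats) —
    sufficient for AOCL / AO meanAPD extraction.

    A numerical failure mid-protocol yields a partial run with
    ``failure`` set instead of raising.
    """
    schedule = schedule or PacingSchedule.default()
    cfg = cfg or IntegratorConfig()

    if init_state is None:
        state, prepace_beats = steady_state_init(
            g,
            schedule.cycle_lengths[0],
            cfg,
            tol=prepace_tol,
            max_beats=prepace_max_beats,
        )
    else:
        state, prepace_beats = init_state, 0

    y = state.as_array()
    p = g.as_array()
    sample_every = max(1, int(round(sample_dt / cfg.dt)))
    eff_dt = sample_every * cfg.dt

    beats: dict[float, list[BeatRecord]] = {}
    traces: dict[float, np.ndarray] = {}
    failure = None
    t_abs = 0.0

    for cl in schedule.cycle_lengths:
        n_samp = int(round(cl / cfg.dt)) // sample_every + 2
        records: list[BeatRecord] = []
        cl_traces = [] if store_traces else None
        beats[cl] = records
        for b in range(schedule.beats_per_cl):
            buf = np.empty(n_samp, dtype=np.float64)
            res = _tt04.integrate(
                y,
                p,
                cl,
                cfg.dt,
                cfg.stim_amplitude,
                cfg.stim_duration,
                sample_every,
                buf,
            )
            if res < 0:
                failure = (
                    f"numerical instability at cl={cl:g} ms, beat {b}, "
                    f"t={-(res + 1) * cfg.dt:.2f} ms into the beat"
                )
                break
            v = buf[:res]
            t = np.arange(res) * eff_dt
            records.append(_beat_metrics(t, v, stim_time=t_abs, idx=b))
            if cl_traces is not None:
                cl_traces.append(v[:-1])
            t_abs += cl
        if cl_traces is not None and cl_traces:
            traces[cl] = np.concatenate(cl_traces)
        if failure is not None:
            break
        if early_stop and len(records) == schedule.beats_per_cl:
            tail = records[-ALTERNANS_WINDOW:]
            apds = [
                r.apd90 if (r.captured and np.isfinite(r.apd90)) else np.nan
                for r in tail
            ]
            res_cl = cycle_length_result(cl, apds)
            if res_cl.capture_complete and res_cl.alternans:
                break

    return ProtocolRun(
        scenario=scenario,
        schedule=schedule,
        beats=beats,
        final_state=CellState.from_array(y, time=t_abs),
        prepace_beats=prepace_beats,
        traces=traces,
        trace_dt=eff_dt if store_traces else None,
        failure=failure,
    )
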