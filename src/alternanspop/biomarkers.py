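"""APD-alternans biomarkers.

Per beat: APD90, the interval from the maximum upstroke to 90%
repolarization.  Per cycle length, from the last 11 beats: the alternans
magnitude AM (mean absolute successive APD90 difference), meanAPD (mean
of the last 10 APD90s) and their ratio ANM = AM / meanAPD.  Alternans is
declared at a cycle length when ANM exceeds 0.05 (strict).  Per scenario:
AOCL, the longest cycle length of the descending protocol whose ANM
exceeds the threshold, and AO meanAPD, the meanAPD at the AOCL; both are
0 when no cycle length qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pacing import ProtocolRun

__all__ = [
    "ANM_THRESHOLD",
    "ApdMeasurementError",
    "CycleLengthResult",
    "ScenarioSummary",
    "apd90",
    "alternans_magnitude",
    "anm",
    "classify_alternans",
    "cycle_length_result",
    "summarize_scenario",
    "restitution_curve",
]

#: ANM above which a cycle length is classified as showing APD alternans.
ANM_THRESHOLD = 0.05

#: Number of trailing beats entering the alternans window (10 differences).
ALTERNANS_WINDOW = 11


class ApdMeasurementError(ValueError):
    """The beat cannot yield an APD90 (no capture or no repolarization)."""


def apd90(
    time: np.ndarray,
    voltage: np.ndarray,
    stim_time: float = 0.0,
) -> float:
    """APD90 of a single beat from its membrane-potential trace.

    The beat window is ``[stim_time, next stimulus)``; ``time`` may be
    absolute or beat-relative as long as ``stim_time`` matches.  The
    upstroke is the point of maximum dV/dt after the stimulus; the
    repolarization level is amplitude-relative, ``V_rest + 0.1 * (V_peak
    - V_rest)`` with ``V_rest`` the pre-stimulus potential (first sample
    of the window) and ``V_peak`` the beat maximum.  A beat whose
    upstroke amplitude is below 30 mV is treated as non-captured.  The downward
    crossing is located by linear interpolation, so the sampling interval
    is not accuracy-limiting.

    Raises
    ------
    ApdMeasurementError
        If the beat shows no capture (peak below 0 mV) or the trace never
        falls through the 90%-repolarization level inside the window.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(voltage, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValueError("time and voltage must be equal-length, length >= 3")
    sel = t >= stim_time
    t = t[sel]
    v = v[sel]

    v_rest = v[0]
    i_peak = int(np.argmax(v))
    v_peak = v[i_peak]
    # amplitude-based capture test: genuine short-cycle-length APs can
    # peak below 0 mV; failed responses stay within ~25 mV of rest
    if v_peak - v_rest < 30.0:
        raise ApdMeasurementError(
            f"no capture: upstroke amplitude {v_peak - v_rest:.1f} mV"
        )

    dv = np.diff(v)
    # maximum upstroke; restrict to samples up to the peak
    i_up = int(np.argmax(dv[: max(i_peak, 1)]))
    # place the upstroke at the midpoint of the steepest sampled rise
    t_up = 0.5 * (t[i_up] + t[i_up + 1])

    threshold = v_rest + 0.1 * (v_peak - v_rest)
    after = v[i_peak:]
    below = np.flatnonzero(after < threshold)
    if below.size == 0:
        raise ApdMeasurementError(
            "incomplete repolarization: no 90% crossing inside the beat window"
        )
    k = i_peak + int(below[0])
    # linear interpolation between the bracketing samples
    t_cross = t[k - 1] + (t[k] - t[k - 1]) * (v[k - 1] - threshold) / (
        v[k - 1] - v[k]
    )
    return float(t_cross - t_up)


def alternans_magnitude(apds: Sequence[float]) -> float:
    """AM: mean of the 10 absolute successive differences of 11 APD90s."""
    arr = np.asarray(apds, dtype=float)
    if arr.size != ALTERNANS_WINDOW:
        raise ValueError(
            f"expected {ALTERNANS_WINDOW} APD values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("APD values must be finite")
    return float(np.mean(np.abs(np.diff(arr))))


def anm(apds: Sequence[float]) -> float:
    """Alternans normalization magnitude: AM over the mean of the last 10."""
    arr = np.asarray(apds, dtype=float)
    am = alternans_magnitude(arr)
    mean_apd = float(np.mean(arr[1:]))
    if mean_apd <= 0:
        raise ValueError(f"meanAPD must be positive, got {mean_apd}")
    return am / mean_apd


def classify_alternans(anm_value: float) -> bool:
    """True iff ANM strictly exceeds the 0.05 threshold."""
    if not np.isfinite(anm_value) or anm_value < 0:
        raise ValueError(f"ANM must be finite and non-negative: {anm_value}")
    return anm_value > ANM_THRESHOLD


@dataclass(frozen=True)
class CycleLengthResult:
    """Alternans biomarkers of one cycle length of a protocol run."""

    cycle_length: float
    apd90s: tuple[float, ...]  # last 11 beats (NaN where unmeasurable)
    mean_apd: float
    am: float
    anm: float
    alternans: bool
    capture_complete: bool


@dataclass(frozen=True)
class ScenarioSummary:
    """Scenario-level biomarkers: AOCL, AO meanAPD and the ANM profile."""

    scenario_index: int | None
    levels: tuple[float, ...] | None
    aocl: float  # ms; 0 when no alternans detected
    ao_mean_apd: float  # ms; 0 when no alternans detected
    anm_by_cl: dict[float, float] = field(default_factory=dict)
    mean_apd_by_cl: dict[float, float] = field(default_factory=dict)
    quality: str = "ok"  # "ok" | "incomplete_capture" | "all_incomplete" | "failed"

    @property
    def alternans(self) -> bool:
        return self.aocl > 0


def cycle_length_result(
    cycle_length: float, apds_last11: Sequence[float]
) -> CycleLengthResult:
    """Biomarkers for one cycle length from its last-11 APD90 sequence."""
    arr = np.asarray(apds_last11, dtype=float)
    if arr.size != ALTERNANS_WINDOW:
        raise ValueError(f"need {ALTERNANS_WINDOW} trailing beats")
    complete = bool(np.all(np.isfinite(arr)))
    if complete:
        am = alternans_magnitude(arr)
        mean_apd = float(np.mean(arr[1:]))
        anm_val = am / mean_apd
        alt = classify_alternans(anm_val)
    else:
        am = mean_apd = anm_val = float("nan")
        alt = False
    return CycleLengthResult(
        cycle_length=float(cycle_length),
        apd90s=tuple(float(x) for x in arr),
        mean_apd=mean_apd,
        am=am,
        anm=anm_val,
        alternans=alt,
        capture_complete=complete,
    )


def summarize_scenario(run: "ProtocolRun") -> ScenarioSummary:
    """Scan a protocol run from the longest cycle length down.

    AOCL is the first (longest) cycle length whose ANM exceeds the
    threshold; AO meanAPD is that cycle length's meanAPD.  Cycle lengths
    with incomplete capture are excluded from the scan and degrade the
    quality flag instead of silently contributing zeros.
    """
    results = run.cycle_results()
    if not results:
        raise ValueError("protocol run holds no completed cycle length")
    anm_by_cl: dict[float, float] = {}
    mean_by_cl: dict[float, float] = {}
    aocl = 0.0
    ao_mean = 0.0
    any_incomplete = False
    for res in sorted(results, key=lambda r: -r.cycle_length):
        anm_by_cl[res.cycle_length] = res.anm
        mean_by_cl[res.cycle_length] = res.mean_apd
        if not res.capture_complete:
            any_incomplete = True
            continue
        if aocl == 0.0 and res.alternans:
            aocl = res.cycle_length
            ao_mean = res.mean_apd
    n_complete = sum(r.capture_complete for r in results)
    if run.failure is not None:
        quality = "failed"
    elif n_complete == 0:
        quality = "all_incomplete"
    elif any_incomplete:
        quality = "incomplete_capture"
    else:
        quality = "ok"
    idx = run.scenario.index if run.scenario is not None else None
    levels = run.scenario.levels if run.scenario is not None else None
    return ScenarioSummary(
        scenario_index=idx,
        levels=levels,
        aocl=aocl,
        ao_mean_apd=ao_mean,
        anm_by_cl=anm_by_cl,
        mean_apd_by_cl=mean_by_cl,
        quality=quality,
    )


def restitution_curve(run: "ProtocolRun") -> "pd.DataFrame":
    """meanAPD versus cycle length, with finite-difference slopes.

    One row per complete-capture cycle length; ``slope`` is
    d(meanAPD)/d(CL) between adjacent retained schedule points (NaN for
    the first row).
    """
    import pandas as pd

    rows = [
        (r.cycle_length, r.mean_apd)
        for r in sorted(run.cycle_results(), key=lambda r: -r.cycle_length)
        if r.capture_complete
    ]
    df = pd.DataFrame(rows, columns=["cycle_length", "mean_apd"])
    if len(df) > 1:
        slope = np.gradient(df["mean_apd"].to_numpy(), df["cycle_length"].to_numpy())
    else:
        slope = np.full(len(df), np.nan)
    df["slope"] = slope
    return df
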