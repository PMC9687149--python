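"""Human ventricular epicardial myocyte model with scalable conductances.

The cell is the epicardial variant of the 2004 human ventricular
Hodgkin–Huxley-type model: 12 membrane currents, intracellular Na+/K+/Ca2+
bookkeeping and a simplified sarcoplasmic-reticulum calcium subsystem.
Ten maximal conductances are exposed for scaling (the sensitivity-analysis
design varies each to 50% / 100% / 150% of its default); everything else
is fixed at reference-model values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _tt04

__all__ = [
    "CHANNELS",
    "LEVELS",
    "ConductanceSet",
    "ScenarioCode",
    "CellState",
    "CurrentVector",
    "IntegratorConfig",
    "NumericalInstabilityError",
    "default_conductances",
    "apply_scenario",
    "compute_currents",
    "step",
    "resting_state",
]

#: The 10 varied channels, in the fixed table order used throughout.
CHANNELS = (
    "g_Ks",
    "g_Kr",
    "g_K1",
    "g_Na",
    "g_bNa",
    "g_CaL",
    "g_bCa",
    "g_to",
    "g_pCa",
    "g_pK",
)

#: The three conductance scale levels of the factorial design.
LEVELS = (0.5, 1.0, 1.5)

_STATE_FIELDS = (
    "v",
    "m",
    "h",
    "j",
    "d",
    "f",
    "f_ca",
    "r",
    "s",
    "xs",
    "xr1",
    "xr2",
    "g",
    "na_i",
    "k_i",
    "ca_i",
    "ca_sr",
)

_GATE_FIELDS = ("m", "h", "j", "d", "f", "f_ca", "r", "s", "xs", "xr1", "xr2", "g")


class NumericalInstabilityError(RuntimeError):
    """The integrator produced a non-finite state variable."""

    def __init__(self, variable: str, time_ms: float):
        self.variable = variable
        self.time_ms = time_ms
        super().__init__(
            f"non-finite value in state variable {variable!r} at t={time_ms:.3f} ms"
        )


@dataclass(frozen=True)
class ConductanceSet:
    """Maximal conductances plus non-varied reference maxima.

    Defaults are the epicardial reference model's published values for
    the 10 varied channels (g_Ks .. g_pK in nS/pF except g_CaL, in
    cm^3 uF^-1 s^-1, and g_pCa, in pA/pF — the reference model's own
    unit conventions).  The pump/exchanger/SR maxima are reference-model
    constants and are never touched by scenario scaling.
    """

    g_Ks: float = 0.245
    g_Kr: float = 0.096
    g_K1: float = 5.405
    g_Na: float = 14.838
    g_bNa: float = 0.00029
    g_CaL: float = 0.000175
    g_bCa: float = 0.000592
    g_to: float = 0.294
    g_pCa: float = 0.825
    g_pK: float = 0.0146
    # non-varied maxima (reference model values)
    p_NaK: float = 1.362
    k_NaCa: float = 1000.0
    v_max_up: float = 0.000425
    v_leak: float = 0.00008
    a_rel: float = 0.016464
    c_rel: float = 0.008232

    def __post_init__(self) -> None:
        for name in CHANNELS:
            if not getattr(self, name) > 0:
                raise ValueError(f"conductance {name} must be positive")

    def as_array(self) -> np.ndarray:
        """Flat parameter vector in the kernel layout."""
        return np.array(
            [getattr(self, name) for name in CHANNELS]
            + [
                self.p_NaK,
                self.k_NaCa,
                self.v_max_up,
                self.v_leak,
                self.a_rel,
                self.c_rel,
            ],
            dtype=np.float64,
        )

    def to_config(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_config(cls, mapping: dict[str, float]) -> "ConductanceSet":
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ScenarioCode:
    """One point of the 3^10 factorial: a scale level per channel.

    Levels follow the fixed channel order of :data:`CHANNELS`; the code
    admits a unique base-3 integer index (channel 0 most significant,
    digit 0 ↔ level 0.5).
    """

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(CHANNELS):
            raise ValueError(
                f"expected {len(CHANNELS)} levels, got {len(self.levels)}"
            )
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"level {lv} not in {LEVELS}")

    @classmethod
    def from_levels(cls, levels: Iterable[float]) -> "ScenarioCode":
        return cls(tuple(float(lv) for lv in levels))

    @classmethod
    def from_mapping(
        cls, mapping: dict[str, float], default: float = 1.0
    ) -> "ScenarioCode":
        """Build a code from e.g. ``{"g_CaL": 1.5, "g_bCa": 1.5}``."""
        unknown = set(mapping) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        return cls(tuple(float(mapping.get(ch, default)) for ch in CHANNELS))

    @classmethod
    def from_index(cls, index: int) -> "ScenarioCode":
        n = len(CHANNELS)
        if not 0 <= index < 3**n:
            raise ValueError(f"index {index} out of range [0, {3 ** n})")
        digits = []
        for _ in range(n):
            digits.append(index % 3)
            index //= 3
        return cls(tuple(LEVELS[dig] for dig in reversed(digits)))

    @property
    def index(self) -> int:
        idx = 0
        for lv in self.levels:
            idx = idx * 3 + LEVELS.index(lv)
        return idx

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CHANNELS, self.levels))


@dataclass
class CellState:
    """Full state of the myocyte model at one instant."""

    v: float
    m: float
    h: float
    j: float
    d: float
    f: float
    f_ca: float
    r: float
    s: float
    xs: float
    xr1: float
    xr2: float
    g: float
    na_i: float
    k_i: float
    ca_i: float
    ca_sr: float
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in _STATE_FIELDS], dtype=np.float64
        )

    @classmethod
    def from_array(cls, y: Sequence[float], time: float = 0.0) -> "CellState":
        return cls(*[float(x) for x in y], time=time)

    @classmethod
    def reference_initial(cls) -> "CellState":
        """Published initial conditions of the reference model."""
        return cls.from_array(_tt04.DEFAULT_Y0)

    def validate(self) -> None:
        for name in _GATE_FIELDS:
            val = getattr(self, name)
            # the published calcium-dependent inactivation steady state
            # slightly exceeds 1 at diastolic Ca2+ ((1+0.1+0.2+0.23)/1.46);
            # the formulation is kept verbatim rather than clamped
            hi = 1.05 if name == "f_ca" else 1.0
            if not 0.0 <= val <= hi:
                raise ValueError(f"gate {name}={val} outside [0, {hi}]")
        for name in ("na_i", "k_i", "ca_i", "ca_sr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"concentration {name} must be positive")

    def copy(self) -> "CellState":
        return replace(self)

    def to_config(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in _STATE_FIELDS}
        out["time"] = self.time
        return out

    @classmethod
    def from_config(cls, mapping: dict[str, float]) -> "CellState":
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class CurrentVector:
    """The 12 membrane currents (pA/pF) and their sum."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bCa: float
    I_bNa: float

    @property
    def I_ion(self) -> float:
        return (
            self.I_Na
            + self.I_K1
            + self.I_to
            + self.I_Kr
            + self.I_Ks
            + self.I_CaL
            + self.I_NaCa
            + self.I_NaK
            + self.I_pCa
            + self.I_pK
            + self.I_bCa
            + self.I_bNa
        )


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integrator and stimulus settings.

    dt is the integration step (ms); Rush–Larsen gates plus forward-Euler
    membrane/concentration updates are stable for this model at the 0.02 ms
    default.  ``cm`` (uF/cm^2) is the printed membrane capacitance of the
    membrane equation; currents are carried per unit capacitance (pA/pF),
    so it enters the formulation only through that normalization and is
    retained as metadata.  The stimulus is the conventional 1 ms,
    -52 pA/pF twice-threshold pulse.
    """

    dt: float = 0.02
    cm: float = 2.0
    stim_amplitude: float = -52.0
    stim_duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.stim_duration < self.dt:
            raise ValueError("stimulus duration must be at least dt")

    def to_config(self) -> dict[str, float]:
        return {
            "dt": self.dt,
            "cm": self.cm,
            "stim_amplitude": self.stim_amplitude,
            "stim_duration": self.stim_duration,
        }

    @classmethod
    def from_config(cls, mapping: dict[str, float]) -> "IntegratorConfig":
        return cls(**{k: float(v) for k, v in mapping.items()})


def default_conductances() -> ConductanceSet:
    """Baseline conductance table (the 100% scenario)."""
    return ConductanceSet()


def apply_scenario(base: ConductanceSet, code: ScenarioCode) -> ConductanceSet:
    """Scale each varied conductance by its scenario level.

    Non-varied constants (pumps, exchanger, SR fluxes) are unchanged.
    """
    if not isinstance(code, ScenarioCode):
        code = ScenarioCode.from_levels(code)
    scaled = {
        ch: getattr(base, ch) * lv for ch, lv in zip(CHANNELS, code.levels)
    }
    return replace(base, **scaled)


def compute_currents(state: CellState, g: ConductanceSet) -> CurrentVector:
    """Evaluate all 12 membrane currents at the given state."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        bad = _STATE_FIELDS[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise NumericalInstabilityError(bad, state.time)
    vals = _tt04.currents(y, g.as_array())
    return CurrentVector(*[float(v) for v in vals])


def step(
    state: CellState,
    g: ConductanceSet,
    cfg: IntegratorConfig,
    i_stim: float = 0.0,
) -> CellState:
    """Advance the state by one integration step.

    ``i_stim`` follows the inward-negative convention (the default
    stimulus is negative).  Raises :class:`NumericalInstabilityError`,
    naming the offending variable, if the update produces NaN/Inf.
    """
    y = state.as_array()
    _tt04.step_once(y, g.as_array(), cfg.dt, i_stim)
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise NumericalInstabilityError(
            _STATE_FIELDS[int(bad[0])], state.time + cfg.dt
        )
    return CellState.from_array(y, time=state.time + cfg.dt)


def _integrate_unstimulated(
    y: np.ndarray, p: np.ndarray, duration: float, dt: float
) -> None:
    out = np.empty(0, dtype=np.float64)
    res = _tt04.integrate(y, p, duration, dt, 0.0, 0.0, 0, out)
    if res < 0:
        raise NumericalInstabilityError("v", (-res - 1) * dt)


def resting_state(
    g: ConductanceSet,
    cfg: IntegratorConfig | None = None,
    *,
    settle_tol_mv: float = 0.05,
    horizon_ms: float = 120_000.0,
) -> CellState:
    """Quiescent (unpaced) state for the given conductances.

    Integrates without stimulus from the reference initial conditions in
    1 s blocks until Vm drifts less than ``settle_tol_mv`` per block,
    then returns the equilibrated state (time reset to 0).  Raises if the
    membrane has not quiesced within ``horizon_ms``.
    """
    cfg = cfg or IntegratorConfig()
    y = _tt04.DEFAULT_Y0.copy()
    p = g.as_array()
    block = 1000.0
    elapsed = 0.0
    while elapsed < horizon_ms:
        v_before = y[0]
        _integrate_unstimulated(y, p, block, cfg.dt)
        elapsed += block
        if abs(y[0] - v_before) < settle_tol_mv:
            return CellState.from_array(y, time=0.0)
    raise RuntimeError(
        f"membrane failed to quiesce within {horizon_ms:.0f} ms "
        f"(last 1 s drift {abs(y[0] - v_before):.3f} mV)"
    )


def save_config(mapping: dict[str, float], path: str | Path) -> None:
    """Write a flat key-value text file (one ``key = value`` per line)."""
    lines = [f"{k} = {v!r}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> dict[str, float]:
    """Read a flat key-value text file written by :func:`save_config`."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = float(val)
    return out
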