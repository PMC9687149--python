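"""Factorial population sweep over conductance scenarios.

Enumerates the 3^k factorial of conductance scale levels (k = 10 for the
full design, 59,049 scenarios), runs the descending pacing protocol for
each scenario, and aggregates the population-level alternans statistics.
Scenario runs are independent and deterministic, so results do not
depend on worker count or execution order, and a sweep interrupted
half-way can resume from its output table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .biomarkers import ScenarioSummary, summarize_scenario
from .ionic import (
    CHANNELS,
    LEVELS,
    ConductanceSet,
    IntegratorConfig,
    ScenarioCode,
    apply_scenario,
    default_conductances,
)
from .pacing import PacingSchedule, run_protocol

__all__ = ["SweepConfig", "SweepTable", "enumerate_scenarios", "run_sweep", "aggregate"]

_LEVEL_COLUMNS = [f"level_{ch}" for ch in CHANNELS]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a (possibly partial) factorial sweep."""

    channels: tuple[str, ...] = CHANNELS
    levels: tuple[float, ...] = LEVELS
    schedule: PacingSchedule = field(default_factory=PacingSchedule.default)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    base: ConductanceSet = field(default_factory=default_conductances)
    early_stop: bool = True
    n_workers: int = 1
    seed: int = 0
    prepace_tol: float = 1e-6
    prepace_max_beats: int = 8000

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if not self.levels:
            raise ValueError("level set must be non-empty")

    @property
    def n_scenarios(self) -> int:
        return len(self.levels) ** len(self.channels)


@dataclass
class SweepTable:
    """One row of scenario biomarkers per executed scenario."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SweepTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)


def enumerate_scenarios(cfg: SweepConfig) -> list[ScenarioCode]:
    """Deterministic lexicographic enumeration of the factorial.

    A base-|levels| counter over the configured channels in table order;
    channels outside the subset stay at scale 1.0.  Index 0 is all-lowest,
    the last index all-highest.
    """
    codes = []
    for combo in itertools.product(sorted(cfg.levels), repeat=len(cfg.channels)):
        mapping = dict(zip(cfg.channels, combo))
        codes.append(ScenarioCode.from_mapping(mapping, default=1.0))
    return codes


def _summary_row(summary: ScenarioSummary) -> dict:
    row: dict = {"scenario_id": summary.scenario_index}
    levels = summary.levels or (np.nan,) * len(CHANNELS)
    row.update(dict(zip(_LEVEL_COLUMNS, levels)))
    row["aocl_ms"] = summary.aocl
    row["ao_mean_apd_ms"] = summary.ao_mean_apd
    row["quality"] = summary.quality
    for cl in sorted(summary.anm_by_cl, reverse=True):
        row[f"anm_cl{int(cl)}"] = summary.anm_by_cl[cl]
    return row


def _run_one(cfg: SweepConfig, code: ScenarioCode) -> dict:
    g = apply_scenario(cfg.base, code)
    run = run_protocol(
        g,
        cfg.schedule,
        cfg.integrator,
        early_stop=cfg.early_stop,
        scenario=code,
        prepace_tol=cfg.prepace_tol,
        prepace_max_beats=cfg.prepace_max_beats,
    )
    return _summary_row(summarize_scenario(run))


def run_sweep(
    cfg: SweepConfig,
    codes: Sequence[ScenarioCode] | None = None,
    *,
    out_csv: str | Path | None = None,
    resume: bool = True,
) -> SweepTable:
    """Execute the protocol for every scenario and tabulate biomarkers.

    ``codes`` restricts the sweep to a subset (default: the full
    factorial of ``cfg``).  When ``out_csv`` exists and ``resume`` is on,
    scenarios already present are skipped and the merged table is
    rewritten — interrupting and re-running yields the identical final
    table.  Per-scenario numerical failures become quality-flagged rows,
    never an aborted sweep.
    """
    codes = list(codes) if codes is not None else enumerate_scenarios(cfg)
    done = pd.DataFrame()
    if out_csv is not None and resume and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
        have = set(done["scenario_id"].astype(int))
        codes = [c for c in codes if c.index not in have]

    if cfg.n_workers == 1:
        rows = [_run_one(cfg, code) for code in codes]
    else:
        rows = Parallel(n_jobs=cfg.n_workers)(
            delayed(_run_one)(cfg, code) for code in codes
        )

    df = pd.DataFrame(rows)
    if not done.empty:
        df = pd.concat([done, df], ignore_index=True)
    if not df.empty:
        df = df.sort_values("scenario_id").reset_index(drop=True)
    table = SweepTable(
        df,
        provenance={
            "n_scenarios": len(df),
            "channels": list(cfg.channels),
            "levels": list(cfg.levels),
            "beats_per_cl": cfg.schedule.beats_per_cl,
            "early_stop": cfg.early_stop,
        },
    )
    if out_csv is not None:
        table.to_csv(out_csv)
    return table


def aggregate(table: SweepTable | pd.DataFrame) -> dict:
    """Population statistics over a sweep table.

    Quality-flagged rows are excluded from every statistic (their count
    is reported).  The AOCL–AO meanAPD Pearson correlation is computed
    over alternans-positive scenarios (primary) and, as a secondary
    variant, over all clean rows including the (0, 0) non-alternans ones.
    """
    from scipy import stats

    df = table.df if isinstance(table, SweepTable) else table
    if df.empty:
        raise ValueError("empty sweep table")
    clean = df[df["quality"] == "ok"] if "quality" in df else df
    excluded = len(df) - len(clean)
    pos = clean[clean["aocl_ms"] > 0]
    out: dict = {
        "n_rows": int(len(df)),
        "n_excluded_quality": int(excluded),
        "n_alternans": int(len(pos)),
        "n_non_alternans": int(len(clean) - len(pos)),
    }
    if len(pos):
        max_aocl = pos["aocl_ms"].max()
        min_aocl = pos["aocl_ms"].min()
        at_max = pos[pos["aocl_ms"] == max_aocl]
        at_min = pos[pos["aocl_ms"] == min_aocl]
        out.update(
            max_aocl_ms=float(max_aocl),
            n_at_max_aocl=int(len(at_max)),
            ao_mean_apd_at_max_aocl_mean=float(at_max["ao_mean_apd_ms"].mean()),
            ao_mean_apd_at_max_aocl_range=(
                float(at_max["ao_mean_apd_ms"].min()),
                float(at_max["ao_mean_apd_ms"].max()),
            ),
            min_aocl_ms=float(min_aocl),
            n_at_min_aocl=int(len(at_min)),
            ao_mean_apd_at_min_aocl_mean=float(at_min["ao_mean_apd_ms"].mean()),
            ao_mean_apd_at_min_aocl_range=(
                float(at_min["ao_mean_apd_ms"].min()),
                float(at_min["ao_mean_apd_ms"].max()),
            ),
        )
    if len(pos) >= 2 and pos["aocl_ms"].nunique() > 1 and pos["ao_mean_apd_ms"].nunique() > 1:
        r, p = stats.pearsonr(pos["aocl_ms"], pos["ao_mean_apd_ms"])
        out["pearson_r_alternans_only"] = float(r)
        out["pearson_p_alternans_only"] = float(p)
    else:
        out["pearson_r_alternans_only"] = None
    if len(clean) >= 2 and clean["aocl_ms"].nunique() > 1:
        r_all, _ = stats.pearsonr(clean["aocl_ms"], clean["ao_mean_apd_ms"])
        out["pearson_r_including_zeros"] = float(r_all)
    return out
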