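"""Agent-based population simulation with a fixed-size cap.

Populations start from asynchronous cells and are evolved step by step;
daughters are appended at division and, whenever the census exceeds the
cap, randomly selected cells are removed to bring it back down.  Every
completed cycle is logged to a lineage table; a per-timepoint series of
population mean size is kept for stability classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .model_core import (CellState, Event, ModelParams, Phase, _advance_inplace,
                         new_cell, sample_d, sample_g)

__all__ = [
    "PopulationConfig",
    "PopulationSummary",
    "init_population",
    "run_population",
    "summarize_population",
    "LINEAGE_COLUMNS",
]

# Canonical lineage-table schema (delimited-text interchange format).
LINEAGE_COLUMNS = [
    "cell_id", "parent_id", "birth_time", "division_time",
    "birth_area", "division_area", "g1s_time", "g1s_area", "zone",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population run settings.

    ``burn_in`` hours are excluded from summaries (initialisation
    transients); default three nominal cycle lengths.
    """

    params: ModelParams
    n_init: int = 100
    cap: int = 100
    duration: float = 600.0
    burn_in: float = 72.0
    seed: int = 0
    record_timeseries: bool = True

    def __post_init__(self) -> None:
        if self.n_init < 1 or self.cap < 1:
            raise ValueError("n_init and cap must be >= 1")
        if self.n_init > self.cap:
            raise ValueError("n_init must not exceed cap")
        if not self.duration > self.burn_in >= 0:
            raise ValueError("need duration > burn_in >= 0")


@dataclass
class PopulationSummary:
    n_cycles: int
    birth_size_mean: float
    birth_size_sd: float
    division_size_mean: float
    division_size_sd: float
    cycle_length_mean: float
    cycle_length_sd: float
    g1_length_mean: Optional[float]
    g1_length_sd: Optional[float]
    sgm_length_mean: Optional[float]
    sgm_length_sd: Optional[float]
    birth_size_cycle_slope: float
    birth_size_cycle_corr: float
    timeseries: Optional[pd.DataFrame] = field(default=None, repr=False)


def _nominal_cycle_hours(params: ModelParams) -> float:
    return math.log(2.0) / params.g_mean


def _cull(cells: list, cap: int, rng) -> list:
    """Uniformly random subset of ``cap`` survivors, order preserved."""
    keep = rng.choice(len(cells), size=cap, replace=False)
    keep.sort()
    return [cells[i] for i in keep]


def init_population(config: PopulationConfig) -> List[CellState]:
    """Asynchronous starting population.

    Sizes are drawn log-uniformly between the nominal birth size
    (``size_ref``) and twice it; the CDK accumulator is set in proportion
    to the cell's progress through the cycle so that divisions are spread
    over the first cycle rather than clustered. Deterministic given the
    seed.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    cells: List[CellState] = []
    b0 = params.size_ref
    for i in range(config.n_init):
        u = rng.uniform(0.0, 1.0)           # progress through the cycle
        size = b0 * 2.0 ** u
        cell = new_cell(size, params, g=sample_g(params, rng),
                        d=sample_d(params, rng), birth_time=0.0,
                        lineage_id=i, parent_id=None)
        cell.size = size
        if params.two_transition:
            # place the cell within G1 or S-G2-M according to progress
            g1_frac = 0.6
            if u < g1_frac:
                cell.cdk = (u / g1_frac) * params.T_g1s
            else:
                cell.phase = Phase.S_G2_M
                cell.cdk = ((u - g1_frac) / (1 - g1_frac)) * params.T_g2m
                cell.g1s_time = None    # pre-simulation event, unobserved
                cell.g1s_size = None
        else:
            cell.cdk = u * params.T_division
        cells.append(cell)
    return cells


def run_population(config: PopulationConfig
                   ) -> Tuple[pd.DataFrame, PopulationSummary]:
    """Evolve the population and summarise it.

    Per step: every cell advances by ``dt``; cells completing mitosis are
    logged and replaced by their two daughters; if the census then exceeds
    the cap, uniformly random cells are culled back down to it.
    Reproducible: identical config+seed gives an identical table.
    """
    params = config.params
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cells = init_population(config)
    next_id = config.n_init
    n_steps = int(round(config.duration / params.dt))

    rows: List[tuple] = []
    ts_t: List[float] = []
    ts_n: List[int] = []
    ts_mean: List[float] = []
    ts_sd: List[float] = []

    t = 0.0
    for _ in range(n_steps):
        t += params.dt
        newborn: List[CellState] = []
        survivors: List[CellState] = []
        for cell in cells:
            event = _advance_inplace(cell, params, params.dt)
            if event is Event.DIVIDED:
                rows.append((cell.lineage_id, cell.parent_id,
                             cell.birth_time, t, cell.birth_size,
                             cell.size, cell.g1s_time, cell.g1s_size))
                a1 = cell.size * cell.d / 100.0
                for area, cid in ((a1, next_id),
                                  (cell.size - a1, next_id + 1)):
                    daughter = new_cell(area, params,
                                        g=sample_g(params, rng),
                                        d=sample_d(params, rng),
                                        birth_time=t, lineage_id=cid,
                                        parent_id=cell.lineage_id)
                    newborn.append(daughter)
                next_id += 2
            else:
                survivors.append(cell)
        cells = survivors + newborn
        if not cells:
            raise RuntimeError("population went extinct")
        if len(cells) > config.cap:
            cells = _cull(cells, config.cap, rng)
        if config.record_timeseries:
            sizes = np.fromiter((c.size for c in cells), dtype=float,
                                count=len(cells))
            ts_t.append(t)
            ts_n.append(len(cells))
            ts_mean.append(float(sizes.mean()))
            ts_sd.append(float(sizes.std(ddof=0)))

    table = pd.DataFrame(rows, columns=["cell_id", "parent_id",
                                        "birth_time", "division_time",
                                        "birth_area", "division_area",
                                        "g1s_time", "g1s_area"])
    table["zone"] = pd.NA
    table = table[LINEAGE_COLUMNS]
    timeseries = None
    if config.record_timeseries:
        timeseries = pd.DataFrame({"time": ts_t, "n": ts_n,
                                   "mean_size": ts_mean, "sd_size": ts_sd})
    summary = summarize_population(table, burn_in=config.burn_in,
                                   timeseries=timeseries)
    return table, summary


def summarize_population(table: pd.DataFrame, burn_in: float = 0.0,
                         timeseries: Optional[pd.DataFrame] = None
                         ) -> PopulationSummary:
    """Distribution summaries over completed cycles born after burn-in.

    The birth-size/cycle-length relation is reported as the least-squares
    slope of cycle length on ln(birth size) together with the Pearson
    correlation.
    """
    done = table[table["birth_time"] >= burn_in]
    if len(done) < 2:
        raise ValueError("need at least 2 completed cycles after burn-in")
    birth = done["birth_area"].to_numpy(float)
    div = done["division_area"].to_numpy(float)
    cyc = (done["division_time"] - done["birth_time"]).to_numpy(float)

    g1 = sgm = None
    g1m = g1s = sm = ss = None
    has_g1s = done["g1s_time"].notna()
    if has_g1s.any():
        sub = done[has_g1s]
        g1 = (sub["g1s_time"] - sub["birth_time"]).to_numpy(float)
        sgm = (sub["division_time"] - sub["g1s_time"]).to_numpy(float)
        g1m, g1s = float(g1.mean()), float(g1.std(ddof=1))
        sm, ss = float(sgm.mean()), float(sgm.std(ddof=1))

    ln_b = np.log(birth)
    if np.ptp(ln_b) > 0 and np.ptp(cyc) > 0:
        slope = float(np.polyfit(ln_b, cyc, 1)[0])
        corr = float(np.corrcoef(ln_b, cyc)[0, 1])
    else:
        slope, corr = 0.0, 0.0

    return PopulationSummary(
        n_cycles=len(done),
        birth_size_mean=float(birth.mean()),
        birth_size_sd=float(birth.std(ddof=1)),
        division_size_mean=float(div.mean()),
        division_size_sd=float(div.std(ddof=1)),
        cycle_length_mean=float(cyc.mean()),
        cycle_length_sd=float(cyc.std(ddof=1)),
        g1_length_mean=g1m, g1_length_sd=g1s,
        sgm_length_mean=sm, sgm_length_sd=ss,
        birth_size_cycle_slope=slope,
        birth_size_cycle_corr=corr,
        timeseries=timeseries,
    )
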