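"""Scripted in-silico perturbation experiments.

Reproduces the model analyses: recovery from an uneven division, effect
of the relative growth rate, CDK-production mutants (which move cell size
but not cycle length), sub-linear size-sensing exponents, and fold scans
of the two-transition model mapping where single- and dual-checkpoint
size control breaks down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import (CalibrationTarget, calibrate_one_transition,
                          calibrate_two_transition, classify_stability,
                          simulate_steady_state)
from .model_core import ModelParams, SizeDependence
from .population import PopulationConfig, PopulationSummary, run_population

__all__ = [
    "ScanResult",
    "uneven_division_experiment",
    "rgr_experiment",
    "pcdk_mutant_experiment",
    "exponent_variant_experiment",
    "two_transition_fold_scan",
    "DEFAULT_PCDK_M_FOLDS",
    "DEFAULT_PCDK_S_FOLDS",
]

# Default fold-reduction grids for the two-transition scans.
DEFAULT_PCDK_M_FOLDS: Tuple[float, ...] = (1.0, 1.2, 1.5, 2.0, 2.5, 3.0)
DEFAULT_PCDK_S_FOLDS: Tuple[float, ...] = (1.0, 1.2, 1.4, 1.7, 2.0, 3.0)


@dataclass(frozen=True)
class ScanResult:
    """Per-fold population summary from a rate-reduction scan."""

    fold: float
    g1_mean: Optional[float]
    g1_sd: Optional[float]
    sgm_mean: Optional[float]
    sgm_sd: Optional[float]
    cycle_mean: float
    cycle_sd: float
    division_size_mean: float
    division_size_sd: float
    stability: str


def _birth_trajectory(params: ModelParams, birth_size: float,
                      n_cycles: int) -> List[float]:
    """Successive birth sizes of one noiseless, symmetric lineage."""
    from .calibration import _run_one_cycle
    sizes = [birth_size]
    b = birth_size
    for _ in range(n_cycles):
        div, _, _ = _run_one_cycle(b, params)
        b = div / 2.0
        sizes.append(b)
    return sizes


def uneven_division_experiment(params: ModelParams, size_big: float,
                               size_small: float, n_cycles: int = 15,
                               rel_tol: float = 0.05
                               ) -> Tuple[List[float], List[float],
                                          Optional[int]]:
    """Follow the two daughters of an uneven division.

    Both cells are simulated independently (no noise, symmetric
    subsequent divisions).  Returns the two birth-size trajectories and
    the first generation at which both are within ``rel_tol`` of the
    steady-state birth size, or None if they never converge (the timer
    outcome: size deviations are inherited forever).
    """
    big = _birth_trajectory(params, size_big, n_cycles)
    small = _birth_trajectory(params, size_small, n_cycles)
    if params.size_dependence is SizeDependence.NONE:
        return big, small, None
    ss = simulate_steady_state(params, params.size_ref)
    target = ss.birth_size
    for i in range(n_cycles + 1):
        if abs(big[i] - target) <= rel_tol * target and \
                abs(small[i] - target) <= rel_tol * target:
            return big, small, i
    return big, small, None


def rgr_experiment(params: ModelParams,
                   g_values: Sequence[float]) -> pd.DataFrame:
    """Steady-state division size and cycle length across growth rates.

    For a sizer, faster-growing cells divide larger and cycle faster; for
    a timer, any growth rate whose doubling time differs from the fixed
    cycle length destabilises division size (flagged in ``stability``).
    """
    rows = []
    for g in g_values:
        p = replace(params, g_mean=g, g_sd=0.0, d_sd=0.0)
        ss = simulate_steady_state(p, p.size_ref, max_cycles=60)
        if params.size_dependence is SizeDependence.NONE:
            stab = "STABLE" if abs(ss.cycle_length - math.log(2.0) / g) \
                < p.dt else "LOST"
        else:
            stab = "STABLE" if ss.converged else "LOST"
        rows.append({"g": g, "division_size": ss.division_size,
                     "cycle_length": ss.cycle_length, "stability": stab})
    return pd.DataFrame(rows)


def _noisy_population(params: ModelParams, seed: int, duration: float,
                      burn_in: float) -> Tuple[pd.DataFrame,
                                               PopulationSummary]:
    cfg = PopulationConfig(params=params, n_init=100, cap=100,
                           duration=duration, burn_in=burn_in, seed=seed)
    return run_population(cfg)


def pcdk_mutant_experiment(params: ModelParams,
                           fold_changes: Sequence[float],
                           seed: int = 0, duration: float = 600.0,
                           burn_in: float = 200.0) -> pd.DataFrame:
    """CDK-production mutants: scale pCDK by each fold change and run a
    noisy 100-cell population.

    Size moves opposite to the rate (less CDK production -> larger cells)
    while mean cycle length stays put — the signature distinguishing CDK
    perturbations from growth-rate perturbations.
    """
    rows = []
    for i, f in enumerate(fold_changes):
        p = replace(params, pCDK=params.pCDK * f)
        _, summ = _noisy_population(p, seed + i, duration, burn_in)
        rows.append({"fold_change": f,
                     "division_size_mean": summ.division_size_mean,
                     "division_size_sd": summ.division_size_sd,
                     "cycle_length_mean": summ.cycle_length_mean,
                     "cycle_length_sd": summ.cycle_length_sd,
                     "n_cycles": summ.n_cycles})
    return pd.DataFrame(rows)


def exponent_variant_experiment(alphas: Sequence[float] = (1.0, 0.67, 0.34),
                                T: float = 100.0,
                                g: float = math.log(2.0) / 24.0,
                                dt: float = 0.1,
                                deviation: float = 0.4) -> pd.DataFrame:
    """Convergence speed of sub-linear size sensing.

    For each exponent alpha of the size-proportional production rate, the
    model is recalibrated to the same wild-type steady state and perturbed
    by an uneven division (+/- ``deviation`` of the steady birth size).
    Shallower sensing corrects deviations more slowly, so the number of
    cycles back to within 5% is non-decreasing as alpha falls.
    """
    rows = []
    for a in alphas:
        template = ModelParams(dt=dt, size_exponent=a,
                               size_dependence=SizeDependence.PCDK_PROP_SIZE)
        p = calibrate_one_transition(T, g, template=template)
        ss = simulate_steady_state(p, p.size_ref)
        b = ss.birth_size
        big, small, cycles = uneven_division_experiment(
            p, b * (1 + deviation), b * (1 - deviation), n_cycles=40)
        rows.append({"alpha": a, "pCDK": p.pCDK,
                     "steady_birth_size": b,
                     "convergence_cycles": cycles,
                     "stability": "STABLE" if cycles is not None else "LOST"})
    return pd.DataFrame(rows)


def two_transition_fold_scan(params: ModelParams, which: str,
                             folds: Optional[Sequence[float]] = None,
                             seed: int = 0, duration: float = 600.0,
                             burn_in: float = 200.0,
                             cycle_ref: Optional[float] = None
                             ) -> pd.DataFrame:
    """Reduce one phase's CDK production rate fold by fold and map where
    size control is lost.

    ``params`` must be a calibrated two-transition model (any sizer
    placement).  ``which`` is "pCDK_S" or "pCDK_M".  Each fold runs a
    noisy 100-cell population; phase lengths, sizes, and the stability
    classification are tabulated, plus the mean cycle length relative to
    the unperturbed (fold 1) run.
    """
    if which not in ("pCDK_S", "pCDK_M"):
        raise ValueError("which must be 'pCDK_S' or 'pCDK_M'")
    if not params.two_transition:
        raise ValueError("fold scan needs a two-transition model")
    if folds is None:
        folds = (DEFAULT_PCDK_S_FOLDS if which == "pCDK_S"
                 else DEFAULT_PCDK_M_FOLDS)
    if cycle_ref is None:
        cycle_ref = math.log(2.0) / params.g_mean
    rows = []
    wt_cycle = None
    for i, fold in enumerate(folds):
        if fold < 1:
            raise ValueError("folds are reductions; need fold >= 1")
        p = replace(params, **{which: getattr(params, which) / fold})
        table, summ = _noisy_population(p, seed + i, duration, burn_in)
        ts = summ.timeseries
        stab = classify_stability(ts["time"], ts["mean_size"], cycle_ref)
        if fold == 1.0 and wt_cycle is None:
            wt_cycle = summ.cycle_length_mean
        rows.append({"fold": fold,
                     "g1_mean": summ.g1_length_mean,
                     "g1_sd": summ.g1_length_sd,
                     "sgm_mean": summ.sgm_length_mean,
                     "sgm_sd": summ.sgm_length_sd,
                     "cycle_mean": summ.cycle_length_mean,
                     "cycle_sd": summ.cycle_length_sd,
                     "division_size_mean": summ.division_size_mean,
                     "division_size_sd": summ.division_size_sd,
                     "stability": stab})
    df = pd.DataFrame(rows)
    if wt_cycle is None:
        wt_cycle = df["cycle_mean"].iloc[0]
    df["cycle_rel_wt"] = df["cycle_mean"] / wt_cycle
    return df


def scan_boundaries(scan: pd.DataFrame,
                    cycle_tolerance: float = 0.05) -> Dict[str, Optional[float]]:
    """Largest stable fold with unchanged cycle length, and smallest fold
    classified LOST, from a fold-scan table (no interpolation)."""
    ok = scan[(scan["stability"] == "STABLE")
              & ((scan["cycle_rel_wt"] - 1.0).abs() <= cycle_tolerance)]
    lost = scan[scan["stability"] == "LOST"]
    return {
        "max_stable_fold": float(ok["fold"].max()) if len(ok) else None,
        "min_lost_fold": float(lost["fold"].min()) if len(lost) else None,
    }
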