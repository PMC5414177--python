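"""Parameterisation of the CDK-threshold models.

Thresholds are fixed at arbitrary values (only the rate/threshold ratio
matters); production rates are then solved by bisection so that the
noiseless, symmetrically dividing steady state reproduces the wild-type
behaviour: a doubling from 20 to 40 um^2 per cycle and, for the
two-transition model, a G1 phase occupying 60% of the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .model_core import (CellState, Event, ModelParams, _advance_inplace,
                         new_cell)

__all__ = [
    "CalibrationTarget",
    "SteadyState",
    "adder_closed_form_pcdk",
    "simulate_steady_state",
    "calibrate_one_transition",
    "calibrate_two_transition",
    "classify_stability",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Bisection could not bracket or reach the calibration target."""


@dataclass(frozen=True)
class CalibrationTarget:
    """Wild-type behaviour the rates are solved for."""

    birth_size_target: float = 20.0
    division_size_target: float = 40.0
    g1_fraction_target: float = 0.60
    tolerance: float = 1e-3   # relative, on sizes; absolute on G1 fraction

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise CalibrationError("tolerance must be positive "
                                   "(zero is unreachable)")
        if not 0.0 < self.g1_fraction_target < 1.0:
            raise ValueError("g1_fraction_target must lie in (0, 1)")
        if self.birth_size_target <= 0:
            raise ValueError("birth_size_target must be positive")


@dataclass(frozen=True)
class SteadyState:
    birth_size: float
    division_size: float
    cycle_length: float
    g1_length: Optional[float]
    g1_fraction: Optional[float]
    converged: bool
    n_cycles: int


def adder_closed_form_pcdk(T: float, g: float, delta_size: float,
                           size_ref: float) -> float:
    """Continuous-limit rate adding ``delta_size`` per cycle.

    For a size-proportional production sizer (alpha=1) the CDK integral
    between birth and threshold crossing is
    pCDK * (S_div - S_birth) / (g * size_ref), so a cell adds exactly
    g * T * size_ref / pCDK of area per cycle whatever its birth size
    (adder behaviour); invert for the rate.
    """
    if min(T, g, delta_size, size_ref) <= 0:
        raise ValueError("all inputs must be positive")
    return g * T * size_ref / delta_size


def _run_one_cycle(birth_size: float, params: ModelParams
                   ) -> Tuple[float, float, Optional[float]]:
    """(division size, cycle length, G1 length) of one noiseless cell.

    A cell that fails to divide within 20 doubling times (production rate
    far too low for its threshold) reports an infinite division size so
    that calibration searches steer away rather than abort.
    """
    cell = new_cell(birth_size, params, g=params.g_mean, d=50.0)
    max_steps = int(20 * math.log(2.0) / (params.g_mean * params.dt)) + 10000
    for _ in range(max_steps):
        event = _advance_inplace(cell, params, params.dt)
        if event is Event.DIVIDED:
            g1 = None
            if cell.g1s_time is not None:
                g1 = cell.g1s_time - cell.birth_time
            return cell.size, cell.age, g1
    g1 = None if cell.g1s_time is None else cell.g1s_time - cell.birth_time
    return math.inf, math.inf, g1


def simulate_steady_state(params: ModelParams, birth_size: float,
                          tol: float = 1e-3, max_cycles: int = 200
                          ) -> SteadyState:
    """Iterate single-lineage cycles (symmetric division, no noise) until
    consecutive birth sizes agree within ``tol`` (relative)."""
    b = birth_size
    last = None
    for i in range(1, max_cycles + 1):
        div, cyc, g1 = _run_one_cycle(b, params)
        if not math.isfinite(div):
            return SteadyState(b, div, cyc, g1, None, False, i)
        b_next = div / 2.0
        converged = abs(b_next - b) <= tol * b
        last = (b_next, div, cyc, g1)
        b = b_next
        if converged:
            frac = None if g1 is None or cyc == 0 else g1 / cyc
            return SteadyState(b_next, div, cyc, g1, frac, True, i)
    b_next, div, cyc, g1 = last
    frac = None if g1 is None or cyc == 0 else g1 / cyc
    return SteadyState(b_next, div, cyc, g1, frac, False, max_cycles)


def _bisect(fn, lo: float, hi: float, xtol_rel: float = 1e-10,
            max_iter: int = 200, expand: int = 12) -> float:
    """Bisection on a decreasing function of a positive rate.

    fn(rate) > 0 means the rate is too low (outcome above target).
    The bracket is expanded geometrically if needed.
    """
    flo, fhi = fn(lo), fn(hi)
    for _ in range(expand):
        if flo > 0 >= fhi:
            break
        if flo <= 0:
            lo /= 4.0
            flo = fn(lo)
        elif fhi > 0:
            hi *= 4.0
            fhi = fn(hi)
    else:
        raise CalibrationError(
            f"could not bracket the target: f({lo})={flo}, f({hi})={fhi}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = fn(mid)
        if fm == 0 or (hi - lo) <= xtol_rel * mid:
            return mid
        if fm > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_one_transition(T: float, g: float,
                             target: CalibrationTarget = CalibrationTarget(),
                             template: Optional[ModelParams] = None
                             ) -> ModelParams:
    """Solve pCDK so the sizer steady state divides at the target size.

    Bisection on pCDK (division size decreases monotonically with the
    rate), seeded by the continuous-limit closed form.
    """
    from .model_core import SizeDependence
    base = template if template is not None else ModelParams(
        size_dependence=SizeDependence.PCDK_PROP_SIZE)
    if base.size_dependence is SizeDependence.NONE or base.two_transition:
        raise CalibrationError("one-transition calibration needs a "
                               "single-transition sizer mode")
    base = replace(base, T_division=T, g_mean=g, g_sd=0.0, d_sd=0.0)
    delta = target.division_size_target - target.birth_size_target
    guess = adder_closed_form_pcdk(T, g, delta, base.size_ref)

    def objective(pcdk: float) -> float:
        p = replace(base, pCDK=pcdk)
        ss = simulate_steady_state(p, target.birth_size_target,
                                   tol=target.tolerance)
        return ss.division_size - target.division_size_target

    solved = _bisect(objective, guess / 4.0, guess * 4.0)
    result = replace(base, pCDK=solved)
    ss = simulate_steady_state(result, target.birth_size_target,
                               tol=target.tolerance)
    err = abs(ss.division_size - target.division_size_target)
    if err > max(10 * target.tolerance * target.division_size_target, 0.1):
        raise CalibrationError(
            f"calibration landed at division size {ss.division_size:.3f}, "
            f"target {target.division_size_target}")
    return result


def calibrate_two_transition(T_g1s: float, T_g2m: float, g: float,
                             target: CalibrationTarget = CalibrationTarget(),
                             template: Optional[ModelParams] = None
                             ) -> ModelParams:
    """Solve (pCDK_S, pCDK_M) for the two-transition wild type.

    Nested bisection: the outer loop tunes pCDK_S to the G1 fraction, the
    inner loop tunes pCDK_M to the division size.  Works for any sizer
    placement (G1/S only, G2/M only, or both); at least one sizer flag
    must be set or no steady state exists.
    """
    from .model_core import SizeDependence
    base = template if template is not None else ModelParams(
        two_transition=True, dt=0.1,
        size_dependence=SizeDependence.PCDK_PROP_SIZE)
    if not base.two_transition:
        raise CalibrationError("template must have two_transition=True")
    if not (base.sizer_at_g1s or base.sizer_at_g2m):
        raise CalibrationError("at least one sizer flag must be set")
    base = replace(base, T_g1s=T_g1s, T_g2m=T_g2m, g_mean=g,
                   g_sd=0.0, d_sd=0.0)

    doubling = math.log(2.0) / g
    t_g1 = target.g1_fraction_target * doubling
    # continuous-limit seeds at birth size = size_ref
    pS0 = g * T_g1s / (math.exp(g * t_g1) - 1.0)
    pM0 = g * T_g2m / (2.0 - math.exp(g * t_g1))
    b0 = target.birth_size_target

    def steady_for(pS: float, pM: float) -> SteadyState:
        p = replace(base, pCDK_S=pS, pCDK_M=pM)
        return simulate_steady_state(p, b0, tol=target.tolerance)

    def solve_pM(pS: float) -> float:
        def inner(pM: float) -> float:
            return (steady_for(pS, pM).division_size
                    - target.division_size_target)
        try:
            return _bisect(inner, pM0 / 4.0, pM0 * 4.0)
        except CalibrationError:
            # size target unreachable at this outer candidate (e.g. the
            # G1 phase alone already overshoots): best-effort rate so the
            # outer loop can keep steering on the G1 fraction
            lo, hi = pM0 / 256.0, pM0 * 256.0
            return lo if abs(inner(lo)) < abs(inner(hi)) else hi

    def outer(pS: float) -> float:
        ss = steady_for(pS, solve_pM(pS))
        if ss.g1_fraction is None:
            raise CalibrationError("no G1/S events recorded at steady state")
        return ss.g1_fraction - target.g1_fraction_target

    pS = _bisect(outer, pS0 / 4.0, pS0 * 4.0)
    pM = solve_pM(pS)
    result = replace(base, pCDK_S=pS, pCDK_M=pM)
    ss = simulate_steady_state(result, b0, tol=target.tolerance)
    if ss.g1_fraction is None or \
            abs(ss.g1_fraction - target.g1_fraction_target) > 0.02 or \
            abs(ss.division_size - target.division_size_target) > \
            max(10 * target.tolerance * target.division_size_target, 0.2):
        raise CalibrationError(
            f"infeasible targets for threshold ratio {T_g1s}:{T_g2m} "
            f"(reached division size {ss.division_size:.2f}, "
            f"G1 fraction {ss.g1_fraction})")
    return result


def classify_stability(times: Sequence[float], mean_sizes: Sequence[float],
                       cycle_ref: float,
                       drift_per_cycle: float = 0.05,
                       bound_factor: float = 10.0) -> str:
    """"STABLE" or "LOST" from a per-timepoint mean-size series.

    STABLE requires (a) the log-linear trend of mean size over the final
    half of the series to stay below ``drift_per_cycle`` fractional change
    per reference cycle length, and (b) mean size bounded below
    ``bound_factor`` times its initial value.  The series must span at
    least 10 reference cycles.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(mean_sizes, dtype=float)
    if t.ndim != 1 or t.shape != s.shape or len(t) < 4:
        raise ValueError("times and mean_sizes must be equal-length 1-D")
    if (t[-1] - t[0]) < 10 * cycle_ref:
        raise ValueError("series must span >= 10 reference cycle lengths")
    if np.any(s <= 0):
        return "LOST"
    if np.max(s) >= bound_factor * s[0]:
        return "LOST"
    half = t >= t[0] + 0.5 * (t[-1] - t[0])
    slope = np.polyfit(t[half], np.log(s[half]), 1)[0]
    if abs(slope) * cycle_ref > math.log1p(drift_per_cycle):
        return "LOST"
    return "STABLE"
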