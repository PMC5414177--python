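"""Single-cell CDK-accumulation cell-cycle engine.

Cells grow exponentially at a per-cell relative growth rate ``g`` while
producing active CDK at a rate ``pCDK``.  When accumulated CDK activity
strictly exceeds a threshold the cell passes a cycle transition; in the
one-transition model the single threshold triggers mitosis, in the
two-transition model a first threshold gates G1/S and a second gates G2/M.
Cell-size dependence can be placed on the production rate (activator
accumulation, optionally sub-linear in size) or on the threshold
(inhibitor dilution), which is what turns a "timer" cycle into a "sizer".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

__all__ = [
    "Phase",
    "Event",
    "SizeDependence",
    "ModelParams",
    "CellState",
    "grow_step",
    "cdk_production_rate",
    "effective_threshold",
    "advance_cell",
    "divide_cell",
    "new_cell",
]

# Division-ratio truncation bounds (percent of parent area to daughter 1).
# Observed divisions never approach such asymmetry; truncation prevents
# degenerate zero/negative daughter sizes from extreme normal draws.
D_MIN = 5.0
D_MAX = 95.0


class Phase(enum.Enum):
    """Cell-cycle phase. One-transition cells use INTERPHASE/MITOSIS;
    two-transition cells use G1/S_G2_M/MITOSIS."""

    INTERPHASE = "interphase"
    G1 = "G1"
    S_G2_M = "S-G2-M"
    MITOSIS = "mitosis"


class Event(enum.Enum):
    NONE = "none"
    G1S_TRANSITION = "g1s"
    DIVISION_TRIGGERED = "division_triggered"
    DIVIDED = "divided"


class SizeDependence(enum.Enum):
    """How cell size feeds back on cycle progression."""

    NONE = "none"                        # timer: no feedback
    PCDK_PROP_SIZE = "pcdk_prop_size"    # activator accumulation sizer
    THRESHOLD_INV_SIZE = "threshold_inv_size"  # inhibitor dilution sizer
    PCDK_INV_SIZE = "pcdk_inv_size"      # reversed variant
    THRESHOLD_PROP_SIZE = "threshold_prop_size"  # reversed variant


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    Parameters
    ----------
    dt : time step in hours (default 1).
    g_mean, g_sd : mean/sd of the per-cell relative growth rate (h^-1);
        each cell draws its own ``g`` at birth (truncated > 0).
    d_mean, d_sd : mean/sd of the division ratio ``d`` in percent of parent
        area inherited by the first daughter (truncated to [5, 95]).
    pCDK : CDK production rate (a.u. h^-1), one-transition model.
    T_division : CDK threshold triggering mitosis, one-transition model.
    size_dependence : where size feedback acts (see SizeDependence).
    size_exponent : exponent alpha for PCDK_PROP_SIZE (1, 0.67 or 0.34).
    size_ref : normalisation size (um^2) so rates keep their units for
        every alpha; default 20, the wild-type birth size.
    two_transition : use the sequential CDK_S / CDK_M model.
    pCDK_S, pCDK_M : phase production rates (two-transition).
    T_g1s, T_g2m : G1/S and G2/M thresholds (two-transition).
    sizer_at_g1s, sizer_at_g2m : apply ``size_dependence`` to that phase.
    mitosis_steps : steps mitosis takes (growth continues, CDK frozen).
    rgr_size_slope : optional size-dependent RGR term,
        g_eff = g + slope * (size - size_ref); default 0.
    """

    dt: float = 1.0
    g_mean: float = math.log(2.0) / 24.0
    g_sd: float = 0.0
    d_mean: float = 50.0
    d_sd: float = 0.0
    pCDK: float = 3.15
    T_division: float = 100.0
    size_dependence: SizeDependence = SizeDependence.NONE
    size_exponent: float = 1.0
    size_ref: float = 20.0
    two_transition: bool = False
    pCDK_S: float = 5.6
    pCDK_M: float = 11.9
    T_g1s: float = 100.0
    T_g2m: float = 200.0
    sizer_at_g1s: bool = True
    sizer_at_g2m: bool = True
    mitosis_steps: int = 1
    rgr_size_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        for name in ("pCDK", "T_division", "pCDK_S", "pCDK_M", "T_g1s",
                     "T_g2m", "size_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.d_mean < 100.0:
            raise ValueError("d_mean must lie in (0, 100)")
        if self.d_sd < 0 or self.g_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mitosis_steps < 1:
            raise ValueError("mitosis_steps must be >= 1")


@dataclass
class CellState:
    """One simulated cell.

    ``cdk`` is the currently accumulating activity: total CDK in the
    one-transition model, CDK_S during G1 and CDK_M during S-G2-M in the
    two-transition model (it resets to 0 at birth and at G1/S).
    """

    size: float
    g: float
    d: float
    phase: Phase
    cdk: float = 0.0
    age: float = 0.0
    birth_size: float = 0.0
    birth_time: float = 0.0
    g1s_time: Optional[float] = None
    g1s_size: Optional[float] = None
    lineage_id: int = 0
    parent_id: Optional[int] = None
    mitosis_elapsed: int = field(default=0, repr=False)

    def copy(self) -> "CellState":
        return replace(self)


def new_cell(size: float, params: ModelParams, g: float, d: float,
             birth_time: float = 0.0, lineage_id: int = 0,
             parent_id: Optional[int] = None) -> CellState:
    """A newborn cell: CDK reset, age 0, phase G1 (or INTERPHASE)."""
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    phase = Phase.G1 if params.two_transition else Phase.INTERPHASE
    return CellState(size=size, g=g, d=d, phase=phase, birth_size=size,
                     birth_time=birth_time, lineage_id=lineage_id,
                     parent_id=parent_id)


# ---------------------------------------------------------------------------
# Elementary update rules
# ---------------------------------------------------------------------------

def grow_step(size: float, g: float, dt: float) -> float:
    """Exact exponential growth over one step: size * exp(g * dt)."""
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return size * math.exp(g * dt)


def cdk_production_rate(size: float, params: ModelParams,
                        which: str = "single") -> float:
    """CDK production rate at the given size (a.u. h^-1).

    ``which`` selects the base rate: "single" -> pCDK, "S" -> pCDK_S,
    "M" -> pCDK_M.  Size dependence (if the mode puts it on the rate, and
    for two-transition phases only if the matching sizer flag is set) is
    applied relative to ``size_ref``.
    """
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if which == "single":
        base, sized = params.pCDK, True
    elif which == "S":
        base, sized = params.pCDK_S, params.sizer_at_g1s
    elif which == "M":
        base, sized = params.pCDK_M, params.sizer_at_g2m
    else:
        raise ValueError(f"unknown rate selector {which!r}")
    mode = params.size_dependence
    if not sized or mode in (SizeDependence.NONE,
                             SizeDependence.THRESHOLD_INV_SIZE,
                             SizeDependence.THRESHOLD_PROP_SIZE):
        return base
    if mode is SizeDependence.PCDK_PROP_SIZE:
        return base * (size / params.size_ref) ** params.size_exponent
    if mode is SizeDependence.PCDK_INV_SIZE:
        return base * params.size_ref / size
    raise ValueError(f"unknown size-dependence mode {mode!r}")


def effective_threshold(size: float, params: ModelParams,
                        which: str = "single") -> float:
    """CDK threshold at the given size (a.u.), for threshold-side sizers."""
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if which == "single":
        base, sized = params.T_division, True
    elif which == "G1S":
        base, sized = params.T_g1s, params.sizer_at_g1s
    elif which == "G2M":
        base, sized = params.T_g2m, params.sizer_at_g2m
    else:
        raise ValueError(f"unknown threshold selector {which!r}")
    mode = params.size_dependence
    if not sized or mode in (SizeDependence.NONE,
                             SizeDependence.PCDK_PROP_SIZE,
                             SizeDependence.PCDK_INV_SIZE):
        return base
    if mode is SizeDependence.THRESHOLD_INV_SIZE:
        return base * params.size_ref / size
    if mode is SizeDependence.THRESHOLD_PROP_SIZE:
        return base * size / params.size_ref
    raise ValueError(f"unknown size-dependence mode {mode!r}")


# ---------------------------------------------------------------------------
# One step of the cycle
# ---------------------------------------------------------------------------

def _advance_inplace(cell: CellState, params: ModelParams,
                     dt: float) -> Event:
    """Advance ``cell`` by one step of ``dt`` hours, mutating it.

    Order within a step: grow (rate feedback frozen at start-of-step size),
    accumulate CDK, compare strictly against the threshold.  Growth
    continues during mitosis; CDK does not.
    """
    s0 = cell.size
    g_eff = cell.g + params.rgr_size_slope * (s0 - params.size_ref)
    cell.size = grow_step(s0, g_eff, dt)
    cell.age += dt

    if cell.phase is Phase.MITOSIS:
        cell.mitosis_elapsed += 1
        if cell.mitosis_elapsed >= params.mitosis_steps:
            return Event.DIVIDED
        return Event.NONE

    if cell.phase is Phase.G1 and params.two_transition:
        cell.cdk += cdk_production_rate(s0, params, "S") * dt
        if cell.cdk > effective_threshold(s0, params, "G1S"):
            cell.phase = Phase.S_G2_M
            cell.cdk = 0.0
            cell.g1s_time = cell.birth_time + cell.age
            cell.g1s_size = cell.size
            return Event.G1S_TRANSITION
        return Event.NONE

    if cell.phase is Phase.S_G2_M:
        cell.cdk += cdk_production_rate(s0, params, "M") * dt
        if cell.cdk > effective_threshold(s0, params, "G2M"):
            cell.phase = Phase.MITOSIS
            cell.mitosis_elapsed = 0
            return Event.DIVISION_TRIGGERED
        return Event.NONE

    # one-transition interphase
    cell.cdk += cdk_production_rate(s0, params, "single") * dt
    if cell.cdk > effective_threshold(s0, params, "single"):
        cell.phase = Phase.MITOSIS
        cell.mitosis_elapsed = 0
        return Event.DIVISION_TRIGGERED
    return Event.NONE


def advance_cell(cell: CellState, params: ModelParams,
                 dt: Optional[float] = None) -> Tuple[CellState, Event]:
    """Advance a cell by one time step; returns (new state, event).

    The input state is not modified.  ``dt`` defaults to ``params.dt``.
    """
    step = params.dt if dt is None else dt
    if step < 0:
        raise ValueError("dt must be non-negative")
    out = cell.copy()
    if step == 0:
        return out, Event.NONE
    event = _advance_inplace(out, params, step)
    return out, event


def divide_cell(cell: CellState, params: ModelParams, rng,
                id1: int = 0, id2: int = 1
                ) -> Tuple[CellState, CellState]:
    """Split a post-mitotic cell into two daughters.

    The first daughter receives ``d`` percent of the parent area (the
    parent's pre-assigned ratio); the second gets the remainder, so the
    daughter areas sum exactly to the parent area.  Each daughter draws a
    fresh ``g`` and ``d`` at birth.
    """
    if cell.phase is not Phase.MITOSIS or \
            cell.mitosis_elapsed < params.mitosis_steps:
        raise RuntimeError("divide_cell called before mitosis completion")
    a1 = cell.size * cell.d / 100.0
    a2 = cell.size - a1
    t = cell.birth_time + cell.age
    d1 = new_cell(a1, params, g=sample_g(params, rng),
                  d=sample_d(params, rng), birth_time=t,
                  lineage_id=id1, parent_id=cell.lineage_id)
    d2 = new_cell(a2, params, g=sample_g(params, rng),
                  d=sample_d(params, rng), birth_time=t,
                  lineage_id=id2, parent_id=cell.lineage_id)
    return d1, d2


def sample_g(params: ModelParams, rng) -> float:
    """Per-cell RGR drawn at birth: Normal(g_mean, g_sd), truncated > 0."""
    if params.g_sd == 0:
        return params.g_mean
    while True:
        g = rng.normal(params.g_mean, params.g_sd)
        if g > 0:
            return g


def sample_d(params: ModelParams, rng) -> float:
    """Per-cell division ratio drawn at birth, truncated to [5, 95] %."""
    if params.d_sd == 0:
        return min(max(params.d_mean, D_MIN), D_MAX)
    d = rng.normal(params.d_mean, params.d_sd)
    return min(max(d, D_MIN), D_MAX)
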