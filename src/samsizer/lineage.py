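"""Measurement formulas and statistics for lineage-tracking tables.

Operates on tidy tables of tracked cells (one row per cell: identifiers,
birth/division/G1-S event times in hours, outer cell surface areas in
um^2, optional developmental-zone label).  Both simulated output and
measured tracking data use the same schema.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "compute_rgr",
    "infer_interval_length",
    "sister_pair_table",
    "binomial_tail_greater",
    "convergence_test",
    "classify_phase_from_markers",
    "zone_summary",
    "ASYMMETRY_THRESHOLD",
]

# Sister pairs differing by more than this at birth count as asymmetric
# divisions (um^2 of outer surface area).
ASYMMETRY_THRESHOLD = 5.0


def compute_rgr(a0: float, a1: float, t0: float, t1: float) -> float:
    """Relative growth rate (ln A1 - ln A0) / (t1 - t0), in h^-1."""
    if a0 <= 0 or a1 <= 0:
        raise ValueError("areas must be positive")
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    return (math.log(a1) - math.log(a0)) / (t1 - t0)


def infer_interval_length(area_start: float, area_end: float,
                          rgr: float) -> float:
    """Hours needed to grow from one area to another at a given RGR.

    Inverts the RGR formula; applied to (mean birth, mean division) areas
    it yields cycle length, to (birth, G1/S) the G1 length and to
    (G1/S, division) the S-G2-M length.
    """
    if area_start <= 0 or area_end <= 0:
        raise ValueError("areas must be positive")
    if rgr <= 0:
        raise ValueError("rgr must be positive")
    return (math.log(area_end) - math.log(area_start)) / rgr


def sister_pair_table(table: pd.DataFrame,
                      sync_resolution: float = 0.0,
                      asymmetry_threshold: float = ASYMMETRY_THRESHOLD
                      ) -> pd.DataFrame:
    """Per-division statistics for sister pairs that both completed a cycle.

    Differences are signed larger-at-birth minus smaller-at-birth:
    ``delta_birth`` (um^2, >= 0), ``delta_cycle`` (h, negative when the
    larger daughter divided first), ``delta_growth`` (um^2 of area added
    over the cycle).  ``asymmetric`` flags pairs differing by more than
    the threshold at birth, ``synchronous`` pairs dividing within
    ``sync_resolution`` hours of each other, and ``closer_at_division``
    pairs whose area difference shrank between birth and division.
    """
    done = table[table["division_time"].notna() & table["parent_id"].notna()]
    rows = []
    for parent, grp in done.groupby("parent_id", sort=True):
        if len(grp) != 2:
            continue
        a, b = grp.iloc[0], grp.iloc[1]
        if a["birth_area"] >= b["birth_area"]:
            big, small = a, b
        else:
            big, small = b, a
        delta_birth = float(big["birth_area"] - small["birth_area"])
        cyc_big = float(big["division_time"] - big["birth_time"])
        cyc_small = float(small["division_time"] - small["birth_time"])
        delta_cycle = cyc_big - cyc_small
        growth_big = float(big["division_area"] - big["birth_area"])
        growth_small = float(small["division_area"] - small["birth_area"])
        div_diff = abs(float(big["division_area"] - small["division_area"]))
        rows.append({
            "pair_id": parent,
            "delta_birth": delta_birth,
            "delta_cycle": delta_cycle,
            "delta_growth": growth_big - growth_small,
            "asymmetric": delta_birth > asymmetry_threshold,
            "synchronous": abs(delta_cycle) <= sync_resolution,
            "closer_at_division": div_diff < delta_birth,
        })
    return pd.DataFrame(rows, columns=["pair_id", "delta_birth",
                                       "delta_cycle", "delta_growth",
                                       "asymmetric", "synchronous",
                                       "closer_at_division"])


def binomial_tail_greater(k: int, n: int, p: float) -> float:
    """Exact strictly-greater binomial tail P(X > k), X ~ Binomial(n, p).

    Computed by direct summation of the probability mass function.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p < 1.0:
        raise ValueError("need 0 < p < 1")
    q = 1.0 - p
    total = 0.0
    for i in range(k + 1, n + 1):
        total += math.comb(n, i) * p ** i * q ** (n - i)
    return min(total, 1.0)


def convergence_test(pairs: pd.DataFrame) -> Tuple[int, int, float]:
    """Do asymmetric sister pairs converge in size by division?

    Among pairs flagged asymmetric, counts those closer in size at
    division than at birth and tests the count against a null of one half
    with the exact tail P(X >= k) = P(X > k-1).  Returns
    (k_closer, n_asymmetric, p_value).
    """
    asym = pairs[pairs["asymmetric"]]
    n = len(asym)
    if n == 0:
        raise ValueError("no asymmetric pairs")
    k = int(asym["closer_at_division"].sum())
    p = 1.0 if k == 0 else binomial_tail_greater(k - 1, n, 0.5)
    return k, n, p


def classify_phase_from_markers(edu: bool, venus: bool) -> str:
    """Cycle phase from EdU incorporation and an S-G2-M reporter.

    The reporter switches on at G1/S and is degraded at mitosis, so
    double-negative cells are in G1, double-positive cells in S, and
    reporter-only cells in G2-M.  EdU without the reporter is not an
    expected state and is flagged INCONSISTENT.
    """
    if edu and venus:
        return "S"
    if venus:
        return "G2_M"
    if edu:
        return "INCONSISTENT"
    return "G1"


def zone_summary(table: pd.DataFrame,
                 zone_column: str = "zone") -> pd.DataFrame:
    """Per-developmental-zone means and sds of size and timing measures.

    One row per zone label: birth area, division area, cycle length,
    per-cell RGR, and (where G1/S events are recorded) G1 and S-G2-M
    lengths.  Unknown labels simply form their own group.
    """
    if zone_column not in table.columns:
        raise ValueError(f"table has no column {zone_column!r}")
    df = table.copy()
    df["cycle_length"] = df["division_time"] - df["birth_time"]
    df["rgr"] = (np.log(df["division_area"]) - np.log(df["birth_area"])) \
        / df["cycle_length"]
    df["g1_length"] = df["g1s_time"] - df["birth_time"]
    df["sgm_length"] = df["division_time"] - df["g1s_time"]
    agg = df.groupby(zone_column, dropna=False).agg(
        n=("cell_id", "size"),
        birth_area_mean=("birth_area", "mean"),
        birth_area_sd=("birth_area", "std"),
        division_area_mean=("division_area", "mean"),
        division_area_sd=("division_area", "std"),
        cycle_length_mean=("cycle_length", "mean"),
        cycle_length_sd=("cycle_length", "std"),
        rgr_mean=("rgr", "mean"),
        rgr_sd=("rgr", "std"),
        g1_length_mean=("g1_length", "mean"),
        g1_length_sd=("g1_length", "std"),
        sgm_length_mean=("sgm_length", "mean"),
        sgm_length_sd=("sgm_length", "std"),
    )
    return agg.reset_index()
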