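"""Delimited-text serialisation of lineage tables and run manifests.

Tables are comma-separated UTF-8 with a header row and ``NA`` for missing
optional fields; the column set is ``LINEAGE_COLUMNS``.  Manifests are
JSON records from which any stochastic run can be reproduced exactly
(full resolved config + seed).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .population import LINEAGE_COLUMNS

__all__ = [
    "read_lineage_table",
    "write_lineage_table",
    "validate_lineage_table",
    "LineageTableError",
    "write_manifest",
]

_NUMERIC = ["birth_time", "division_time", "birth_area", "division_area",
            "g1s_time", "g1s_area"]


class LineageTableError(ValueError):
    """Schema or invariant violation in a lineage table."""


def validate_lineage_table(table: pd.DataFrame, strict: bool = True,
                           area_tolerance: float = 1e-6) -> List[str]:
    """Check lineage-table invariants.

    Checks: required columns, division after birth, positive areas,
    daughters born when the parent divides, and daughter birth areas
    summing to the parent division area (within ``area_tolerance``,
    relative; measured data should pass a loosened tolerance).  In strict
    mode the first report raises ``LineageTableError``; otherwise all
    reports are returned, with offending row indices named.
    """
    issues: List[str] = []
    missing = [c for c in LINEAGE_COLUMNS if c not in table.columns]
    if missing:
        issues.append(f"missing columns: {missing}")
        if strict:
            raise LineageTableError(issues[0])
        return issues

    has_div = table["division_time"].notna()
    bad = table.index[has_div
                      & (table["division_time"] <= table["birth_time"])]
    for i in bad:
        issues.append(f"row {i}: division_time <= birth_time")
    for col in ("birth_area", "division_area", "g1s_area"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.notna() & (vals <= 0)]
        for i in bad:
            issues.append(f"row {i}: non-positive {col}")

    by_id = table.set_index("cell_id", drop=False)
    dup = by_id.index[by_id.index.duplicated()]
    for i in dup:
        issues.append(f"duplicate cell_id {i}")
    if not len(dup):
        with_parent = table[table["parent_id"].notna()]
        for parent, grp in with_parent.groupby("parent_id"):
            if parent not in by_id.index:
                continue
            prow = by_id.loc[parent]
            if pd.isna(prow["division_time"]):
                continue
            for i, row in grp.iterrows():
                if abs(row["birth_time"] - prow["division_time"]) > 1e-9:
                    issues.append(
                        f"row {i}: birth_time {row['birth_time']} != "
                        f"parent division_time {prow['division_time']}")
            if len(grp) == 2 and pd.notna(prow["division_area"]):
                total = grp["birth_area"].sum()
                if abs(total - prow["division_area"]) > \
                        area_tolerance * prow["division_area"]:
                    rows = list(grp.index)
                    issues.append(
                        f"rows {rows}: daughter birth areas sum to "
                        f"{total:.4f}, parent division area "
                        f"{prow['division_area']:.4f}")
    if strict and issues:
        raise LineageTableError("; ".join(issues))
    return issues


def write_lineage_table(table: pd.DataFrame,
                        path: Union[str, Path]) -> None:
    """Write a lineage table as CSV (header row, NA for missing)."""
    out = table[LINEAGE_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="NA")


def read_lineage_table(path: Union[str, Path], strict: bool = False,
                       area_tolerance: float = 1e-6) -> pd.DataFrame:
    """Read a lineage-table CSV; optionally enforce invariants.

    Lossless round trip with ``write_lineage_table``.  Malformed files
    (missing columns, non-numeric measurements) raise
    ``LineageTableError`` regardless of mode.
    """
    try:
        table = pd.read_csv(path, na_values=["NA"])
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise LineageTableError(f"unreadable lineage table {path}: {e}")
    missing = [c for c in LINEAGE_COLUMNS if c not in table.columns]
    if missing:
        raise LineageTableError(f"{path}: missing columns {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[table[col].notna() & coerced.isna()]
        if len(bad):
            raise LineageTableError(
                f"{path}: non-numeric {col} in rows {list(bad)}")
        table[col] = coerced
    validate_lineage_table(table, strict=strict,
                           area_tolerance=area_tolerance)
    return table


def write_manifest(path: Union[str, Path], command: str, config: Dict,
                   seed: Optional[int], outputs: List[str],
                   wall_time: float) -> None:
    """JSON run manifest: command, resolved config, seed, version,
    produced files and wall time."""
    from . import __version__

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "value"):   # enums
            return o.value
        return str(o)

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "outputs": outputs,
        "wall_time_s": round(wall_time, 3),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=default))
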