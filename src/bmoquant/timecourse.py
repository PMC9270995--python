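"""Homing dynamics and CFSE-dilution tracking across time points.

Each imaged organoid contributes one record per time point: the number of
homed cells detected inside it and that count as a percentage of the cells
initially seeded.  CFSE intensity halves with every cell division, so a
cell's division count (generation k) follows from its intensity relative to
the labeling intensity I0: k = round(log2(I0 / intensity)).  The dilution
check is purely descriptive — it reports per-time median intensities and
flags intervals where the median drops by at least 40%, the pattern expected
if the rise in cell counts came from proliferation rather than continued
migration into the organoid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "homing_summary",
    "condition_summary",
    "cfse_generation",
    "dilution_check",
]

HALVING_FLAG_DROP = 0.40  # fractional median drop that flags suspected division


def homing_summary(
    cell_table: pd.DataFrame,
    n_seeded: int,
    organoids: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-organoid, per-time homed-cell counts and normalized percentages.

    Parameters
    ----------
    cell_table
        Tidy per-cell table with one row per detected homed cell; required
        columns ``organoid_id`` and ``time_h``, optional ``condition``,
        ``treatment`` and ``intensity``.
    n_seeded
        Number of cells initially seeded per organoid (> 0).
    organoids
        Optional roster of all imaged (organoid_id, time_h[, condition,
        treatment]) combinations, so organoids with zero detected cells still
        appear with a count of 0.

    Returns one row per (organoid_id, time_h) with ``n_cells`` and
    ``pct_homed`` = 100·n_cells/n_seeded.
    """
    if n_seeded <= 0:
        raise ValueError("n_seeded must be > 0")
    keys = ["organoid_id", "time_h"]
    label_cols = [c for c in ("condition", "treatment") if c in cell_table.columns]
    if cell_table.empty:
        counts = pd.DataFrame(columns=keys + label_cols + ["n_cells"])
    else:
        counts = (
            cell_table.groupby(keys + label_cols, dropna=False)
            .size()
            .rename("n_cells")
            .reset_index()
        )
    if organoids is not None:
        counts = organoids.merge(counts, on=keys + [c for c in label_cols if c in organoids.columns], how="left")
        counts["n_cells"] = counts["n_cells"].fillna(0).astype(int)
    out = counts.copy()
    out["pct_homed"] = 100.0 * out["n_cells"] / n_seeded
    return out.sort_values(keys).reset_index(drop=True)


def condition_summary(records: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean and SD of counts and homing percentages across organoids."""
    if by is None:
        by = [c for c in ("condition", "treatment", "time_h") if c in records.columns]
    agg = (
        records.groupby(by, dropna=False)
        .agg(
            n_organoids=("n_cells", "size"),
            mean_n_cells=("n_cells", "mean"),
            sd_n_cells=("n_cells", "std"),
            mean_pct_homed=("pct_homed", "mean"),
            sd_pct_homed=("pct_homed", "std"),
        )
        .reset_index()
    )
    return agg


def cfse_generation(intensity, i0: float, k_max: int = 8):
    """CFSE division count from intensity halving: k = round(log2(I0/I)).

    Clipped to [0, k_max]; non-positive intensities yield NaN (flagged
    undefined).  Accepts scalars or arrays.
    """
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    arr = np.asarray(intensity, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.full(arr.shape, np.nan)
    pos = arr > 0
    out[pos] = np.clip(np.round(np.log2(i0 / arr[pos])), 0, k_max)
    if scalar:
        v = out[0]
        return int(v) if np.isfinite(v) else float("nan")
    return out


def dilution_check(intensity_table: pd.DataFrame) -> pd.DataFrame:
    """Per-time median CFSE intensity with a halving-consistency flag.

    Input: one row per cell with columns ``time_h`` and ``intensity``.
    Output: one row per time point with the median intensity, the fractional
    drop relative to the previous time point, and ``proliferation_suspected``
    — True when the median fell by at least 40% over the interval.  Purely
    descriptive; no hypothesis test.
    """
    if not {"time_h", "intensity"}.issubset(intensity_table.columns):
        raise ValueError("intensity_table needs columns 'time_h' and 'intensity'")
    med = (
        intensity_table.groupby("time_h")["intensity"]
        .agg(["median", "size"])
        .rename(columns={"median": "median_intensity", "size": "n_cells"})
        .reset_index()
        .sort_values("time_h")
        .reset_index(drop=True)
    )
    prev = med["median_intensity"].shift(1)
    med["drop_fraction"] = 1.0 - med["median_intensity"] / prev
    med["proliferation_suspected"] = med["drop_fraction"] >= HALVING_FLAG_DROP
    med.loc[0, "proliferation_suspected"] = False
    return med
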