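"""Tabular record types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .network import NetworkMetrics

__all__ = ["CellRecord", "OrganoidRecord", "cells_to_frame"]


@dataclass
class CellRecord:
    """One detected (or ground-truth) cell.

    Distances are attached by the distance stage: ``d_o_um`` to the organoid
    surface, ``d_n_um`` to the endothelial network surface (None when the
    organoid has no network, e.g. a pure-MSC condition).  ``generation`` is
    the CFSE division count k inferred from intensity halving.
    """

    cell_id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    volume_um3: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    peak_intensity: Optional[float] = None
    d_o_um: Optional[float] = None
    d_n_um: Optional[float] = None
    generation: Optional[int] = None
    excluded: bool = False
    voxels: Optional[np.ndarray] = None  # (n, 3) zyx indices of the cell volume

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("cell volume must be > 0")
        for name in ("d_o_um", "d_n_um"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Flatten cell records to a tidy table (one row per cell)."""
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "z_um": c.centroid_um[0],
            "y_um": c.centroid_um[1],
            "x_um": c.centroid_um[2],
            "volume_um3": c.volume_um3,
            "peak_intensity": c.peak_intensity,
            "d_o_um": c.d_o_um,
            "d_n_um": c.d_n_um,
            "generation": c.generation,
            "excluded": c.excluded,
        }
        for ch, v in c.mean_intensity.items():
            row[f"mean_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OrganoidRecord:
    """Per-organoid summary assembled by the pipeline."""

    organoid_id: str
    condition: str = ""
    estimated_volume_um3: float = 0.0
    radius_major_um: float = 0.0
    radius_minor_um: float = 0.0
    network: NetworkMetrics = field(default_factory=NetworkMetrics)
    expected_d_o_um: Optional[float] = None
    expected_d_n_um: Optional[float] = None
    n_cells: int = 0
    fraction_below_expected_o: Optional[float] = None
    fraction_below_expected_n: Optional[float] = None
    pct_homed: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fraction_below_expected_o", "fraction_below_expected_n"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("network")
        d.update(self.network.as_dict())
        return d
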