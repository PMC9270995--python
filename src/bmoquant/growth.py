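"""Organoid growth from brightfield microwell plates and ellipse-fit volume.

Growth is read out from 2D brightfield images of a hydrogel microwell array
(11×11 = 121 round-bottom microwells of 400 µm diameter per well): aggregates
appear as dark particles on a brighter background, and per-microwell particle
areas track organoid size over days in culture.

Organoid volume from a 3D mask uses the equivalent-ellipse estimator: the
mask is projected along the optical (z) axis, an ellipse is fitted to the
projection by second-order image moments, and

    Vol = 4/3 · π · R_major · R_minor²

with the semi-axes of the fitted ellipse.  The formula is exact for spheres
and for prolate ellipsoids lying in the imaging plane; for oblate shapes
flattened along z it overestimates the true volume by roughly the ratio of
the in-plane to the axial radius — a documented bias of the estimator, kept
because it is the field's standard projection-based read-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .grids import BinaryMask

__all__ = [
    "PlateLayout",
    "PlateImage",
    "VolumeEstimate",
    "measure_growth",
    "estimate_volume",
]


@dataclass
class PlateLayout:
    """Geometry of one microwell array (one plate well).

    Defaults describe an 11×11 array of 400 µm microwells; ``origin_um`` is
    the (y, x) position of the first microwell centre in image coordinates.
    """

    rows: int = 11
    cols: int = 11
    microwell_diameter_um: float = 400.0
    pitch_um: float = 450.0
    origin_um: tuple[float, float] = (225.0, 225.0)
    n_wells_per_plate: int = 24

    def __post_init__(self) -> None:
        if self.microwell_diameter_um > self.pitch_um:
            raise ValueError("microwell diameter must not exceed the pitch")
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")

    @property
    def n_microwells(self) -> int:
        return self.rows * self.cols

    def centers_um(self) -> np.ndarray:
        """(n, 2) array of microwell centre (y, x) positions in µm."""
        yy, xx = np.meshgrid(
            self.origin_um[0] + np.arange(self.rows) * self.pitch_um,
            self.origin_um[1] + np.arange(self.cols) * self.pitch_um,
            indexing="ij",
        )
        return np.column_stack([yy.ravel(), xx.ravel()])


@dataclass
class PlateImage:
    """A 2D brightfield image calibrated in µm per pixel."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("plate image must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def measure_growth(
    image: PlateImage,
    layout: PlateLayout,
    well_id: str = "A1",
    day: float = 0.0,
    threshold: float | None = None,
    area_bounds_um2: tuple[float, float] = (5e3, 2e5),
) -> pd.DataFrame:
    """Per-microwell aggregate area by thresholding and particle analysis.

    Aggregates are darker than the background: the image is inverse-
    thresholded (Otsu by default), connected particles are measured, and each
    particle is assigned to the microwell whose region-of-interest circle
    (radius = pitch/2) contains its centroid.  Particles outside the area
    bounds are dropped as debris (below) or flagged merged (above).  Every
    microwell yields one record; empty microwells are flagged, not dropped.

    Returns a table with one row per microwell:
    ``well_id, microwell_index, row, col, day, area_um2,
    equivalent_diameter_um, n_particles, flag``.
    """
    px = image.pixel_size_um
    centers = layout.centers_um()
    h_um, w_um = (np.asarray(image.values.shape) * px)
    r_roi = layout.pitch_um / 2.0
    if (centers[:, 0].max() + r_roi > h_um) or (centers[:, 1].max() + r_roi > w_um) or (
        centers.min() - r_roi < -px
    ):
        raise ValueError("layout is not registered to the image: ROIs fall outside it")

    thr = threshold if threshold is not None else threshold_otsu(image.values)
    fg = image.values < thr
    labels = measure.label(fg, connectivity=2)
    props = measure.regionprops(labels)

    area_min, area_max = area_bounds_um2
    # assign particles to microwells by centroid
    per_well: dict[int, list] = {i: [] for i in range(layout.n_microwells)}
    img_shape = image.values.shape
    for p in props:
        area_um2 = p.area * px * px
        if area_um2 < area_min:
            continue
        cy, cx = np.asarray(p.centroid) * px
        d2 = (centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2
        idx = int(np.argmin(d2))
        if d2[idx] > r_roi**2:
            continue
        touches_edge = (
            p.bbox[0] == 0
            or p.bbox[1] == 0
            or p.bbox[2] == img_shape[0]
            or p.bbox[3] == img_shape[1]
        )
        per_well[idx].append((area_um2, touches_edge, area_um2 > area_max))

    rows = []
    for idx in range(layout.n_microwells):
        particles = per_well[idx]
        if not particles:
            area, flag, n_particles = 0.0, "empty", 0
        else:
            particles.sort(reverse=True)
            area, at_edge, merged = particles[0]
            n_particles = len(particles)
            if merged:
                flag = "merged"
            elif at_edge:
                flag = "edge"
            elif n_particles > 1:
                flag = "multi"
            else:
                flag = "ok"
        rows.append(
            {
                "well_id": well_id,
                "microwell_index": idx,
                "row": idx // layout.cols,
                "col": idx % layout.cols,
                "day": day,
                "area_um2": area,
                "equivalent_diameter_um": 2.0 * np.sqrt(area / np.pi),
                "n_particles": n_particles,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VolumeEstimate:
    volume_um3: float
    radius_major_um: float
    radius_minor_um: float


def estimate_volume(mask: BinaryMask) -> VolumeEstimate:
    """Ellipse-fit volume of an organoid mask.

    Projects the mask along z, fits the equivalent ellipse of the (largest)
    projected region via second-order moments and applies
    Vol = 4/3·π·R_major·R_minor².
    """
    if mask.is_empty():
        raise ValueError("cannot estimate volume of an empty mask")
    _, dy, dx = mask.spacing_um
    proj = mask.values.any(axis=0)
    labels = measure.label(proj, connectivity=2)
    props = measure.regionprops(labels, spacing=(dy, dx))
    largest = max(props, key=lambda p: p.area)
    r_major = largest.axis_major_length / 2.0
    r_minor = largest.axis_minor_length / 2.0
    vol = 4.0 / 3.0 * np.pi * r_major * r_minor**2
    return VolumeEstimate(float(vol), float(r_major), float(r_minor))
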