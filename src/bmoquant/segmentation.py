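"""Organoid surface, endothelial-network mask and labeled-cell detection.

The organoid body is segmented from the smoothed nuclear/mesenchymal channel
(Gaussian smoothing in physical units, global threshold, hole filling,
largest connected component).  The endothelial network is segmented from the
CD31 channel restricted to the organoid mask, with small speckle objects
removed.  Labeled cells (CD45 or CFSE tracer) are detected as blobs with a
scale-matched Laplacian-of-Gaussian filter; only cells whose centroid falls
inside the organoid mask are returned — that is the operational definition
of a *homed* cell.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .grids import BinaryMask, VoxelGrid
from .records import CellRecord

__all__ = ["segment_organoid", "segment_network", "detect_cells", "NoForegroundError"]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoForegroundError(ValueError):
    """Raised when thresholding finds no organoid."""


def _smooth(img: np.ndarray, sigma_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if sigma_um == 0:
        return img.astype(float)
    sigma_vox = sigma_um / np.asarray(spacing)
    return ndi.gaussian_filter(img.astype(float), sigma=sigma_vox)


def _threshold(img: np.ndarray, method: str, threshold: float | None,
               within: np.ndarray | None = None) -> float:
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        return float(threshold)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    vals = img[within] if within is not None else img.ravel()
    if vals.size == 0 or np.ptp(vals) == 0:
        raise NoForegroundError("no organoid found: image has no contrast")
    return float(threshold_otsu(vals))


def segment_organoid(
    grid: VoxelGrid,
    channel: str | int = "DAPI",
    sigma_um: float = 2.0,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Segment the organoid body from a smoothed nuclear/mesenchymal channel.

    Smoothing sigma is given in µm and converted per axis, so anisotropic
    stacks are smoothed isotropically in physical space.  After thresholding,
    interior holes are filled and only the largest 26-connected component is
    kept (one organoid per stack; a smaller second object is discarded).
    """
    img = _smooth(grid.channel(channel), sigma_um, grid.spacing_um)
    try:
        thr = _threshold(img, method, threshold)
    except NoForegroundError:
        raise NoForegroundError("no organoid found")
    fg = img > thr
    if not fg.any():
        raise NoForegroundError("no organoid found")
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg, structure=_STRUCT_26)
    if n > 1:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(fg, grid.spacing_um)


def segment_network(
    grid: VoxelGrid,
    organoid: BinaryMask,
    channel: str | int = "CD31",
    sigma_um: float = 1.0,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_um3: float = 100.0,
) -> BinaryMask:
    """Segment the endothelial network inside the organoid.

    The threshold is computed from voxels inside the organoid only.  Objects
    smaller than ``min_object_um3`` are removed as speckle.  An empty result
    is valid (a pure-MSC organoid has no network) and is logged, not raised.
    """
    if organoid.is_empty():
        raise ValueError("organoid mask is empty")
    img = _smooth(grid.channel(channel), sigma_um, grid.spacing_um)
    empty = BinaryMask(np.zeros_like(organoid.values), grid.spacing_um)
    try:
        thr = _threshold(img, method, threshold, within=organoid.values)
    except NoForegroundError:
        logger.warning("no network: CD31 channel has no contrast inside the organoid")
        return empty
    fg = (img > thr) & organoid.values
    # drop speckle below the minimum physical object size
    min_vox = int(np.ceil(min_object_um3 / organoid.voxel_volume_um3))
    labels, n = ndi.label(fg, structure=_STRUCT_26)
    if n:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_vox) + 1
        fg = np.isin(labels, keep)
    if not fg.any():
        logger.warning("no network found inside the organoid")
        return empty
    return BinaryMask(fg, grid.spacing_um)


def detect_cells(
    grid: VoxelGrid,
    organoid: BinaryMask,
    channel: str | int = "tracer",
    diameter_range_um: tuple[float, float] = (6.0, 14.0),
    threshold_rel: float = 0.02,
    min_separation_um: float | None = None,
    num_sigma: int = 4,
    snr_min: float = 7.0,
) -> list[CellRecord]:
    """Detect labeled cells as blobs; keep those homed inside the organoid.

    A Laplacian-of-Gaussian scale stack spanning the expected diameter range
    finds intensity peaks; peaks closer than ``min_separation_um`` (default:
    the minimum diameter) are merged, brightest wins.  Around each surviving
    peak the cell volume is segmented locally at half the peak intensity,
    giving the centroid, volume and per-channel mean intensities.  Cells
    whose centroid lies outside the organoid mask are discarded ("homed" =
    centroid strictly inside).  An empty channel yields an empty list — zero
    homed cells is a valid result.
    """
    d_min, d_max = diameter_range_um
    if not (2.0 < d_min < d_max < 30.0):
        raise ValueError("diameter_range_um must be increasing and within (2, 30) µm")
    if min_separation_um is None:
        min_separation_um = d_min
    spacing = np.asarray(grid.spacing_um)
    img = grid.channel(channel).astype(float)
    vmax = img.max()
    if vmax <= 0:
        return []

    # blob radius r relates to the LoG scale by r = sigma * sqrt(3) in 3D
    sig_lo = d_min / 2.0 / np.sqrt(3.0) / spacing
    sig_hi = d_max / 2.0 / np.sqrt(3.0) / spacing
    blobs = blob_log(
        img / vmax,
        min_sigma=sig_lo,
        max_sigma=sig_hi,
        num_sigma=num_sigma,
        threshold=threshold_rel,
        overlap=0.8,
    )
    if blobs.size == 0:
        return []
    peaks_vox = blobs[:, :3].astype(int)

    # validate candidates against the robust background on a scale-matched
    # smoothed copy: white noise that slips past the LoG threshold rarely
    # survives matched smoothing at the cell scale
    smooth = ndi.gaussian_filter(img, sigma=(d_min / 4.0) / spacing)
    med = float(np.median(smooth))
    mad_sd = 1.4826 * float(np.median(np.abs(smooth - med)))
    floor = med + snr_min * mad_sd
    sm_vals = smooth[peaks_vox[:, 0], peaks_vox[:, 1], peaks_vox[:, 2]]
    peaks_vox = peaks_vox[sm_vals > floor]
    if peaks_vox.size == 0:
        return []
    peak_vals = img[peaks_vox[:, 0], peaks_vox[:, 1], peaks_vox[:, 2]]

    # greedy non-maximum suppression at the physical separation limit
    order = np.argsort(peak_vals)[::-1]
    kept: list[int] = []
    pos_um = peaks_vox * spacing
    for i in order:
        if all(np.linalg.norm(pos_um[i] - pos_um[j]) >= min_separation_um for j in kept):
            kept.append(i)

    half_box = np.ceil((d_max / 2.0) / spacing).astype(int)
    voxvol = grid.voxel_volume_um3
    channels = grid.channel_names or ("ch0",)

    records: list[CellRecord] = []
    cell_id = 0
    for i in kept:
        vox = peaks_vox[i]
        lo = np.maximum(vox - half_box, 0)
        hi = np.minimum(vox + half_box + 1, img.shape)
        local = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        peak_val = img[tuple(vox)]
        lmask = local >= 0.5 * peak_val
        # keep only the component containing the peak
        lab, _ = ndi.label(lmask, structure=_STRUCT_26)
        lmask = lab == lab[tuple(vox - lo)]
        cell_vox = np.argwhere(lmask) + lo
        w = local[lmask]
        centroid_um = (cell_vox * spacing * w[:, None]).sum(axis=0) / w.sum()
        centroid_vox = np.round(centroid_um / spacing).astype(int)
        if not organoid.values[tuple(np.clip(centroid_vox, 0, np.asarray(img.shape) - 1))]:
            continue
        mean_int = {
            str(ch): float(
                grid.channel(ci)[cell_vox[:, 0], cell_vox[:, 1], cell_vox[:, 2]].mean()
            )
            for ci, ch in enumerate(channels)
        }
        records.append(
            CellRecord(
                cell_id=cell_id,
                centroid_um=tuple(centroid_um),
                volume_um3=float(len(cell_vox)) * voxvol,
                mean_intensity=mean_int,
                peak_intensity=float(peak_val),
                voxels=cell_vox,
            )
        )
        cell_id += 1
    return records
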