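"""Seeded, ground-truthed synthetic organoid images.

Everything downstream of acquisition is testable against this module: it
builds a roughly spherical organoid body, grows a tubular endothelial-like
capsule network inside it (biased toward the outer region, where endothelial
cells preferentially arrange), places point-like cells by a configurable
spatial law, renders multi-channel confocal-like stacks (optical blur,
Gaussian + Poisson noise, CFSE intensity halving per division), and draws 2D
brightfield views of an 11×11 microwell array.  Every stochastic operation is
a pure function of its inputs and a seed, and each generated scene carries a
:class:`TruthBundle` with the true masks, vessel graph and per-cell positions
and distances.

Placement laws
--------------
``uniform``       — independent uniform draws over organoid voxels outside
                    the network: the null model of the distance statistics.
``perivascular``  — rejection sampling with acceptance weight
                    exp(−D_n / scale_um): cells attracted to the vessel
                    surface with a single length-scale knob; recovers the
                    uniform law as scale → ∞.
``depth_biased``  — acceptance weight exp((D_o − max D_o) / scale_um):
                    cells attracted to the organoid core (large distance from
                    the surface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .distances import distance_channel
from .grids import BinaryMask, VoxelGrid
from .growth import PlateImage, PlateLayout

__all__ = [
    "ShapeSpec",
    "VesselParams",
    "PlacementLaw",
    "OpticsModel",
    "CellTruth",
    "TruthBundle",
    "make_organoid_mask",
    "make_vessel_network",
    "place_cells",
    "render_image",
    "make_brightfield_plate",
    "true_branch_junction_counts",
]

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("DAPI", "CD31", "tracer")


# ---------------------------------------------------------------------------
# parameter records


@dataclass
class ShapeSpec:
    """Geometry of the organoid body (a ball or axis-aligned ellipsoid)."""

    kind: Literal["ball", "ellipsoid"] = "ball"
    radii_um: tuple[float, ...] = (120.0,)
    center_um: tuple[float, float, float] | None = None  # defaults to grid centre

    def full_radii(self) -> tuple[float, float, float]:
        r = tuple(float(x) for x in self.radii_um)
        if any(x <= 0 for x in r):
            raise ValueError("degenerate shape: all radii must be > 0")
        if self.kind == "ball":
            if len(r) != 1:
                raise ValueError("a ball takes exactly one radius")
            return (r[0], r[0], r[0])
        if len(r) == 1:
            return (r[0], r[0], r[0])
        if len(r) == 2:  # axial, in-plane
            return (r[0], r[1], r[1])
        if len(r) == 3:
            return r  # type: ignore[return-value]
        raise ValueError("radii_um takes 1-3 positive lengths")


@dataclass
class VesselParams:
    """Knobs of the random capsule-tree vessel generator.

    Root segments start on a shell at 0.6-0.9 of the organoid radius;
    each branch event splits a growing tip into two daughters.  ``outer_bias``
    (0-1) blends segment headings toward the local tangent plane, so biased
    networks wrap around the outer region instead of plunging inward.
    ``min_clearance_um`` keeps non-adjacent segments apart (default: two
    vessel diameters plus a little), which keeps the true graph and the
    skeleton of the rasterised mask topologically identical.
    """

    n_seeds: int = 4
    n_branch_events: int = 8
    segment_length_um: float = 45.0
    vessel_radius_um: float = 5.0
    outer_bias: float = 0.5
    min_clearance_um: float | None = None

    def __post_init__(self) -> None:
        if self.segment_length_um <= 0 or self.vessel_radius_um <= 0:
            raise ValueError("segment length and vessel radius must be > 0")
        if not 0.0 <= self.outer_bias <= 1.0:
            raise ValueError("outer_bias must lie in [0, 1]")

    @property
    def clearance_um(self) -> float:
        if self.min_clearance_um is not None:
            return self.min_clearance_um
        return 4.5 * self.vessel_radius_um


@dataclass
class PlacementLaw:
    """Spatial law for seeding cells inside the organoid."""

    kind: Literal["uniform", "perivascular", "depth_biased"] = "uniform"
    scale_um: float | None = None

    def __post_init__(self) -> None:
        if self.kind != "uniform":
            if self.scale_um is None or self.scale_um <= 0:
                raise ValueError(f"{self.kind} placement requires scale_um > 0")


@dataclass
class OpticsModel:
    """Confocal-like acquisition model: blur, background, noise, quantisation."""

    psf_sigma_um: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (z, y, x)
    background_level: float = 10.0
    gaussian_noise_sd: float = 2.0
    poisson_scaling: float = 0.0  # photons per intensity unit; 0 disables shot noise
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("psf sigmas must be >= 0")
        if self.gaussian_noise_sd < 0 or self.poisson_scaling < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def noiseless(cls) -> "OpticsModel":
        return cls(psf_sigma_um=(0.0, 0.0, 0.0), background_level=0.0,
                   gaussian_noise_sd=0.0, poisson_scaling=0.0)


@dataclass
class CellTruth:
    """Ground truth for one planted cell."""

    centroid_um: tuple[float, float, float]
    radius_um: float
    generation: int
    d_o_um: float
    d_n_um: float | None


@dataclass
class TruthBundle:
    """Everything the generator knows about a synthetic scene."""

    organoid_mask: BinaryMask
    network_mask: BinaryMask
    vessel_graph: nx.Graph
    cells: list[CellTruth] = field(default_factory=list)
    placement: PlacementLaw | None = None
    seed: int | None = None

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return self.organoid_mask.spacing_um


# ---------------------------------------------------------------------------
# organoid body


def make_organoid_mask(
    spec: ShapeSpec,
    spacing_um: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
) -> BinaryMask:
    """Voxelise a ball/ellipsoid; the mask is connected and hole-free."""
    radii = np.asarray(spec.full_radii())
    spacing = np.asarray(spacing_um, dtype=float)
    shape = np.asarray(grid_shape)
    extent = (shape - 1) * spacing
    if spec.center_um is None:
        center = extent / 2.0
    else:
        center = np.asarray(spec.center_um, dtype=float)
    if np.any(center - radii < -spacing) or np.any(center + radii > extent + spacing):
        raise ValueError("shape exceeds the grid extent")
    zz = (np.arange(shape[0]) * spacing[0] - center[0]) / radii[0]
    yy = (np.arange(shape[1]) * spacing[1] - center[1]) / radii[1]
    xx = (np.arange(shape[2]) * spacing[2] - center[2]) / radii[2]
    q = (
        zz[:, None, None] ** 2
        + yy[None, :, None] ** 2
        + xx[None, None, :] ** 2
    )
    return BinaryMask(q <= 1.0, tuple(spacing))


# ---------------------------------------------------------------------------
# vessel network


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _rotate(h: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of unit vector h about unit axis."""
    return (
        h * np.cos(angle)
        + np.cross(axis, h) * np.sin(angle)
        + axis * np.dot(axis, h) * (1 - np.cos(angle))
    )


def _tangential_bias(h: np.ndarray, radial: np.ndarray, bias: float) -> np.ndarray:
    """Blend a heading toward the tangent plane of the radial direction."""
    tang = h - np.dot(h, radial) * radial
    tn = np.linalg.norm(tang)
    if tn < 1e-9:
        return h
    blended = (1 - bias) * h + bias * tang / tn
    return _unit(blended)


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D line segments."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = np.dot(u, u), np.dot(u, v), np.dot(v, v)
    d, e = np.dot(u, w), np.dot(v, w)
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for clamped t
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


def _paint_capsule(mask: np.ndarray, p0, p1, radius: float, spacing: np.ndarray) -> None:
    """OR a capsule (cylinder with hemispherical caps) into a voxel mask."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, mask.shape)
    if np.any(i0 >= i1):
        return
    zz = np.arange(i0[0], i1[0]) * spacing[0]
    yy = np.arange(i0[1], i1[1]) * spacing[1]
    xx = np.arange(i0[2], i1[2]) * spacing[2]
    P = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1)
    u = p1 - p0
    L2 = np.dot(u, u)
    w = P - p0
    t = np.clip((w @ u) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(P.shape[:-1])
    closest = p0 + t[..., None] * u
    d2 = np.sum((P - closest) ** 2, axis=-1)
    mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= radius**2


def make_vessel_network(
    organoid: BinaryMask,
    params: VesselParams,
    seed: int = 0,
) -> tuple[BinaryMask, nx.Graph]:
    """Grow a random capsule-tree network inside the organoid.

    Returns the rasterised vessel mask (clipped to the organoid) and the true
    centreline graph: nodes carry ``coord_um``, edges carry ``length_um``.
    Deterministic per seed.  Branch events that cannot be placed without
    violating the clearance constraint are dropped (the graph records what
    was actually placed).
    """
    if organoid.is_empty():
        raise ValueError("organoid mask is empty")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(organoid.spacing_um)

    # interior depth map: how far inside the organoid each point lies
    depth = ndi.distance_transform_edt(organoid.values, sampling=spacing)
    center = np.asarray(ndi.center_of_mass(organoid.values)) * spacing
    r_eq = (3.0 * organoid.volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    def depth_at(points: np.ndarray) -> np.ndarray:
        coords = (points / spacing).T
        return ndi.map_coordinates(depth, coords, order=1, mode="constant")

    margin = params.vessel_radius_um + 1.5 * float(spacing.max())

    segments: list[tuple[int, int, np.ndarray, np.ndarray]] = []  # (na, nb, p0, p1)
    graph = nx.Graph()
    next_node = 0
    tips: list[tuple[int, np.ndarray]] = []  # (node id, heading)

    def stays_inside(p0: np.ndarray, p1: np.ndarray) -> bool:
        pts = p0 + np.linspace(0, 1, 9)[:, None] * (p1 - p0)
        return bool(np.all(depth_at(pts) >= margin))

    def inward_fallback(p0: np.ndarray, h: np.ndarray, radial: np.ndarray) -> np.ndarray | None:
        """Heading kept if its segment stays inside; else its outward radial
        component is reflected inward and the reflected heading is tried."""
        if stays_inside(p0, p0 + params.segment_length_um * h):
            return h
        out = np.dot(h, radial)
        if out <= 0:
            return None
        h_ref = _unit(h - 2.0 * out * radial)
        if stays_inside(p0, p0 + params.segment_length_um * h_ref):
            return h_ref
        return None

    def capsule_fits(p0: np.ndarray, p1: np.ndarray, shared_nodes: set[int]) -> bool:
        if not stays_inside(p0, p1):
            return False
        for na, nb, q0, q1 in segments:
            if na in shared_nodes or nb in shared_nodes:
                continue
            if _segment_distance(p0, p1, q0, q1) < params.clearance_um:
                return False
        return True

    def add_segment(node_a: int | None, p0: np.ndarray, p1: np.ndarray):
        nonlocal next_node
        if node_a is None:
            node_a = next_node
            graph.add_node(node_a, coord_um=tuple(p0))
            next_node += 1
        node_b = next_node
        graph.add_node(node_b, coord_um=tuple(p1))
        next_node += 1
        graph.add_edge(node_a, node_b, length_um=float(np.linalg.norm(p1 - p0)))
        segments.append((node_a, node_b, p0.copy(), p1.copy()))
        return node_a, node_b

    min_pair_angle = np.deg2rad(45.0)

    # --- roots on a shell at 0.6-0.9 of the organoid radius
    for _ in range(params.n_seeds):
        placed = False
        for _attempt in range(300):
            u = _unit(rng.normal(size=3))
            r = rng.uniform(0.6, 0.9) * r_eq
            p0 = center + r * u
            if depth_at(p0[None])[0] < margin:
                continue
            h = _unit(rng.normal(size=3))
            h = _tangential_bias(h, u, params.outer_bias)
            h = inward_fallback(p0, h, u)
            if h is None:
                continue
            p1 = p0 + params.segment_length_um * h
            if capsule_fits(p0, p1, set()):
                _, nb = add_segment(None, p0, p1)
                tips.append((nb, h))
                placed = True
                break
        if not placed:
            logger.warning("could not place a root segment; continuing with fewer")

    # --- branch events: a tip splits into two daughters
    for _ in range(params.n_branch_events):
        if not tips:
            break
        placed = False
        order = rng.permutation(len(tips))
        for ti in order:
            tip_node, h = tips[ti]
            p0 = np.asarray(graph.nodes[tip_node]["coord_um"])
            radial = _unit(p0 - center) if np.linalg.norm(p0 - center) > 1e-9 else np.array([0.0, 0.0, 1.0])
            for _attempt in range(60):
                axis = _unit(np.cross(h, rng.normal(size=3)))
                th1 = rng.uniform(np.deg2rad(30), np.deg2rad(55))
                th2 = rng.uniform(np.deg2rad(30), np.deg2rad(55))
                h1 = _tangential_bias(_unit(_rotate(h, axis, th1)), radial, params.outer_bias)
                h2 = _tangential_bias(_unit(_rotate(h, axis, -th2)), radial, params.outer_bias)
                h1 = inward_fallback(p0, h1, radial)
                h2 = inward_fallback(p0, h2, radial)
                if h1 is None or h2 is None:
                    continue
                back = -h
                ok_angles = (
                    np.arccos(np.clip(np.dot(h1, h2), -1, 1)) >= min_pair_angle
                    and np.arccos(np.clip(np.dot(h1, back), -1, 1)) >= min_pair_angle
                    and np.arccos(np.clip(np.dot(h2, back), -1, 1)) >= min_pair_angle
                )
                if not ok_angles:
                    continue
                q1 = p0 + params.segment_length_um * h1
                q2 = p0 + params.segment_length_um * h2
                shared = {tip_node}
                if not capsule_fits(p0, q1, shared) or not capsule_fits(p0, q2, shared):
                    continue
                # siblings diverge from the same junction; beyond the junction
                # zone their capsules must separate cleanly
                if (
                    _segment_distance(p0 + 0.5 * (q1 - p0), q1, p0 + 0.5 * (q2 - p0), q2)
                    < 2.5 * params.vessel_radius_um
                ):
                    continue
                _, n1 = add_segment(tip_node, p0, q1)
                _, n2 = add_segment(tip_node, p0, q2)
                tips.pop(ti)
                tips.append((n1, h1))
                tips.append((n2, h2))
                placed = True
                break
            if placed:
                break
        if not placed:
            logger.warning("branch event dropped: no admissible placement found")

    if not segments:
        raise ValueError("vessel parameters produced an empty network")

    vessel = np.zeros(organoid.values.shape, dtype=bool)
    for _, _, p0, p1 in segments:
        _paint_capsule(vessel, p0, p1, params.vessel_radius_um, spacing)
    vessel &= organoid.values
    return BinaryMask(vessel, organoid.spacing_um), graph


def true_branch_junction_counts(graph: nx.Graph) -> tuple[int, int]:
    """(n_branches, n_junctions) of a true vessel graph.

    Branches are maximal paths between nodes of degree ≠ 2 (degree-2 nodes
    are geometric waypoints, not topological events), matching what a
    skeleton of the rasterised mask resolves.
    """
    if graph.number_of_nodes() == 0:
        return 0, 0
    n_junctions = sum(1 for n in graph.nodes if graph.degree(n) >= 3)
    # contract degree-2 chains: each maximal path contributes one branch
    terminal_deg = sum(graph.degree(n) for n in graph.nodes if graph.degree(n) != 2)
    n_branches = terminal_deg // 2
    # pure cycles (components whose nodes are all degree 2) count as 1 branch
    for comp in nx.connected_components(graph):
        if all(graph.degree(n) == 2 for n in comp):
            n_branches += 1
    return n_branches, n_junctions


# ---------------------------------------------------------------------------
# cell placement


def place_cells(
    organoid: BinaryMask,
    network: BinaryMask | None,
    n: int,
    law: PlacementLaw,
    seed: int = 0,
    cell_radius_um: float = 4.0,
    generations: Sequence[int] | int = 0,
    min_separation_um: float | None = None,
) -> list[CellTruth]:
    """Place ``n`` cells inside the organoid (outside the network) by a law.

    Uniform: independent uniform draws over the admissible voxels.
    Perivascular / depth-biased: rejection sampling on the same voxel set
    with acceptance weights exp(−D_n/scale) and exp((D_o − max D_o)/scale).
    True distances D_o and D_n (µm) are recorded per cell from the true
    masks' distance channels.

    ``min_separation_um`` adds a hard-core constraint (cells are bodies, not
    points, and cannot interpenetrate): draws from the law are thinned until
    all pairwise centre distances reach the limit.  Default None keeps the
    laws' pure independent-draw form, which the null-model statistics assume.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    has_network = network is not None and not network.is_empty()
    admissible = organoid.values.copy()
    if has_network:
        admissible &= ~network.values
    candidates = np.argwhere(admissible)
    if n > len(candidates):
        raise ValueError(f"cannot place {n} cells in {len(candidates)} admissible voxels")
    if n == 0:
        return []

    dist_o = distance_channel(organoid, organoid, "organoid_surface")
    dist_n = (
        distance_channel(network, BinaryMask(admissible, organoid.spacing_um), "network_surface")
        if has_network
        else None
    )

    d_o_all = dist_o.values[admissible]
    d_n_all = dist_n.values[admissible] if dist_n is not None else None

    if law.kind == "uniform":
        weights = None
    elif law.kind == "perivascular":
        if d_n_all is None:
            raise ValueError("perivascular placement requires a non-empty network")
        weights = np.exp(-d_n_all / law.scale_um)
    elif law.kind == "depth_biased":
        weights = np.exp((d_o_all - d_o_all.max()) / law.scale_um)
    else:  # pragma: no cover
        raise ValueError(f"unknown placement law {law.kind!r}")

    spacing = np.asarray(organoid.spacing_um)

    def draw(k: int) -> np.ndarray:
        if weights is None:
            return rng.integers(0, len(candidates), size=k)
        return _rejection_sample(rng, weights, k)

    if min_separation_um is None:
        idx = draw(n)
    else:
        accepted: list[int] = []
        pos: list[np.ndarray] = []
        for _ in range(200 * max(n, 1)):
            if len(accepted) == n:
                break
            j = int(draw(1)[0])
            p = candidates[j] * spacing
            if all(np.linalg.norm(p - q) >= min_separation_um for q in pos):
                accepted.append(j)
                pos.append(p)
        if len(accepted) < n:
            raise ValueError(
                f"could not place {n} cells at separation {min_separation_um} µm"
            )
        idx = np.asarray(accepted)
    gens = np.full(n, generations) if np.isscalar(generations) else np.asarray(generations)
    if gens.shape != (n,):
        raise ValueError("generations must be a scalar or length-n sequence")

    cells = []
    for i, j in enumerate(idx):
        vox = candidates[j]
        cells.append(
            CellTruth(
                centroid_um=tuple(vox * spacing),
                radius_um=cell_radius_um,
                generation=int(gens[i]),
                d_o_um=float(d_o_all[j]),
                d_n_um=float(d_n_all[j]) if d_n_all is not None else None,
            )
        )
    return cells


def _rejection_sample(rng: np.random.Generator, weights: np.ndarray, n: int) -> np.ndarray:
    """Indices of n accepted draws; proposals uniform over the weight array."""
    out = np.empty(n, dtype=int)
    got = 0
    while got < n:
        batch = max(4 * (n - got), 256)
        props = rng.integers(0, len(weights), size=batch)
        accept = rng.random(batch) < weights[props]
        taken = props[accept][: n - got]
        out[got : got + len(taken)] = taken
        got += len(taken)
    return out


def build_truth(
    organoid: BinaryMask,
    network: BinaryMask,
    vessel_graph: nx.Graph,
    cells: list[CellTruth],
    law: PlacementLaw | None = None,
    seed: int | None = None,
) -> TruthBundle:
    return TruthBundle(organoid, network, vessel_graph, cells, law, seed)


# ---------------------------------------------------------------------------
# rendering


def render_image(
    truth: TruthBundle,
    optics: OpticsModel | None = None,
    seed: int = 0,
    i0: float = 1000.0,
    organoid_level: float = 400.0,
    network_level: float = 800.0,
) -> VoxelGrid:
    """Render a 3-channel stack (DAPI/ENG proxy, CD31, tracer) from truth.

    The organoid mask fills the nuclear/mesenchymal channel, the vessel mask
    the CD31 channel, and each cell adds a Gaussian blob to the tracer
    channel with peak intensity i0 / 2**generation (CFSE halves with every
    division).  Blobs are composited with a voxelwise maximum so the planted
    peak intensity is exact before blur and noise.  Channels are then blurred
    by the PSF, shot noise (Poisson) and Gaussian read noise are applied on
    top of a constant background, and values are clipped to the bit depth.
    """
    optics = optics or OpticsModel()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(truth.spacing_um)
    shape = truth.organoid_mask.values.shape
    if truth.network_mask.values.shape != shape:
        raise ValueError("truth masks must share one grid")

    chans = np.zeros((3,) + shape, dtype=float)
    chans[0][truth.organoid_mask.values] = organoid_level
    chans[1][truth.network_mask.values] = network_level

    tracer = chans[2]
    for cell in truth.cells:
        peak = i0 / (2.0 ** cell.generation)
        _paint_blob(tracer, np.asarray(cell.centroid_um), cell.radius_um / 2.0, peak, spacing)

    sigma_vox = np.asarray(optics.psf_sigma_um) / spacing
    for c in range(3):
        if np.any(sigma_vox > 0):
            chans[c] = ndi.gaussian_filter(chans[c], sigma=sigma_vox)
        img = chans[c] + optics.background_level
        if optics.poisson_scaling > 0:
            img = rng.poisson(np.maximum(img, 0) * optics.poisson_scaling) / optics.poisson_scaling
        if optics.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, optics.gaussian_noise_sd, size=shape)
        chans[c] = np.clip(img, 0.0, 2.0**optics.bit_depth - 1)

    return VoxelGrid(chans, truth.spacing_um, DEFAULT_CHANNELS)


def _paint_blob(img: np.ndarray, center_um: np.ndarray, sigma_um: float, peak: float,
                spacing: np.ndarray) -> None:
    """Composite a Gaussian blob via voxelwise maximum (peak stays exact)."""
    half = 3.5 * sigma_um
    i0 = np.maximum(np.floor((center_um - half) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((center_um + half) / spacing).astype(int) + 1, img.shape)
    zz = np.arange(i0[0], i1[0]) * spacing[0] - center_um[0]
    yy = np.arange(i0[1], i1[1]) * spacing[1] - center_um[1]
    xx = np.arange(i0[2], i1[2]) * spacing[2] - center_um[2]
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    blob = peak * np.exp(-d2 / (2.0 * sigma_um**2))
    view = img[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    np.maximum(view, blob, out=view)


# ---------------------------------------------------------------------------
# brightfield plate


def make_brightfield_plate(
    layout: PlateLayout,
    aggregate_radii_um: Sequence[float] | np.ndarray,
    seed: int = 0,
    pixel_size_um: float = 5.0,
    background_level: float = 200.0,
    aggregate_level: float = 60.0,
    noise_sd: float = 2.0,
):
    """Draw a brightfield view of one microwell array plus its truth table.

    Each microwell holds one dark circular aggregate of the given radius
    (0 = empty), centred in the well.  Returns ``(PlateImage, DataFrame)``;
    the truth table carries per-microwell area (π r²) and an ``oversize``
    warning flag when the aggregate diameter exceeds the microwell diameter.
    """
    radii = np.asarray(aggregate_radii_um, dtype=float)
    if radii.shape != (layout.n_microwells,):
        raise ValueError(f"need {layout.n_microwells} radii, got {radii.shape}")
    if np.any(radii < 0):
        raise ValueError("aggregate radii must be >= 0")
    rng = np.random.default_rng(seed)

    h_um = 2 * layout.origin_um[0] + (layout.rows - 1) * layout.pitch_um
    w_um = 2 * layout.origin_um[1] + (layout.cols - 1) * layout.pitch_um
    shape = (int(np.ceil(h_um / pixel_size_um)), int(np.ceil(w_um / pixel_size_um)))
    img = np.full(shape, background_level, dtype=float)

    yy = (np.arange(shape[0]) + 0.5) * pixel_size_um
    xx = (np.arange(shape[1]) + 0.5) * pixel_size_um
    centers = layout.centers_um()

    rows = []
    for idx, ((cy, cx), r) in enumerate(zip(centers, radii)):
        if r > 0:
            j0 = np.searchsorted(yy, cy - r) ; j1 = np.searchsorted(yy, cy + r) + 1
            k0 = np.searchsorted(xx, cx - r) ; k1 = np.searchsorted(xx, cx + r) + 1
            d2 = (yy[j0:j1, None] - cy) ** 2 + (xx[None, k0:k1] - cx) ** 2
            img[j0:j1, k0:k1][d2 <= r**2] = aggregate_level
        rows.append(
            {
                "microwell_index": idx,
                "row": idx // layout.cols,
                "col": idx % layout.cols,
                "radius_um": r,
                "area_um2": np.pi * r**2,
                "oversize": bool(2 * r > layout.microwell_diameter_um),
            }
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)

    import pandas as pd

    return PlateImage(img, pixel_size_um), pd.DataFrame(rows)
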