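"""End-to-end orchestration: config in, per-organoid result bundle out.

A :class:`RunConfig` fully determines a run: simulation parameters (or input
stack paths), every stage parameter, and the seed.  ``run`` executes
simulate → segment → network → distances → volume and assembles an
:class:`~bmoquant.records.OrganoidRecord`, a per-cell table and distance
histograms.  Identical config + seed give identical outputs; every file
written carries the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as bio
from .distances import (
    cell_distances,
    distance_channel,
    distance_distribution,
    expected_distance,
    fraction_below_expected,
)
from .grids import BinaryMask, VoxelGrid
from .growth import estimate_volume
from .network import network_metrics, skeletonize_mask
from .records import OrganoidRecord, cells_to_frame
from .segmentation import detect_cells, segment_network, segment_organoid
from .synthetic import (
    OpticsModel,
    PlacementLaw,
    ShapeSpec,
    TruthBundle,
    VesselParams,
    make_organoid_mask,
    make_vessel_network,
    place_cells,
    render_image,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SimulateConfig", "run", "simulate_scene"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ShapeConfig(_Strict):
    kind: Literal["ball", "ellipsoid"] = "ball"
    radii_um: list[float] = [120.0]


class VesselConfig(_Strict):
    enabled: bool = True
    n_seeds: int = 4
    n_branch_events: int = 8
    segment_length_um: float = 45.0
    vessel_radius_um: float = 5.0
    outer_bias: float = 0.5
    min_clearance_um: Optional[float] = None


class PlacementConfig(_Strict):
    kind: Literal["uniform", "perivascular", "depth_biased"] = "uniform"
    scale_um: Optional[float] = None
    min_separation_um: Optional[float] = None


class OpticsConfig(_Strict):
    psf_sigma_um: list[float] = [0.0, 0.0, 0.0]
    background_level: float = 0.0
    gaussian_noise_sd: float = 0.0
    poisson_scaling: float = 0.0
    bit_depth: int = 16


class SimulateConfig(_Strict):
    grid_shape: list[int] = [192, 192, 192]
    spacing_um: list[float] = [1.0, 1.0, 1.0]
    shape: ShapeConfig = ShapeConfig()
    vessels: VesselConfig = VesselConfig()
    n_cells: int = 100
    placement: PlacementConfig = PlacementConfig()
    optics: OpticsConfig = OpticsConfig()
    i0: float = 1000.0


class SegmentationConfig(_Strict):
    organoid_channel: str = "DAPI"
    network_channel: str = "CD31"
    cell_channel: str = "tracer"
    organoid_sigma_um: float = 2.0
    network_sigma_um: float = 1.0
    min_object_um3: float = 100.0
    diameter_range_um: list[float] = [6.0, 14.0]
    threshold_rel: float = 0.02


class AnalysisConfig(_Strict):
    bin_width_um: float = 5.0
    prune_length_um: Optional[float] = None
    n_seeded: Optional[int] = None  # for pct_homed; defaults to n_cells simulated


class RunConfig(_Strict):
    """Everything that determines one pipeline run."""

    organoid_id: str = "organoid-0"
    condition: str = "75/25"
    seed: int = 0
    input_stack: Optional[str] = None  # OME-TIFF path; None = simulate
    simulate: SimulateConfig = SimulateConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        data = self.model_dump()
        if str(path).endswith((".yml", ".yaml")):
            Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            Path(path).write_text(json.dumps(data, indent=1))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def simulate_scene(cfg: SimulateConfig, seed: int) -> tuple[TruthBundle, VoxelGrid]:
    """Build a synthetic scene and render it; deterministic per seed."""
    spacing = tuple(cfg.spacing_um)
    organoid = make_organoid_mask(
        ShapeSpec(cfg.shape.kind, tuple(cfg.shape.radii_um)), spacing, tuple(cfg.grid_shape)
    )
    if cfg.vessels.enabled:
        vp = VesselParams(
            n_seeds=cfg.vessels.n_seeds,
            n_branch_events=cfg.vessels.n_branch_events,
            segment_length_um=cfg.vessels.segment_length_um,
            vessel_radius_um=cfg.vessels.vessel_radius_um,
            outer_bias=cfg.vessels.outer_bias,
            min_clearance_um=cfg.vessels.min_clearance_um,
        )
        network, graph = make_vessel_network(organoid, vp, seed=seed)
    else:
        import networkx as nx

        network = BinaryMask(np.zeros_like(organoid.values), spacing)
        graph = nx.Graph()
    law = PlacementLaw(cfg.placement.kind, cfg.placement.scale_um)
    cells = place_cells(
        organoid, network, cfg.n_cells, law, seed=seed + 1,
        min_separation_um=cfg.placement.min_separation_um,
    )
    truth = TruthBundle(organoid, network, graph, cells, law, seed)
    optics = OpticsModel(
        psf_sigma_um=tuple(cfg.optics.psf_sigma_um),
        background_level=cfg.optics.background_level,
        gaussian_noise_sd=cfg.optics.gaussian_noise_sd,
        poisson_scaling=cfg.optics.poisson_scaling,
        bit_depth=cfg.optics.bit_depth,
    )
    grid = render_image(truth, optics, seed=seed + 2, i0=cfg.i0)
    return truth, grid


def run(config: RunConfig, out_dir: str | Path | None = None) -> OrganoidRecord:
    """Execute the configured pipeline and (optionally) write the bundle."""
    stage = "load"
    try:
        if config.input_stack is not None:
            grid = bio.load_stack(config.input_stack)
        else:
            stage = "simulate"
            _, grid = simulate_scene(config.simulate, config.seed)

        seg = config.segmentation
        stage = "segment_organoid"
        organoid = segment_organoid(grid, seg.organoid_channel, seg.organoid_sigma_um)
        stage = "segment_network"
        network = segment_network(
            grid, organoid, seg.network_channel, seg.network_sigma_um,
            min_object_um3=seg.min_object_um3,
        )
        has_network = not network.is_empty()
        if not has_network:
            logger.warning("organoid %s: no network detected", config.organoid_id)

        stage = "network"
        skeleton = skeletonize_mask(network, config.analysis.prune_length_um)
        net = network_metrics(network, skeleton)

        stage = "detect_cells"
        cells = detect_cells(
            grid, organoid, seg.cell_channel,
            diameter_range_um=tuple(seg.diameter_range_um),
            threshold_rel=seg.threshold_rel,
        )

        stage = "distances"
        dist_o = distance_channel(organoid, organoid, "organoid_surface")
        exp_o = expected_distance(dist_o)
        dist_n = exp_n = None
        if has_network:
            cleared = organoid - network  # network-volume-cleared organoid volume
            dist_n = distance_channel(network, cleared, "network_surface")
            exp_n = expected_distance(dist_n, cleared)
        cells = cell_distances(cells, dist_o, dist_n)

        frac_o = fraction_below_expected(cells, exp_o, "d_o_um") if cells else None
        frac_n = (
            fraction_below_expected(cells, exp_n, "d_n_um")
            if cells and exp_n is not None
            else None
        )

        stage = "volume"
        vol = estimate_volume(organoid)

        n_seeded = config.analysis.n_seeded or (
            config.simulate.n_cells if config.input_stack is None else None
        )
        record = OrganoidRecord(
            organoid_id=config.organoid_id,
            condition=config.condition,
            estimated_volume_um3=vol.volume_um3,
            radius_major_um=vol.radius_major_um,
            radius_minor_um=vol.radius_minor_um,
            network=net,
            expected_d_o_um=exp_o,
            expected_d_n_um=exp_n,
            n_cells=len([c for c in cells if not c.excluded]),
            fraction_below_expected_o=frac_o,
            fraction_below_expected_n=frac_n,
            pct_homed=(100.0 * len(cells) / n_seeded) if n_seeded else None,
        )

        if out_dir is not None:
            stage = "write"
            _write_bundle(config, record, cells, organoid, network, Path(out_dir))
        return record
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise


def _write_bundle(config, record, cells, organoid, network, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"# config_hash={config.hash()} seed={config.seed}\n"

    doc = {"config_hash": config.hash(), "seed": config.seed, **record.as_dict()}
    (out_dir / "organoid.json").write_text(json.dumps(doc, indent=1))

    frame = cells_to_frame(cells)
    with open(out_dir / "cells.csv", "w") as fh:
        fh.write(tag)
        frame.to_csv(fh, index=False)

    for which, name in (("d_o_um", "hist_d_o.csv"), ("d_n_um", "hist_d_n.csv")):
        eligible = [c for c in cells if not c.excluded and getattr(c, which) is not None]
        if not eligible:
            continue
        hist = distance_distribution(eligible, which, config.analysis.bin_width_um, "relative")
        with open(out_dir / name, "w") as fh:
            fh.write(tag)
            hist.to_csv(fh, index=False)

    bio.save_mask(organoid, out_dir / "organoid_mask.tif")
    bio.save_mask(network, out_dir / "network_mask.tif")
    config.to_file(out_dir / "config.json")


def run_batch(configs: list[RunConfig]) -> pd.DataFrame:
    """Run several organoids and stack their records into one table."""
    return pd.DataFrame([run(c).as_dict() for c in configs])
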