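"""Reading and writing the pipeline's file formats.

Stacks travel as OME-TIFF (channel names and physical voxel size in the
metadata), masks as single-channel TIFF, tables as CSV and structured results
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .grids import BinaryMask, VoxelGrid

__all__ = [
    "save_stack",
    "load_stack",
    "save_mask",
    "load_mask",
    "save_graph_json",
    "load_graph_json",
]


def save_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a (multi-channel) stack as OME-TIFF with spacing + channel names."""
    dz, dy, dx = grid.spacing_um
    values = grid.values if grid.values.ndim == 4 else grid.values[None]
    names = list(grid.channel_names) or [f"ch{i}" for i in range(values.shape[0])]
    tifffile.imwrite(
        Path(path),
        values.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def load_stack(path: str | Path) -> VoxelGrid:
    """Read an OME-TIFF written by :func:`save_stack`."""
    with tifffile.TiffFile(Path(path)) as tif:
        values = tif.asarray()
        meta = tif.ome_metadata
    spacing, names = _parse_ome(meta, values)
    if values.ndim == 3:
        values = values[None]
    return VoxelGrid(values, spacing, tuple(names))


def _parse_ome(meta: str | None, values: np.ndarray):
    spacing = (1.0, 1.0, 1.0)
    names: list[str] = []
    if meta:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(meta)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None:
            spacing = (
                float(px.get("PhysicalSizeZ", 1.0)),
                float(px.get("PhysicalSizeY", 1.0)),
                float(px.get("PhysicalSizeX", 1.0)),
            )
            names = [
                ch.get("Name") or f"ch{i}"
                for i, ch in enumerate(px.findall("ome:Channel", ns))
            ]
    if not names:
        n = values.shape[0] if values.ndim == 4 else 1
        names = [f"ch{i}" for i in range(n)]
    return spacing, names


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    dz, dy, dx = mask.spacing_um
    tifffile.imwrite(
        Path(path),
        mask.values.astype(np.uint8),
        metadata={"spacing_um": [dz, dy, dx]},
    )


def load_mask(path: str | Path, spacing_um=None) -> BinaryMask:
    with tifffile.TiffFile(Path(path)) as tif:
        values = tif.asarray().astype(bool)
        meta = tif.shaped_metadata
    if spacing_um is None:
        spacing_um = (1.0, 1.0, 1.0)
        if meta and "spacing_um" in meta[0]:
            spacing_um = tuple(meta[0]["spacing_um"])
    return BinaryMask(values, spacing_um)


def save_graph_json(graph: nx.Graph, path: str | Path, **extra) -> None:
    """Vessel/skeleton graph as a JSON node-link document."""
    doc = {
        "nodes": [
            {"id": int(n), **{k: _jsonable(v) for k, v in d.items()}}
            for n, d in graph.nodes(data=True)
        ],
        "edges": [
            {"source": int(u), "target": int(v), **{k: _jsonable(w) for k, w in d.items() if k != "path"}}
            for u, v, d in graph.edges(data=True)
        ],
        **extra,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_graph_json(path: str | Path) -> nx.Graph:
    doc = json.loads(Path(path).read_text())
    g = nx.Graph()
    for n in doc["nodes"]:
        nid = n.pop("id")
        g.add_node(nid, **n)
    for e in doc["edges"]:
        g.add_edge(e.pop("source"), e.pop("target"), **e)
    return g


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    return v
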