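import logging

import networkx as nx
import numpy as np
import pytest

from bmoquant import (
    BinaryMask,
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

# the capsule-tree generator logs dropped branch events; keep test output quiet
logging.getLogger("bmoquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ball_100():
    """Digital ball R=100 µm at 1 µm isotropic spacing, centred on a voxel."""
    return make_organoid_mask(ShapeSpec("ball", (100.0,)), (1.0, 1.0, 1.0), (211, 211, 211))


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free rendered organoid (ball R=70) with network and 40 cells.

    Session-scoped: several segmentation/distance tests share this scene.
    """
    spacing = (1.0, 1.0, 1.0)
    org = make_organoid_mask(ShapeSpec("ball", (70.0,)), spacing, (150, 150, 150))
    net, graph = make_vessel_network(
        org,
        VesselParams(n_seeds=3, n_branch_events=5, segment_length_um=35.0,
                     vessel_radius_um=5.0, min_clearance_um=12.0),
        seed=7,
    )
    cells = place_cells(org, net, 40, PlacementLaw("uniform"), seed=8,
                        min_separation_um=10.0)
    truth = TruthBundle(org, net, graph, cells, PlacementLaw("uniform"), seed=7)
    grid = render_image(truth, OpticsModel.noiseless(), seed=9)
    return truth, grid


@pytest.fixture()
def empty_mask():
    return BinaryMask(np.zeros((20, 20, 20), dtype=bool), (1.0, 1.0, 1.0))


@pytest.fixture()
def no_vessel_graph():
    return nx.Graph()
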