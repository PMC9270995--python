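"""Segmentation and detection: round-trips against synthetic truth."""

import networkx as nx
import numpy as np
import pytest
from scipy.spatial import cKDTree

from bmoquant import (
    BinaryMask,
    NoForegroundError,
    OpticsModel,
    PlacementLaw,
    ShapeSpec,
    TruthBundle,
    VoxelGrid,
    detect_cells,
    make_organoid_mask,
    place_cells,
    render_image,
    segment_network,
    segment_organoid,
)
from bmoquant.synthetic import CellTruth


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    return (a & b).n_voxels / (a | b).n_voxels


class TestSegmentOrganoid:
    def test_round_trip_jaccard(self, small_scene):
        truth, grid = small_scene
        seg = segment_organoid(grid, "DAPI")
        assert jaccard(seg, truth.organoid_mask) >= 0.95

    def test_constant_image_raises(self):
        grid = VoxelGrid(np.full((3, 40, 40, 40), 7.0), (1, 1, 1), ("DAPI", "CD31", "tracer"))
        with pytest.raises(NoForegroundError, match="no organoid"):
            segment_organoid(grid, "DAPI")

    def test_largest_of_two_organoids_kept(self):
        spacing = (1.0, 1.0, 1.0)
        big = make_organoid_mask(
            ShapeSpec("ball", (40.0,), center_um=(60.0, 60.0, 50.0)), spacing, (120, 120, 180)
        )
        small = make_organoid_mask(
            ShapeSpec("ball", (20.0,), center_um=(60.0, 60.0, 140.0)), spacing, (120, 120, 180)
        )
        both = big | small
        empty = BinaryMask(np.zeros_like(both.values), spacing)
        truth = TruthBundle(both, empty, nx.Graph(), [])
        grid = render_image(truth, OpticsModel.noiseless(), seed=0)
        seg = segment_organoid(grid, "DAPI")
        assert jaccard(seg, big) >= 0.95
        assert not (seg.values & small.values).any()

    def test_idempotent_on_rendered_mask(self, small_scene):
        truth, grid = small_scene
        seg1 = segment_organoid(grid, "DAPI")
        empty = BinaryMask(np.zeros_like(seg1.values), seg1.spacing_um)
        re_rendered = render_image(
            TruthBundle(seg1, empty, nx.Graph(), []), OpticsModel.noiseless(), seed=0
        )
        seg2 = segment_organoid(re_rendered, "DAPI")
        # identical up to a one-voxel boundary shell
        from scipy import ndimage as ndi

        disagreement = seg1.values ^ seg2.values
        shell = ndi.binary_dilation(seg1.values) & ~ndi.binary_erosion(seg1.values)
        assert not (disagreement & ~shell).any()

    def test_anisotropic_spacing_volume_agreement(self):
        analytic = 4 / 3 * np.pi * 60**3
        for spacing, shape in (((1.0, 1.0, 1.0), (130, 130, 130)),
                               ((0.5, 0.71, 0.71), (260, 184, 184))):
            org = make_organoid_mask(ShapeSpec("ball", (60.0,)), spacing, shape)
            empty = BinaryMask(np.zeros(shape, bool), spacing)
            grid = render_image(TruthBundle(org, empty, nx.Graph(), []),
                                OpticsModel.noiseless(), seed=0)
            seg = segment_organoid(grid, "DAPI")
            assert seg.volume_um3 == pytest.approx(analytic, rel=0.05)


class TestSegmentNetwork:
    def test_round_trip_jaccard(self, small_scene):
        truth, grid = small_scene
        seg_o = segment_organoid(grid, "DAPI")
        seg_n = segment_network(grid, seg_o, "CD31")
        assert jaccard(seg_n, truth.network_mask) >= 0.9

    def test_blank_channel_gives_empty_mask(self, small_scene):
        truth, grid = small_scene
        blank = VoxelGrid(
            np.stack([grid.channel("DAPI"), np.zeros_like(grid.channel("CD31")),
                      grid.channel("tracer")]),
            grid.spacing_um,
            grid.channel_names,
        )
        seg_o = segment_organoid(blank, "DAPI")
        seg_n = segment_network(blank, seg_o, "CD31")
        assert seg_n.is_empty()

    def test_result_contained_in_organoid(self, small_scene):
        _, grid = small_scene
        seg_o = segment_organoid(grid, "DAPI")
        seg_n = segment_network(grid, seg_o, "CD31")
        assert not (seg_n.values & ~seg_o.values).any()


class TestDetectCells:
    def test_noise_free_round_trip_exact(self, small_scene):
        truth, grid = small_scene
        seg_o = segment_organoid(grid, "DAPI")
        det = detect_cells(grid, seg_o, "tracer")
        assert len(det) == len(truth.cells)
        planted = np.array([c.centroid_um for c in truth.cells])
        found = np.array([c.centroid_um for c in det])
        d, _ = cKDTree(planted).query(found)
        assert d.max() <= np.linalg.norm(truth.spacing_um)  # within one voxel

    def test_blank_channel_gives_no_cells(self, ball_100):
        shape = ball_100.values.shape
        vals = np.zeros((3,) + shape)
        vals[0][ball_100.values] = 100.0
        grid = VoxelGrid(vals, ball_100.spacing_um, ("DAPI", "CD31", "tracer"))
        assert detect_cells(grid, ball_100, "tracer") == []

    def test_sub_resolution_pair_merges_to_one_record(self):
        org = make_organoid_mask(ShapeSpec("ball", (30.0,)), (1, 1, 1), (70, 70, 70))
        empty = BinaryMask(np.zeros_like(org.values), (1, 1, 1))
        cells = [CellTruth((35.0, 35.0, 33.0), 4.0, 0, 0.0, None),
                 CellTruth((35.0, 35.0, 36.0), 4.0, 0, 0.0, None)]
        grid = render_image(TruthBundle(org, empty, nx.Graph(), cells),
                            OpticsModel.noiseless(), seed=0)
        det = detect_cells(grid, org, "tracer", diameter_range_um=(8.0, 14.0))
        assert len(det) == 1

    def test_noisy_recall_and_precision(self):
        # peak SNR 5: planted peak 1000 against Gaussian noise sd 200
        org = make_organoid_mask(ShapeSpec("ball", (70.0,)), (1, 1, 1), (150, 150, 150))
        empty = BinaryMask(np.zeros_like(org.values), (1, 1, 1))
        cells = place_cells(org, None, 50, PlacementLaw("uniform"), seed=1,
                            min_separation_um=10.0)
        optics = OpticsModel(psf_sigma_um=(1.0, 0.5, 0.5), background_level=100.0,
                             gaussian_noise_sd=200.0)
        grid = render_image(TruthBundle(org, empty, nx.Graph(), cells), optics, seed=11)
        det = detect_cells(grid, segment_organoid(grid, "DAPI"), "tracer")
        planted = np.array([c.centroid_um for c in cells])
        found = np.array([c.centroid_um for c in det])
        d, idx = cKDTree(planted).query(found)
        matched = d <= 6.0
        recall = len(set(idx[matched])) / len(planted)
        precision = matched.mean()
        assert recall >= 0.95 and precision >= 0.95
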