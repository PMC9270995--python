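"""Generator contracts: geometry, determinism, placement laws, rendering."""

import networkx as nx
import numpy as np
import pytest

from bmoquant import (
    BinaryMask,
    OpticsModel,
    PlacementLaw,
    PlateLayout,
    ShapeSpec,
    TruthBundle,
    VesselParams,
    make_brightfield_plate,
    make_organoid_mask,
    make_vessel_network,
    place_cells,
    render_image,
)
from bmoquant.synthetic import _paint_capsule


class TestOrganoidMask:
    @pytest.mark.parametrize(
        "spec, analytic",
        [
            (ShapeSpec("ball", (100.0,)), 4 / 3 * np.pi * 100**3),
            (ShapeSpec("ellipsoid", (120.0, 80.0, 80.0)), 4 / 3 * np.pi * 120 * 80**2),
        ],
        ids=["ball", "ellipsoid"],
    )
    def test_voxel_volume_matches_analytic(self, spec, analytic):
        mask = make_organoid_mask(spec, (1.0, 1.0, 1.0), (250, 210, 210))
        assert mask.volume_um3 == pytest.approx(analytic, rel=0.01)

    def test_mask_is_connected_and_hole_free(self):
        from scipy import ndimage as ndi

        mask = make_organoid_mask(ShapeSpec("ball", (30.0,)), (1.0, 1.0, 1.0), (70, 70, 70))
        _, n = ndi.label(mask.values)
        assert n == 1
        assert (ndi.binary_fill_holes(mask.values) == mask.values).all()

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_organoid_mask(ShapeSpec("ball", (0.0,)), (1.0, 1.0, 1.0), (50, 50, 50))

    def test_shape_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            make_organoid_mask(ShapeSpec("ball", (100.0,)), (1.0, 1.0, 1.0), (50, 50, 50))


class TestVesselNetwork:
    def test_single_capsule_volume_matches_analytic(self):
        # capsule radius 5, length 100 at 0.5 µm spacing
        spacing = np.array([0.5, 0.5, 0.5])
        m = np.zeros((40, 40, 240), dtype=bool)
        _paint_capsule(m, np.array([10.0, 10.0, 10.0]), np.array([10.0, 10.0, 110.0]), 5.0, spacing)
        vol = m.sum() * 0.5**3
        analytic = np.pi * 25 * 100 + 4 / 3 * np.pi * 125
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_network_clipped_to_organoid(self, ball_100):
        net, _ = make_vessel_network(ball_100, VesselParams(n_seeds=3, n_branch_events=3), seed=0)
        assert not (net.values & ~ball_100.values).any()

    def test_same_seed_is_bit_identical(self, ball_100):
        params = VesselParams(n_seeds=2, n_branch_events=2)
        net1, g1 = make_vessel_network(ball_100, params, seed=5)
        net2, g2 = make_vessel_network(ball_100, params, seed=5)
        assert (net1.values == net2.values).all()
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_empty_organoid_rejected(self, empty_mask):
        with pytest.raises(ValueError):
            make_vessel_network(empty_mask, VesselParams(), seed=0)


class TestPlaceCells:
    def test_uniform_mean_distance_is_quarter_radius(self, ball_100):
        cells = place_cells(ball_100, None, 2000, PlacementLaw("uniform"), seed=3)
        d_o = np.array([c.d_o_um for c in cells])
        # mean distance from a uniform point in a ball of radius R to its
        # surface is R/4
        assert d_o.mean() == pytest.approx(25.0, abs=1.0)

    def test_zero_cells_gives_empty_list(self, ball_100):
        assert place_cells(ball_100, None, 0, PlacementLaw("uniform"), seed=0) == []

    def test_too_many_cells_rejected(self):
        tiny = make_organoid_mask(ShapeSpec("ball", (4.0,)), (1.0, 1.0, 1.0), (12, 12, 12))
        with pytest.raises(ValueError, match="cannot place"):
            place_cells(tiny, None, 10**6, PlacementLaw("uniform"), seed=0)

    def test_centroids_inside_organoid_and_distances_nonnegative(self, small_scene):
        truth, _ = small_scene
        spacing = np.asarray(truth.spacing_um)
        for c in truth.cells:
            vox = tuple(np.round(np.asarray(c.centroid_um) / spacing).astype(int))
            assert truth.organoid_mask.values[vox]
            assert c.d_o_um >= 0 and c.d_n_um >= 0

    def test_perivascular_mean_matches_weighted_expectation(self, small_scene):
        truth, _ = small_scene
        from bmoquant import distance_channel

        scale = 10.0
        cells = place_cells(
            truth.organoid_mask, truth.network_mask, 800,
            PlacementLaw("perivascular", scale), seed=11,
        )
        sample_mean = np.mean([c.d_n_um for c in cells])
        # exact expectation of the rejection sampler: weighted average of the
        # distance channel with weights exp(-d/scale) over admissible voxels
        admissible = truth.organoid_mask - truth.network_mask
        d = distance_channel(truth.network_mask, admissible).values[admissible.values]
        w = np.exp(-d / scale)
        exact = float((d * w).sum() / w.sum())
        assert sample_mean == pytest.approx(exact, rel=0.10)
        assert sample_mean == pytest.approx(scale, rel=0.35)

    def test_hard_core_separation_respected(self, ball_100):
        cells = place_cells(ball_100, None, 100, PlacementLaw("uniform"), seed=4,
                            min_separation_um=10.0)
        pos = np.array([c.centroid_um for c in cells])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0


class TestRenderImage:
    def _truth(self, cells=(), gens=()):
        org = make_organoid_mask(ShapeSpec("ball", (25.0,)), (1.0, 1.0, 1.0), (60, 60, 60))
        empty = BinaryMask(np.zeros_like(org.values), org.spacing_um)
        from bmoquant.synthetic import CellTruth

        truth_cells = [
            CellTruth(tuple(c), 4.0, int(k), 0.0, None) for c, k in zip(cells, gens)
        ]
        return TruthBundle(org, empty, nx.Graph(), truth_cells)

    def test_noiseless_maxima_at_planted_centroids_with_halving(self):
        truth = self._truth([(30.0, 30.0, 20.0), (30.0, 30.0, 40.0)], [0, 1])
        grid = render_image(truth, OpticsModel.noiseless(), seed=0, i0=1000.0)
        tracer = grid.channel("tracer")
        assert tracer[30, 30, 20] == pytest.approx(1000.0)
        assert tracer[30, 30, 40] == pytest.approx(500.0)  # generation 1 halves
        assert tracer.max() == pytest.approx(1000.0)

    def test_background_only_channel_statistics(self):
        truth = self._truth()
        quiet = OpticsModel(psf_sigma_um=(0, 0, 0), background_level=50.0,
                            gaussian_noise_sd=0.0, poisson_scaling=0.0)
        grid = render_image(truth, quiet, seed=0)
        assert grid.channel("tracer").max() == pytest.approx(50.0)
        noisy = OpticsModel(psf_sigma_um=(0, 0, 0), background_level=50.0,
                            gaussian_noise_sd=5.0, poisson_scaling=0.0)
        grid = render_image(truth, noisy, seed=0)
        frac_above = (grid.channel("tracer") > 50.0 + 3 * 5.0).mean()
        assert frac_above <= 0.005  # Gaussian 3-sigma tail is ~0.13%

    def test_deterministic_per_seed(self):
        truth = self._truth([(30.0, 30.0, 30.0)], [0])
        noisy = OpticsModel(gaussian_noise_sd=5.0, poisson_scaling=0.1)
        a = render_image(truth, noisy, seed=3).values
        b = render_image(truth, noisy, seed=3).values
        assert (a == b).all()


class TestBrightfieldPlate:
    def test_microwell_count_and_truth_areas(self):
        layout = PlateLayout()
        assert layout.n_microwells == 121
        img, truth = make_brightfield_plate(layout, np.full(121, 100.0), seed=0)
        assert len(truth) == 121
        assert truth.area_um2.unique() == pytest.approx([np.pi * 100**2])

    def test_same_seed_identical_image(self):
        layout = PlateLayout()
        radii = np.full(121, 80.0)
        img1, _ = make_brightfield_plate(layout, radii, seed=2)
        img2, _ = make_brightfield_plate(layout, radii, seed=2)
        assert (img1.values == img2.values).all()

    def test_oversize_aggregate_flagged(self):
        layout = PlateLayout()
        radii = np.full(121, 50.0)
        radii[0] = 210.0  # diameter 420 > microwell diameter 400
        _, truth = make_brightfield_plate(layout, radii, seed=0)
        assert bool(truth.loc[0, "oversize"])
        assert not truth.loc[1:, "oversize"].any()
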