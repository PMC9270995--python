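"""Distance channels, the uniform-placement null model and its statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from bmoquant import (
    BinaryMask,
    CellRecord,
    PlacementLaw,
    cell_distances,
    distance_channel,
    distance_distribution,
    expected_distance,
    fraction_below_expected,
    place_cells,
)
from bmoquant.distances import surface_voxels


def _cell(cell_id, d_o=None, d_n=None, excluded=False):
    return CellRecord(cell_id, (0.0, 0.0, 0.0), 1.0, d_o_um=d_o, d_n_um=d_n,
                      excluded=excluded)


class TestDistanceChannel:
    def test_ball_center_value_is_radius(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        assert dg.values[105, 105, 105] == pytest.approx(100.0, abs=1.0)

    def test_outside_domain_is_undefined_not_zero(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        assert np.isnan(dg.values[0, 0, 0])
        assert np.isfinite(dg.values[ball_100.values]).all()

    def test_empty_reference_raises(self, ball_100, empty_mask):
        big_empty = BinaryMask(np.zeros_like(ball_100.values), ball_100.spacing_um)
        with pytest.raises(ValueError, match="no reference surface"):
            distance_channel(big_empty, ball_100)

    def test_matches_brute_force_on_random_masks(self):
        # exhaustive nearest-surface-voxel search as the oracle
        rng = np.random.default_rng(0)
        spacing = (0.5, 0.71, 0.71)
        full = BinaryMask(np.ones((16, 16, 16), bool), spacing)
        for _ in range(25):
            ref = BinaryMask(rng.random((16, 16, 16)) < 0.08, spacing)
            if ref.is_empty():
                continue
            dg = distance_channel(ref, full)
            surf = np.argwhere(surface_voxels(ref)) * np.asarray(spacing)
            pts = np.argwhere(full.values) * np.asarray(spacing)
            brute = cKDTree(surf).query(pts)[0].reshape(16, 16, 16)
            assert np.abs(brute - dg.values).max() <= 0.5 * np.linalg.norm(spacing)


class TestCellDistances:
    def test_point_cell_at_ball_center(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        cell = CellRecord(0, (105.0, 105.0, 105.0), 1.0,
                          voxels=np.array([[105, 105, 105]]))
        (out,) = cell_distances([cell], dg)
        assert out.d_o_um == pytest.approx(100.0, abs=1.0)

    def test_mean_over_constant_shell_is_exact(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        shell = np.argwhere(np.isclose(dg.values, 7.0))
        cell = CellRecord(0, tuple(shell[0].astype(float)), float(len(shell)),
                          voxels=shell)
        (out,) = cell_distances([cell], dg)
        assert out.d_o_um == pytest.approx(7.0)

    def test_cell_outside_domain_flagged_excluded(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        corner = CellRecord(0, (1.0, 1.0, 1.0), 1.0, voxels=np.array([[1, 1, 1]]))
        (out,) = cell_distances([corner], dg)
        assert out.excluded and out.d_o_um is None

    def test_pipeline_distances_track_truth(self, small_scene):
        truth, _ = small_scene
        dg_o = distance_channel(truth.organoid_mask, truth.organoid_mask)
        spacing = np.asarray(truth.spacing_um)
        cells = [
            CellRecord(i, c.centroid_um, 1.0,
                       voxels=np.round(np.asarray(c.centroid_um) / spacing).astype(int)[None])
            for i, c in enumerate(truth.cells)
        ]
        cells = cell_distances(cells, dg_o)
        err = [abs(c.d_o_um - t.d_o_um) for c, t in zip(cells, truth.cells)]
        assert np.mean(err) <= 1.5


class TestExpectedDistance:
    def test_ball_closed_form_quarter_radius(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        assert expected_distance(dg) == pytest.approx(25.0, rel=0.03)

    def test_single_voxel_domain_returns_its_distance(self, ball_100):
        dg = distance_channel(ball_100, ball_100)
        domain = np.zeros_like(ball_100.values)
        domain[105, 105, 105] = True
        got = expected_distance(dg, BinaryMask(domain, ball_100.spacing_um))
        assert got == dg.values[105, 105, 105]

    def test_empty_domain_raises(self, ball_100, empty_mask):
        dg = distance_channel(ball_100, ball_100)
        big_empty = BinaryMask(np.zeros_like(ball_100.values), ball_100.spacing_um)
        with pytest.raises(ValueError, match="empty domain"):
            expected_distance(dg, big_empty)

    def test_adding_vessels_decreases_expected_network_distance(self, small_scene):
        truth, _ = small_scene
        org = truth.organoid_mask
        net = truth.network_mask
        # a nested sub-network: erase some components by keeping a half-space
        partial_vals = net.values.copy()
        partial_vals[:, :, : net.values.shape[2] // 2] = False
        partial = BinaryMask(partial_vals, net.spacing_um)
        assert not partial.is_empty() and partial.n_voxels < net.n_voxels
        e_full = expected_distance(distance_channel(net, org - net), org - net)
        e_part = expected_distance(distance_channel(partial, org - partial), org - partial)
        assert e_full < e_part


class TestFractionBelowExpected:
    def test_uniform_ball_matches_closed_form(self, ball_100):
        # P(D_o < E[D_o]) for uniform placement in a ball is 1-(3/4)^3 = 37/64,
        # not 0.5: the comparison is to the volume mean, not the median
        dg = distance_channel(ball_100, ball_100)
        expected = expected_distance(dg)
        cells = place_cells(ball_100, None, 2000, PlacementLaw("uniform"), seed=5)
        recs = [_cell(i, d_o=c.d_o_um) for i, c in enumerate(cells)]
        frac = fraction_below_expected(recs, expected, "d_o_um")
        assert frac == pytest.approx(37 / 64, abs=0.03)

    def test_all_cells_at_center(self):
        recs = [_cell(i, d_o=100.0) for i in range(5)]
        assert fraction_below_expected(recs, 101.0, "d_o_um") == 1.0

    def test_tie_counts_as_not_below(self):
        recs = [_cell(0, d_o=10.0), _cell(1, d_o=5.0)]
        assert fraction_below_expected(recs, 10.0, "d_o_um") == 0.5

    def test_no_eligible_cells_returns_none(self):
        assert fraction_below_expected([], 10.0, "d_o_um") is None
        assert fraction_below_expected([_cell(0, excluded=True, d_o=1.0)], 10.0, "d_o_um") is None

    def test_depth_biased_placement_shifts_below_uniform(self, small_scene):
        # cells attracted to the core sit farther from the surface than the
        # uniform expectation, so the below-expected fraction drops
        truth, _ = small_scene
        org = truth.organoid_mask
        dg = distance_channel(org, org)
        exp_o = expected_distance(dg)
        uni = place_cells(org, truth.network_mask, 500, PlacementLaw("uniform"), seed=6)
        deep = place_cells(org, truth.network_mask, 500,
                           PlacementLaw("depth_biased", 15.0), seed=6)
        f_uni = np.mean([c.d_o_um < exp_o for c in uni])
        f_deep = np.mean([c.d_o_um < exp_o for c in deep])
        assert f_deep < f_uni - 0.1


class TestDistanceDistribution:
    def test_absolute_counts_in_half_open_bins(self):
        recs = [_cell(i, d_o=d) for i, d in enumerate([2.0, 7.0, 12.0])]
        hist = distance_distribution(recs, "d_o_um", 5.0, "absolute")
        assert hist.value.tolist() == [1.0, 1.0, 1.0]
        assert hist.bin_left_um.tolist() == [0.0, 5.0, 10.0]

    def test_single_cell_single_bin(self):
        hist = distance_distribution([_cell(0, d_o=3.0)], "d_o_um", 5.0, "relative")
        assert len(hist) == 1 and hist.value.iloc[0] == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(
        dists=st.lists(st.floats(0.0, 200.0), min_size=1, max_size=50),
        width=st.floats(0.5, 20.0),
    )
    def test_relative_mode_normalizes(self, dists, width):
        recs = [_cell(i, d_o=d) for i, d in enumerate(dists)]
        hist = distance_distribution(recs, "d_o_um", width, "relative")
        assert hist.value.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_distribution([_cell(0, d_o=1.0)], "d_o_um", 0.0)
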