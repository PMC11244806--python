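"""Morphometry: segmentation fidelity, skeleton graphs, radii, axis profiles."""

import numpy as np
import pytest

from vstain import morphometry as mm
from vstain import phantom as ph


def _straight_tube(shape=(32, 32, 64), radius=3.0, x0=4, x1=59):
    pts = np.array([[shape[0] / 2, shape[1] / 2, x0],
                    [shape[0] / 2, shape[1] / 2, x1]])
    return ph.rasterize_tube(shape, pts, np.array([radius, radius]))


# ------------------------------------------------------------- segmentation
def test_segmentation_recovers_phantom_tubes(small_phantom):
    channel = small_phantom.channels["bc"]
    truth_mask = channel > 0
    mask = mm.segment_network(channel)
    inter = np.logical_and(mask, truth_mask).sum()
    union = np.logical_or(mask, truth_mask).sum()
    assert inter / union >= 0.99


def test_zero_channel_warns_empty_mask():
    with pytest.warns(UserWarning):
        mask = mm.segment_network(np.zeros((8, 8, 8), np.float32))
    assert not mask.any()


def test_segmentation_invariant_under_affine_rescale(small_phantom):
    channel = small_phantom.channels["bc"]
    m1 = mm.segment_network(channel)
    m2 = mm.segment_network(2.5 * channel + 0.3)
    assert np.mean(m1 != m2) < 0.001


# ------------------------------------------------------------- skeletonizing
def test_straight_tube_single_branch_length():
    mask = _straight_tube()
    graph = mm.skeletonize_network(mask)
    graph = mm.prune_spurs(graph, 3.0)
    assert graph.n_branches == 1
    expected = 55.0  # centerline from x=4 to x=59
    assert graph.branches[0].length_um == pytest.approx(expected, rel=0.07)


def test_empty_mask_empty_graph():
    graph = mm.skeletonize_network(np.zeros((8, 8, 8), bool))
    assert graph.n_branches == 0 and len(graph.nodes) == 0


def test_y_junction_three_branches():
    shape = (32, 48, 48)
    center = np.array([16.0, 24.0, 24.0])
    tips = [np.array([16.0, 24.0, 4.0]), np.array([16.0, 4.0, 40.0]),
            np.array([16.0, 44.0, 40.0])]
    mask = np.zeros(shape, bool)
    for tip in tips:
        ph.rasterize_tube(shape, np.vstack([center, tip]), np.array([2.0, 2.0]),
                          out=mask)
    graph = mm.prune_spurs(mm.skeletonize_network(mask), 4.0)
    assert graph.n_branches == 3
    assert graph.n_junctions == 1


def test_skeleton_length_invariant_to_intensity_rescale(small_phantom):
    channel = small_phantom.channels["bc"]
    g1 = mm.skeletonize_network(mm.segment_network(channel))
    g2 = mm.skeletonize_network(mm.segment_network(channel * 7.0))
    total1 = sum(b.length_um for b in g1.branches)
    total2 = sum(b.length_um for b in g2.branches)
    assert total1 == pytest.approx(total2, rel=1e-6)


# ------------------------------------------------------------------- radii
def test_straight_tube_radius_within_10_percent():
    mask = _straight_tube(radius=3.0)
    graph = mm.skeletonize_network(mask)
    stats = mm.radius_stats(mask, graph)
    assert stats["mean_radius_um"] == pytest.approx(3.0, rel=0.10)


def test_two_radii_bimodal_mean():
    shape = (48, 48, 64)
    mask = np.zeros(shape, bool)
    ph.rasterize_tube(shape, np.array([[12, 12, 4], [12, 12, 59]]),
                      np.array([2.0, 2.0]), out=mask)
    ph.rasterize_tube(shape, np.array([[34, 34, 4], [34, 34, 59]]),
                      np.array([4.0, 4.0]), out=mask)
    graph = mm.skeletonize_network(mask)
    stats = mm.radius_stats(mask, graph)
    assert stats["mean_radius_um"] == pytest.approx(3.0, rel=0.15)
    radii = stats["radii_um"]
    assert (radii < 3).sum() > 10 and (radii > 3).sum() > 10


def test_dilation_grows_mean_radius_by_about_one_voxel():
    from scipy import ndimage
    mask = _straight_tube(radius=3.0)
    graph = mm.skeletonize_network(mask)
    base = mm.radius_stats(mask, graph)["mean_radius_um"]
    ball = ndimage.generate_binary_structure(3, 3)
    dilated = ndimage.binary_dilation(mask, ball)
    grown = mm.radius_stats(dilated, mm.skeletonize_network(dilated))["mean_radius_um"]
    assert grown - base == pytest.approx(1.0, abs=0.5)


def test_lengths_scale_linearly_with_voxel_size():
    mask = _straight_tube()
    g1 = mm.skeletonize_network(mask, voxel_size=(1, 1, 1))
    g2 = mm.skeletonize_network(mask, voxel_size=(0.3, 0.3, 0.3))
    l1 = sum(b.length_um for b in g1.branches)
    l2 = sum(b.length_um for b in g2.branches)
    assert l2 == pytest.approx(0.3 * l1, rel=1e-6)


# ---------------------------------------------------------- branch statistics
def _graph_with_lengths(lengths):
    branches = [mm.Branch(np.array([[0, 0, 0], [0, 0, 1]]), l,
                          ((0, 0, 0), (0, 0, 1))) for l in lengths]
    return mm.NetworkGraph([], branches, np.zeros((1, 3), int), np.ones(1))


def test_mean_branch_length_arithmetic():
    assert mm.branch_length_stats(_graph_with_lengths([10.0]))[
        "mean_branch_length_um"] == 10.0
    assert mm.branch_length_stats(_graph_with_lengths([10.0, 20.0]))[
        "mean_branch_length_um"] == 15.0


def test_spur_pruning_removes_short_terminal_branch():
    shape = (24, 48, 48)
    mask = np.zeros(shape, bool)
    ph.rasterize_tube(shape, np.array([[12, 24, 4], [12, 24, 43]]),
                      np.array([2.0, 2.0]), out=mask)
    ph.rasterize_tube(shape, np.array([[12, 24, 24], [12, 29, 24]]),
                      np.array([1.5, 1.5]), out=mask)  # 5-voxel spur
    graph = mm.skeletonize_network(mask)
    pruned = mm.prune_spurs(graph, min_length_um=8.0)
    assert pruned.n_branches < graph.n_branches


def test_empty_graph_errors():
    empty = mm.NetworkGraph([], [], np.empty((0, 3), int), np.empty(0))
    with pytest.raises(ValueError):
        mm.branch_length_stats(empty)
    with pytest.raises(ValueError):
        mm.radius_stats(np.zeros((4, 4, 4), bool), empty)


# -------------------------------------------------------------- axis profile
def test_uniform_quantity_gives_flat_profile(rng):
    pos = rng.uniform(0, 100, (200, 3))
    q = np.full(200, 2.5)
    prof = mm.profile_along_axis(q, pos, (0, 0, 0), (0, 0, 1), 100.0, n_bins=5)
    occupied = prof.counts > 1
    np.testing.assert_allclose(prof.mean[occupied], 2.5)
    np.testing.assert_allclose(prof.sd[occupied], 0.0, atol=1e-12)


def test_single_sample_one_bin_no_sd():
    prof = mm.profile_along_axis([1.0], [(0.0, 0.0, 50.0)], (0, 0, 0), (0, 0, 1),
                                 100.0, n_bins=10)
    assert prof.counts.sum() == 1
    assert np.isnan(prof.sd[prof.counts == 1]).all()


def test_linear_gradient_profile_recovers_endpoints():
    """A tube whose radius grows linearly 2 -> 4 µm along x."""
    shape = (24, 24, 96)
    xs = np.linspace(4, 91, 30)
    pts = np.stack([np.full(30, 12.0), np.full(30, 12.0), xs], axis=1)
    radii = 2.0 + (xs - 4) / (91 - 4) * 2.0
    mask = ph.rasterize_tube(shape, pts, radii)
    graph = mm.skeletonize_network(mask)
    coords = graph.skeleton_coords.astype(float)
    prof = mm.profile_along_axis(graph.radii_um, coords, (12, 12, 0), (0, 0, 1),
                                 96.0, n_bins=8)
    occ = np.where(prof.counts >= 3)[0]
    means = prof.mean[occ]
    assert means[0] == pytest.approx(2.0, rel=0.15)
    assert means[-1] == pytest.approx(4.0, rel=0.15)
    assert np.corrcoef(occ, means)[0, 1] > 0.9  # monotone trend


def test_profile_validates_inputs():
    with pytest.raises(ValueError):
        mm.profile_along_axis([1.0], [(0, 0, 0)], (0, 0, 0), (0, 0, 1), 10.0, n_bins=0)
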