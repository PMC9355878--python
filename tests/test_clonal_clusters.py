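"""Unit and oracle tests for registration, color classing and clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lnmech import clonal_clusters as cc
from lnmech import synthetic_data as sd


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0.0],
                     [np.sin(a), np.cos(a), 0.0],
                     [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# ICP registration
# ---------------------------------------------------------------------------

def test_icp_recovers_translation():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-100, 100, (60, 3))
    moved = pts + np.array([3.0, -2.0, 1.0])
    tf = cc.icp_register(cc.SpotSet("red", pts), cc.SpotSet("green", moved))
    assert np.allclose(tf.translation, [3.0, -2.0, 1.0], atol=1e-6)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-8)


def test_icp_recovers_rotation_and_translation():
    rng = np.random.default_rng(1)
    pts = rng.uniform(-100, 100, (80, 3))
    R = _rot_z(5.0)
    moved = pts @ R.T + np.array([3.0, -2.0, 1.0])
    tf = cc.icp_register(cc.SpotSet("red", pts), cc.SpotSet("green", moved))
    assert np.allclose(tf.apply(pts), moved, atol=1e-5)
    assert tf.rms_residual < 1e-6


def test_icp_collinear_cloud_raises():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(cc.RankDeficiencyError):
        cc.icp_register(cc.SpotSet("red", line),
                        cc.SpotSet("green", line + [1.0, 0.0, 0.0]))


def test_icp_needs_enough_points():
    p = np.zeros((3, 3)) + np.arange(3)[:, None]
    with pytest.raises(ValueError):
        cc.icp_register(cc.SpotSet("red", p), cc.SpotSet("green", p))


def test_rigid_transform_identity():
    p = np.array([[1.0, 2.0, 3.0]])
    assert np.allclose(cc.RigidTransform.identity().apply(p), p)


# ---------------------------------------------------------------------------
# Color classification
# ---------------------------------------------------------------------------

def test_classify_mutual_pair_becomes_yellow_midpoint():
    g = cc.SpotSet("green", [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    r = cc.SpotSet("red", [[4.0, 0.0, 0.0], [200.0, 0.0, 0.0]])
    cells = cc.classify_colors(g, r)
    assert sorted(cells.color_class) == ["green", "red", "yellow"]
    y = cells.positions[cells.color_class == "yellow"][0]
    assert np.allclose(y, [2.0, 0.0, 0.0])


def test_classify_distance_threshold():
    g = cc.SpotSet("green", [[0.0, 0.0, 0.0]])
    r = cc.SpotSet("red", [[6.5, 0.0, 0.0]])
    cells = cc.classify_colors(g, r, cell_radius=6.0)
    assert sorted(cells.color_class) == ["green", "red"]


def test_classify_each_spot_contributes_once():
    rng = np.random.default_rng(2)
    g = cc.SpotSet("green", rng.uniform(0, 500, (40, 3)))
    r = cc.SpotSet("red", rng.uniform(0, 500, (30, 3)))
    cells = cc.classify_colors(g, r)
    n_yellow = int(np.sum(cells.color_class == "yellow"))
    assert len(cells) == 70 - n_yellow


# ---------------------------------------------------------------------------
# Region masks and exclusions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_masks():
    return cc.RegionMasks.from_ellipsoid((300.0, 250.0, 250.0),
                                         voxel_size=10.0, edge_margin=100.0)


def test_exclusions_keep_center_drop_edge_and_outside(small_masks):
    cells = cc.CellSet(
        [[0.0, 0.0, 0.0],        # center: kept
         [280.0, 0.0, 0.0],      # inside but within the 100 um margin: dropped
         [500.0, 0.0, 0.0]],     # outside the node: dropped
        ["green", "green", "red"])
    kept = cc.apply_exclusions(cells, small_masks)
    assert len(kept) == 1
    assert np.allclose(kept.positions[0], [0.0, 0.0, 0.0])


def test_placement_region_respects_margin_and_vessels():
    masks = cc.RegionMasks.from_ellipsoid(
        (300.0, 250.0, 250.0),
        hev_cylinders=[((-200.0, 0.0, 0.0), (200.0, 0.0, 0.0), 20.0)],
        voxel_size=10.0, edge_margin=100.0)
    region = masks.placement_region()
    interior = masks.interior_distance() >= masks.edge_margin
    assert not (region & masks.hev_mask).any()
    assert (region <= interior).all()


def test_sample_uniform_stays_in_region(small_masks):
    rng = np.random.default_rng(3)
    pts = small_masks.sample_uniform(200, rng, small_masks.placement_region())
    d = small_masks.lookup(small_masks.interior_distance(), pts, outside=0.0)
    # jittered within voxels of the eroded interior: allow one voxel of slack
    assert (d >= small_masks.edge_margin - small_masks.voxel_size).all()


# ---------------------------------------------------------------------------
# Clustering vs a brute-force density-reachability oracle
# ---------------------------------------------------------------------------

def _oracle_clusters(points, eps, min_samples):
    """Textbook DBSCAN via BFS over the eps-neighborhood graph."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    label = np.full(n, -1)
    cur = 0
    for i in range(n):
        if label[i] != -1 or not core[i]:
            continue
        queue = [i]
        label[i] = cur
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if label[k] == -1:
                    label[k] = cur
                    queue.append(k)
        cur += 1
    return label


@given(seed=st.integers(0, 500))
def test_find_clusters_matches_dbscan_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 150, (40, 3))
    cells = cc.CellSet(pts, np.array(["green"] * 40))
    stats = cc.find_clusters(cells)
    labels = _oracle_clusters(pts, eps=32.0, min_samples=3)
    ours = {frozenset(map(int, m)) for _, m in stats.clusters}
    ref = {frozenset(np.flatnonzero(labels == c)) for c in range(labels.max() + 1)}
    assert ours == ref


def test_neighbor_mode_eps():
    # surface-surface: 20 + 12 = 32 um center distance; surface-center: 26
    pts = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0], [60.0, 0.0, 0.0]])
    cells = cc.CellSet(pts, np.array(["green"] * 3))
    assert cc.find_clusters(cells, neighbor_mode="surface-surface").n_clusters == 1
    assert cc.find_clusters(cells, neighbor_mode="surface-center").n_clusters == 0


def test_lineages_cluster_separately():
    # 3 green + 3 red at the same location form two clusters, never one
    pts = np.tile(np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
                  (2, 1))
    colors = np.array(["green"] * 3 + ["red"] * 3)
    stats = cc.find_clusters(cc.CellSet(pts, colors))
    assert stats.n_clusters == 2
    assert stats.clustered_fraction == 1.0


def test_yellow_excluded_from_clusters_but_counted():
    pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                    [15.0, 0.0, 0.0]])
    colors = np.array(["green", "green", "green", "yellow"])
    stats = cc.find_clusters(cc.CellSet(pts, colors))
    assert stats.n_clusters == 1
    assert stats.sizes.tolist() == [3]
    assert stats.n_cells == 4
    assert stats.clustered_fraction == pytest.approx(0.75)


def test_min_cells_threshold():
    pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    stats = cc.find_clusters(cc.CellSet(pts, np.array(["green"] * 2)))
    assert stats.n_clusters == 0 and stats.clustered_fraction == 0.0


# ---------------------------------------------------------------------------
# Cluster Factor and derived summaries
# ---------------------------------------------------------------------------

def test_cluster_factor_definitional_example():
    assert cc.cluster_factor(1.0, 0.01) == 100.0


def test_cluster_factor_chance_level():
    assert cc.cluster_factor(0.1, 0.1) == 1.0


def test_cluster_factor_degenerate_nulls():
    with pytest.warns(UserWarning, match="inf"):
        assert cc.cluster_factor(0.5, 0.0) == float("inf")
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(cc.cluster_factor(0.0, 0.0))


def test_cluster_size_distribution_sums_to_100():
    pts = np.vstack([np.arange(3)[:, None] * [5.0, 0.0, 0.0],
                     np.arange(4)[:, None] * [5.0, 0.0, 0.0] + 500.0])
    stats = cc.find_clusters(cc.CellSet(pts, np.array(["green"] * 7)))
    dist = cc.cluster_size_distribution(stats)
    assert sum(dist.values()) == pytest.approx(100.0)
    assert dist == {3: 50.0, 4: 50.0}


def test_simulate_random_deterministic(small_masks):
    f1 = cc.simulate_random({"green": 30, "red": 30}, small_masks, seed=7)
    f2 = cc.simulate_random({"green": 30, "red": 30}, small_masks, seed=7)
    assert f1 == f2


def test_simulate_random_empty_region_raises():
    tiny = cc.RegionMasks.from_ellipsoid((120.0, 120.0, 120.0),
                                         voxel_size=10.0, edge_margin=150.0)
    with pytest.raises(cc.PlacementError):
        cc.simulate_random({"green": 5}, tiny, seed=0)


def test_cf_by_hev_distance_profile():
    green, red, masks, _ = sd.gen_madm_cells(seed=3)
    cells = cc.classify_colors(green, red)
    cells = cc.apply_exclusions(cells, masks)
    stats = cc.find_clusters(cells)
    counts = {lin: int(np.sum(cells.color_class == lin))
              for lin in ("green", "red")}
    _, reps = cc.simulate_random(counts, masks, seed=4, return_cells=True)
    prof = cc.cf_by_hev_distance(cells, stats, reps, masks)
    assert prof.bin_width == 50.0
    assert len(prof.distance_bins) == len(prof.cf_per_bin)
    assert np.all(np.diff(prof.distance_bins) == 50.0)
    finite = prof.cf_per_bin[np.isfinite(prof.cf_per_bin)]
    assert (finite >= 0).all()


def test_with_cf_fills_factor():
    pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
    stats = cc.find_clusters(cc.CellSet(pts, np.array(["green"] * 3)))
    assert cc.with_cf(stats, 0.01).cf == pytest.approx(100.0)
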