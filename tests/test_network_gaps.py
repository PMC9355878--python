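"""Unit and oracle tests for the maximal-ball packing and pore statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from lnmech import network_gaps as ng
from lnmech import synthetic_data as sd


# ---------------------------------------------------------------------------
# Reference (brute-force) packer: recompute the full distance transform after
# every single placement.  Definitionally simple, shared only scipy with the
# implementation under test.
# ---------------------------------------------------------------------------

def _edt_blocked_outside(free):
    padded = np.pad(free, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    return d[tuple(slice(1, -1) for _ in free.shape)]


def _ball(idx, d, shape, strict):
    """Coordinates within (strictly within) d/2 of idx, integer arithmetic."""
    r = d // 2
    pts = []
    for off in itertools.product(range(-r, r + 1), repeat=len(shape)):
        n4 = 4 * sum(c * c for c in off)
        if (n4 < d * d) if strict else (n4 <= d * d):
            p = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= c < s for c, s in zip(p, shape)):
                pts.append(p)
    return tuple(np.array(pts).T)


def oracle_pack(voxels):
    """Place the largest ball admitted by the current distance transform at
    the first raster-order pixel, claim its gap pixels, repeat."""
    free = ~voxels
    claimed = np.zeros_like(free)
    elements = []
    counts = []
    if not free.any():
        return elements, counts
    d = int(np.floor(2.0 * _edt_blocked_outside(free).max()))
    while d > 1:
        while True:
            edt = _edt_blocked_outside(~(voxels | claimed))
            cand = np.argwhere(edt >= d / 2.0)
            if not len(cand):
                break
            idx = tuple(cand[0])
            win = _ball(idx, d, free.shape, strict=False)
            sel = free[win] & ~claimed[win]
            counts.append(int(np.count_nonzero(sel)))
            claimed[tuple(c[sel] for c in win)] = True
            elements.append((idx, d))
        d -= 1
    for idx in np.argwhere(free & ~claimed):
        elements.append((tuple(idx), 1))
        counts.append(1)
    return elements, counts


@pytest.mark.parametrize("seed", range(6))
def test_packer_matches_oracle_2d(seed):
    rng = np.random.default_rng(seed)
    mask = ng.NetworkMask(rng.random((16, 16)) < 0.35, 1.0)
    fill = ng.fill_gaps_2d(mask)
    elements, counts = oracle_pack(mask.voxels)
    assert fill.elements == elements
    assert fill.claimed_px == counts


@pytest.mark.parametrize("seed", range(3))
def test_packer_matches_oracle_3d(seed):
    rng = np.random.default_rng(100 + seed)
    mask = ng.NetworkMask(rng.random((9, 9, 9)) < 0.25, 1.0)
    fill = ng.fill_gaps_3d(mask)
    elements, counts = oracle_pack(mask.voxels)
    assert fill.elements == elements
    assert fill.claimed_px == counts


# ---------------------------------------------------------------------------
# Packing invariants
# ---------------------------------------------------------------------------

def test_square_gap_max_diameter():
    # a 6x6 open square bounded by network admits a diameter-6 circle
    m = np.ones((10, 10), bool)
    m[2:8, 2:8] = False
    fill = ng.fill_gaps_2d(ng.NetworkMask(m, 1.0))
    assert fill.elements[0][1] == 6


def test_full_network_has_empty_fill():
    fill = ng.fill_gaps_2d(ng.NetworkMask(np.ones((8, 8), bool), 1.0))
    assert fill.elements == [] and fill.total_gap_px == 0


def test_all_gap_pixels_claimed_once():
    rng = np.random.default_rng(7)
    m = ng.NetworkMask(rng.random((24, 24)) < 0.3, 1.0)
    fill = ng.fill_gaps_2d(m)
    assert sum(fill.claimed_px) == fill.total_gap_px == int((~m.voxels).sum())


def test_diameters_non_increasing():
    rng = np.random.default_rng(8)
    m = ng.NetworkMask(rng.random((24, 24)) < 0.3, 1.0)
    ds = [d for _, d in ng.fill_gaps_2d(m).elements]
    assert all(a >= b for a, b in zip(ds, ds[1:]))


def test_centers_lie_in_gaps():
    rng = np.random.default_rng(9)
    m = ng.NetworkMask(rng.random((20, 20)) < 0.3, 1.0)
    for idx, _ in ng.fill_gaps_2d(m).elements:
        assert not m.voxels[idx]


@given(seed=st.integers(0, 1000))
def test_packing_partitions_gap_space(seed):
    rng = np.random.default_rng(seed)
    m = ng.NetworkMask(rng.random((12, 12)) < 0.4, 1.0)
    fill = ng.fill_gaps_2d(m)
    assert sum(fill.claimed_px) == fill.total_gap_px


def test_3d_anisotropic_resampling():
    # a volume with 2x coarser z sampling packs like its isotropic resampling
    rng = np.random.default_rng(10)
    v = rng.random((6, 12, 12)) < 0.25
    fill = ng.fill_gaps_3d(ng.NetworkMask(v, 1.0, z_spacing=2.0))
    iso = ndimage.zoom(v, (2.0, 1.0, 1.0), order=0)
    ref = ng.fill_gaps_3d(ng.NetworkMask(iso, 1.0))
    assert fill.elements == ref.elements


# ---------------------------------------------------------------------------
# Mask cleaning
# ---------------------------------------------------------------------------

def test_clean_mask_threshold_inclusive():
    m = np.zeros((10, 10), bool)
    m[2, 2:7] = True  # 5-pixel component
    kept = ng.clean_mask(ng.NetworkMask(m, 1.0), min_object_px=5)
    assert kept.voxels.sum() == 5
    removed = ng.clean_mask(ng.NetworkMask(m, 1.0), min_object_px=6)
    assert not removed.voxels.any()


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

def test_distribution_area_fractions_sum_to_one():
    net, _ = sd.gen_network_mask(seed=0)
    dist = ng.pore_size_distribution(ng.fill_gaps_2d(net), net)
    assert np.sum(dist.area_fraction) == pytest.approx(1.0)
    assert np.allclose(dist.weighted_fraction,
                       dist.area_fraction * dist.diameters)


def test_distribution_weighting_shifts_mean_up():
    # diameter weighting emphasizes large pores
    net, _ = sd.gen_network_mask(seed=1, jitter_px=2)
    dist = ng.pore_size_distribution(ng.fill_gaps_2d(net), net)
    assert dist.mean_fitted_diameter > dist.mean_diameter_plain


def test_distribution_lattice_mean_near_gap_size():
    # a clean lattice with 16 px gaps at 0.5 um/px has 8 um pores
    net, truth = sd.gen_network_mask(seed=2)
    dist = ng.pore_size_distribution(ng.fill_gaps_2d(net), net)
    expected = truth.gap_side_px * net.pixel_size
    assert dist.mean_fitted_diameter == pytest.approx(expected, rel=0.15)


def test_distribution_empty_fill_warns():
    m = ng.NetworkMask(np.ones((6, 6), bool), 1.0)
    fill = ng.fill_gaps_2d(m)
    with pytest.warns(UserWarning, match="empty"):
        dist = ng.pore_size_distribution(fill, m)
    assert np.isnan(dist.mean_fitted_diameter)


def test_average_over_stack_identity_and_mean():
    net, _ = sd.gen_network_mask(seed=3)
    d1 = ng.pore_size_distribution(ng.fill_gaps_2d(net), net)
    same = ng.average_over_stack([d1, d1])
    assert np.allclose(same.area_fraction[: len(d1.area_fraction)],
                       d1.area_fraction)
    assert same.mean_fitted_diameter == pytest.approx(d1.mean_fitted_diameter)
    net2, _ = sd.gen_network_mask(seed=4, jitter_px=3)
    d2 = ng.pore_size_distribution(ng.fill_gaps_2d(net2), net2)
    avg = ng.average_over_stack([d1, d2])
    assert np.sum(avg.area_fraction) == pytest.approx(1.0)


def test_average_over_stack_rejects_mixed_pixel_size():
    net, _ = sd.gen_network_mask(seed=5)
    d1 = ng.pore_size_distribution(ng.fill_gaps_2d(net), net)
    net2 = ng.NetworkMask(net.voxels, pixel_size=1.0)
    d2 = ng.pore_size_distribution(ng.fill_gaps_2d(net2), net2)
    with pytest.raises(ValueError):
        ng.average_over_stack([d1, d2])
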