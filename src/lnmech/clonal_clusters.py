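"""Clonal cluster statistics for sparse-labeled stromal cells.

Mosaic two-color lineage labeling marks T-zone reticular cells green or red
heritably, so daughters that stay near their precursor form same-color
clusters.  The pipeline implemented here mirrors the analysis chain from
detected spot coordinates to the Cluster Factor:

1. rigid registration of the two spectral channels (iterative closest point),
2. color classification: mutual-nearest spot pairs closer than a cell radius
   merge into yellow (double-labeled) cells, the rest stay green/red,
3. exclusion of cells outside the node or within an edge margin (default
   100 um) of its surface,
4. per-lineage DBSCAN where cells are 12-um spheres and two cells are
   neighbors when their surface-to-surface gap is at most the search radius
   (default 20 um, i.e. center distance <= 32 um); a cluster needs at least
   3 same-lineage cells,
5. a random-placement null: the same cell counts placed uniformly in the
   same region (node interior eroded by the margin, minus high endothelial
   venule volumes), re-clustered identically, averaged over replicates
   (default 10),
6. the Cluster Factor CF = (observed clustered fraction) / (mean simulated
   clustered fraction); CF = 1 means chance-level clustering.

Region geometry is handled on voxel grids: analytic phantoms (ellipsoid node,
cylindrical vessels) are voxelized once and all interior/surface distances
come from Euclidean distance transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

__all__ = [
    "SpotSet",
    "RigidTransform",
    "CellSet",
    "RegionMasks",
    "ClusterStats",
    "CFProfile",
    "RankDeficiencyError",
    "PlacementError",
    "icp_register",
    "classify_colors",
    "apply_exclusions",
    "find_clusters",
    "simulate_random",
    "cluster_factor",
    "cf_by_hev_distance",
    "cluster_size_distribution",
]


class RankDeficiencyError(ValueError):
    """Raised when a point cloud is too degenerate (collinear) for a unique
    rigid registration."""


class PlacementError(RuntimeError):
    """Raised when the null placement region is empty."""


@dataclass(frozen=True)
class SpotSet:
    """Detected-spot coordinates (um) of one spectral channel."""

    channel: str  # "green" | "red"
    coords: np.ndarray  # (n, 3)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if c.size == 0:
            c = c.reshape(0, 3)
        if c.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map p -> R p + t (um) with the registration RMS residual."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rms_residual: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), 0.0)


@dataclass(frozen=True)
class CellSet:
    """Color-classed cells: positions (um) and per-cell lineage label."""

    positions: np.ndarray  # (n, 3)
    color_class: np.ndarray  # (n,) of {"green", "red", "yellow"}
    sphere_diameter: float = 12.0

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if p.size == 0:
            p = p.reshape(0, 3)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "color_class", np.asarray(self.color_class))
        if len(self.color_class) != len(p):
            raise ValueError("one color class per position required")
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")

    def __len__(self):
        return len(self.positions)


@dataclass(frozen=True)
class RegionMasks:
    """Voxelized node interior and vessel volumes in a common frame.

    ``origin`` is the world position (um) of the corner of voxel (0,0,0);
    world point p maps to voxel floor((p - origin)/voxel_size).
    """

    ln_mask: np.ndarray  # 3D bool, True = inside node
    hev_mask: np.ndarray  # 3D bool, True = vessel
    voxel_size: float
    origin: np.ndarray = field(default=None)
    edge_margin: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "ln_mask", np.asarray(self.ln_mask, dtype=bool))
        object.__setattr__(self, "hev_mask", np.asarray(self.hev_mask, dtype=bool))
        if self.ln_mask.shape != self.hev_mask.shape:
            raise ValueError("ln_mask and hev_mask must share a shape")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.edge_margin < 0:
            raise ValueError("edge_margin must be >= 0")
        origin = self.origin
        if origin is None:
            origin = np.zeros(3)
        object.__setattr__(self, "origin", np.asarray(origin, dtype=float))
        if not self.ln_mask.any():
            raise ValueError("ln_mask is empty")

    @classmethod
    def from_ellipsoid(
        cls,
        semi_axes: tuple[float, float, float],
        hev_cylinders: list[tuple] = (),
        voxel_size: float = 10.0,
        edge_margin: float = 100.0,
    ) -> "RegionMasks":
        """Analytic phantom: axis-aligned ellipsoid centred at the origin with
        cylindrical vessels given as (endpoint0, endpoint1, radius) in um."""
        a = np.asarray(semi_axes, dtype=float)
        origin = -(a + voxel_size)
        shape = np.ceil(2 * (a + voxel_size) / voxel_size).astype(int)
        idx = np.indices(shape, dtype=float)
        centers = (idx + 0.5) * voxel_size  # relative to origin
        world = centers + origin[:, None, None, None]
        ln = ((world[0] / a[0]) ** 2 + (world[1] / a[1]) ** 2
              + (world[2] / a[2]) ** 2) <= 1.0
        hev = np.zeros(tuple(shape), dtype=bool)
        pts = np.stack([w.ravel() for w in world], axis=1)
        for p0, p1, radius in hev_cylinders:
            p0 = np.asarray(p0, dtype=float)
            p1 = np.asarray(p1, dtype=float)
            axis = p1 - p0
            L2 = float(axis @ axis)
            u = np.clip((pts - p0) @ axis / L2, 0.0, 1.0)
            closest = p0 + u[:, None] * axis
            dist = np.linalg.norm(pts - closest, axis=1)
            hev |= (dist <= radius).reshape(tuple(shape))
        hev &= ln
        return cls(ln, hev, voxel_size, origin=origin, edge_margin=edge_margin)

    # -- distances (um) on the voxel grid --------------------------------
    def interior_distance(self) -> np.ndarray:
        """Distance from each inside voxel to the node surface (0 outside)."""
        return ndimage.distance_transform_edt(self.ln_mask) * self.voxel_size

    def hev_distance(self) -> np.ndarray:
        """Distance from each voxel to the nearest vessel voxel."""
        if not self.hev_mask.any():
            raise ValueError("hev_mask is empty")
        return ndimage.distance_transform_edt(~self.hev_mask) * self.voxel_size

    def placement_region(self) -> np.ndarray:
        """Voxels eligible for cells: inside, >= edge_margin from the
        surface and outside vessel volumes."""
        return (self.interior_distance() >= self.edge_margin) & ~self.hev_mask

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        idx = np.floor((np.atleast_2d(points) - self.origin) / self.voxel_size)
        return idx.astype(int)

    def lookup(self, volume: np.ndarray, points: np.ndarray, outside=0.0) -> np.ndarray:
        """Sample a voxel volume at world points; out-of-grid points get
        ``outside``."""
        idx = self.voxel_of(points)
        ok = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
        out = np.full(len(idx), outside, dtype=float)
        if ok.any():
            sel = idx[ok]
            out[ok] = volume[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def sample_uniform(self, n: int, rng: np.random.Generator,
                       region: np.ndarray | None = None) -> np.ndarray:
        """Uniform random points (um) over the placement region."""
        if region is None:
            region = self.placement_region()
        voxels = np.argwhere(region)
        if len(voxels) == 0:
            raise PlacementError("placement region is empty")
        pick = rng.integers(0, len(voxels), size=n)
        jitter = rng.uniform(0.0, 1.0, size=(n, 3))
        return (voxels[pick] + jitter) * self.voxel_size + self.origin


@dataclass(frozen=True)
class ClusterStats:
    """Per-lineage cluster assignment and summary statistics."""

    clusters: list  # of (lineage, np.ndarray of member indices into the CellSet)
    n_clusters: int
    sizes: np.ndarray
    clustered_fraction: float
    n_cells: int
    cf: float | None = None


@dataclass(frozen=True)
class CFProfile:
    """Cluster Factor as a function of distance from the nearest vessel."""

    distance_bins: np.ndarray  # bin left edges, um
    cf_per_bin: np.ndarray  # NaN where undefined
    bin_width: float


# ---------------------------------------------------------------------------
# Registration and color classification
# ---------------------------------------------------------------------------

def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping moving onto fixed (paired)."""
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    if S[0] > 0 and S[1] / S[0] < 1e-9:
        raise RankDeficiencyError(
            "point clouds are (nearly) collinear: rotation is not identifiable")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return R, t


def icp_register(moving: SpotSet, fixed: SpotSet, max_iter: int = 100,
                 tol: float = 1e-6) -> RigidTransform:
    """Iterative-closest-point rigid registration of one channel onto another.

    Alternates nearest-neighbor correspondence with a Kabsch rigid fit until
    the RMS nearest-neighbor distance improves by less than ``tol`` (um) or
    ``max_iter`` is reached.
    """
    mv = moving.coords
    fx = fixed.coords
    if len(mv) < 4 or len(fx) < 4:
        raise ValueError("each cloud needs at least 4 points")
    tree = cKDTree(fx)
    R = np.eye(3)
    t = np.zeros(3)
    prev_rms = np.inf
    rms = np.inf
    for _ in range(max_iter):
        cur = mv @ R.T + t
        dist, nn = tree.query(cur)
        rms = float(np.sqrt(np.mean(dist**2)))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        R, t = _kabsch(mv, fx[nn])
    return RigidTransform(rotation=R, translation=t, rms_residual=rms)


def classify_colors(green: SpotSet, red: SpotSet, cell_radius: float = 6.0,
                    sphere_diameter: float = 12.0) -> CellSet:
    """Merge registered channels into green/red/yellow cells.

    Mutual-nearest spot pairs separated by less than ``cell_radius`` become a
    single yellow cell at the pair midpoint; every other spot becomes a green
    or red cell.  Each spot contributes to exactly one cell.
    """
    g = green.coords
    r = red.coords
    positions = []
    colors = []
    paired_g: set = set()
    paired_r: set = set()
    if len(g) and len(r):
        tg = cKDTree(g)
        tr = cKDTree(r)
        d_gr, nn_gr = tr.query(g)  # for each green: nearest red
        _, nn_rg = tg.query(r)  # for each red: nearest green
        for i in range(len(g)):
            j = int(nn_gr[i])
            if d_gr[i] < cell_radius and int(nn_rg[j]) == i:
                paired_g.add(i)
                paired_r.add(j)
                positions.append((g[i] + r[j]) / 2.0)
                colors.append("yellow")
    for i in range(len(g)):
        if i not in paired_g:
            positions.append(g[i])
            colors.append("green")
    for j in range(len(r)):
        if j not in paired_r:
            positions.append(r[j])
            colors.append("red")
    pos = np.array(positions).reshape(-1, 3)
    return CellSet(pos, np.array(colors), sphere_diameter=sphere_diameter)


def apply_exclusions(cells: CellSet, masks: RegionMasks) -> CellSet:
    """Drop cells outside the node or closer than ``edge_margin`` to its
    surface (edge-effect control); vessel interiors are not excluded for
    observed cells."""
    dist = masks.lookup(masks.interior_distance(), cells.positions, outside=0.0)
    inside = masks.lookup(masks.ln_mask.astype(float), cells.positions) > 0
    keep = inside & (dist >= masks.edge_margin)
    return CellSet(cells.positions[keep], cells.color_class[keep],
                   cells.sphere_diameter)


# ---------------------------------------------------------------------------
# Clustering and the Monte-Carlo null
# ---------------------------------------------------------------------------

def _dbscan_eps(cells: CellSet, search_radius: float, neighbor_mode: str) -> float:
    if neighbor_mode == "surface-surface":
        return search_radius + cells.sphere_diameter
    if neighbor_mode == "surface-center":
        return search_radius + cells.sphere_diameter / 2.0
    raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")


def find_clusters(
    cells: CellSet,
    search_radius: float = 20.0,
    min_cells: int = 3,
    neighbor_mode: str = "surface-surface",
    yellow_in_denominator: bool = True,
) -> ClusterStats:
    """Same-lineage DBSCAN clustering of classified cells.

    Green and red lineages are clustered independently; yellow cells are not
    cluster candidates (clusters are single-lineage) but count in the
    clustered-fraction denominator by default.  Two cells are neighbors when
    their 12-um spheres are within ``search_radius`` of each other
    surface-to-surface, i.e. center distance <= search_radius +
    sphere_diameter; a cluster is a density-connected set of at least
    ``min_cells`` cells (DBSCAN min_samples = min_cells, counting the point
    itself; border cells belong to their cluster).
    """
    if min_cells < 2:
        raise ValueError("min_cells must be >= 2")
    eps = _dbscan_eps(cells, search_radius, neighbor_mode)
    clusters = []
    clustered = 0
    for lineage in ("green", "red"):
        idx = np.flatnonzero(cells.color_class == lineage)
        if len(idx) < min_cells:
            continue
        labels = DBSCAN(eps=eps, min_samples=min_cells).fit_predict(
            cells.positions[idx])
        for lab in np.unique(labels):
            if lab < 0:
                continue
            members = idx[labels == lab]
            clusters.append((lineage, members))
            clustered += len(members)
    n_total = len(cells) if yellow_in_denominator else int(
        np.sum(cells.color_class != "yellow"))
    sizes = np.array([len(m) for _, m in clusters], dtype=int)
    frac = clustered / n_total if n_total else 0.0
    return ClusterStats(clusters=clusters, n_clusters=len(clusters),
                        sizes=sizes, clustered_fraction=frac, n_cells=n_total)


def simulate_random(
    n_per_lineage: dict[str, int],
    masks: RegionMasks,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
    search_radius: float = 20.0,
    min_cells: int = 3,
    sphere_diameter: float = 12.0,
    neighbor_mode: str = "surface-surface",
    return_cells: bool = False,
):
    """Random-placement null for the Cluster Factor.

    Each replicate places the observed per-lineage cell counts uniformly at
    random in the placement region (node interior eroded by the edge margin,
    minus vessel volumes), clusters them with identical parameters and
    records the clustered fraction.  Returns the mean fraction over
    ``n_reps`` (and the per-replicate (CellSet, ClusterStats) pairs when
    ``return_cells`` is set).  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region = masks.placement_region()
    if not region.any():
        raise PlacementError("no voxel available for random placement")
    fractions = []
    reps = []
    for _ in range(n_reps):
        pos = []
        col = []
        for lineage, n in n_per_lineage.items():
            if n == 0:
                continue
            pos.append(masks.sample_uniform(n, rng, region))
            col.extend([lineage] * n)
        cells = CellSet(np.vstack(pos) if pos else np.empty((0, 3)),
                        np.array(col), sphere_diameter=sphere_diameter)
        stats = find_clusters(cells, search_radius=search_radius,
                              min_cells=min_cells, neighbor_mode=neighbor_mode)
        fractions.append(stats.clustered_fraction)
        if return_cells:
            reps.append((cells, stats))
    mean_frac = float(np.mean(fractions))
    if return_cells:
        return mean_frac, reps
    return mean_frac


def cluster_factor(observed_fraction: float, simulated_fraction: float) -> float:
    """CF = observed clustered fraction / simulated clustered fraction.

    CF = 100 means 100 times more cells sit in clusters than expected by
    chance alone; CF = 1 is chance level.
    """
    if observed_fraction < 0 or simulated_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if simulated_fraction == 0:
        if observed_fraction == 0:
            warnings.warn("CF undefined: no clustering observed or simulated",
                          stacklevel=2)
            return float("nan")
        warnings.warn("simulated clustered fraction is 0: CF reported as inf",
                      stacklevel=2)
        return float("inf")
    return observed_fraction / simulated_fraction


def _clustered_flags(cells: CellSet, stats: ClusterStats) -> np.ndarray:
    flags = np.zeros(len(cells), dtype=bool)
    for _, members in stats.clusters:
        flags[members] = True
    return flags


def cf_by_hev_distance(
    cells: CellSet,
    stats: ClusterStats,
    sim_reps: list[tuple[CellSet, ClusterStats]],
    masks: RegionMasks,
    bin_width: float = 50.0,
) -> CFProfile:
    """Cluster Factor profiled by distance from the nearest vessel surface.

    Each observed and simulated cell is assigned its distance to the nearest
    vessel voxel (distance transform of the vessel mask); per distance bin,
    CF is the ratio of the observed to the pooled simulated clustered
    fraction.  Bins without cells (or without simulated cells) yield NaN.
    """
    hev_d = masks.hev_distance()
    d_obs = masks.lookup(hev_d, cells.positions, outside=np.nan)
    obs_flags = _clustered_flags(cells, stats)
    d_sim = []
    sim_flags = []
    for scells, sstats in sim_reps:
        d_sim.append(masks.lookup(hev_d, scells.positions, outside=np.nan))
        sim_flags.append(_clustered_flags(scells, sstats))
    d_sim = np.concatenate(d_sim) if d_sim else np.empty(0)
    sim_flags = np.concatenate(sim_flags) if sim_flags else np.empty(0, dtype=bool)

    dmax = np.nanmax(np.concatenate([d_obs, d_sim])) if len(d_obs) else 0.0
    n_bins = max(1, int(np.ceil((dmax + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    cf = np.full(n_bins, np.nan)
    for b in range(n_bins):
        in_obs = (d_obs >= edges[b]) & (d_obs < edges[b + 1])
        in_sim = (d_sim >= edges[b]) & (d_sim < edges[b + 1])
        if in_obs.sum() == 0 or in_sim.sum() == 0:
            continue
        f_obs = obs_flags[in_obs].mean()
        f_sim = sim_flags[in_sim].mean()
        if f_sim > 0:
            cf[b] = f_obs / f_sim
        elif f_obs == 0:
            cf[b] = np.nan
        else:
            cf[b] = np.inf
    return CFProfile(distance_bins=edges[:-1], cf_per_bin=cf, bin_width=bin_width)


def cluster_size_distribution(stats: ClusterStats) -> dict[int, float]:
    """Percentage of clusters per cluster-size bin, normalized to 100%."""
    if stats.n_clusters == 0:
        return {}
    sizes, counts = np.unique(stats.sizes, return_counts=True)
    pct = 100.0 * counts / counts.sum()
    return {int(s): float(p) for s, p in zip(sizes, pct)}


def with_cf(stats: ClusterStats, simulated_fraction: float) -> ClusterStats:
    """Return a copy of ``stats`` with the Cluster Factor filled in."""
    return replace(stats, cf=cluster_factor(stats.clustered_fraction,
                                            simulated_fraction))
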