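"""Seeded generators producing inputs with known ground truth for every stage.

The toolkit's measurements come from bespoke laboratory assays whose raw data
cannot be redistributed, so each pipeline stage has a matching generator that
emulates its input with the generating parameters recorded alongside:

* double-exponential force relaxation traces with plate geometry,
* square-lattice reticular network masks with a known gap size,
* parent--offspring clustered (or uniform) labeled-cell point patterns inside
  an ellipsoidal node phantom with cylindrical vessel exclusions and a rigid
  two-channel misalignment,
* fibril bundles with a set angular dispersion about a known centerline,
* recoil movies of a textured band retracting from a cut at constant speed,
* aspiration tongue heights for a known capsule modulus.

Determinism: every generator takes a ``seed`` and derives one independent
child stream per stochastic component (placement, noise, ...) from it, so an
identical call yields bit-identical output and changing one parameter does
not reshuffle unrelated draws.

The default node phantom is an ellipsoid with semi-axes (420, 260, 260) um
and three vessel cylinders of radius 20 um.  With the standard 100-um edge
margin this leaves an interior of ~3.4e7 um^3, chosen so that 300 uniformly
placed cells produce a null clustered fraction of roughly 0.1 under the
standard cluster criterion -- dense enough for the chance level to be
estimated stably, sparse enough that clonal clusters stand far above it.
The phantom is a desk-scale stand-in, not an anatomical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .clonal_clusters import CellSet, RegionMasks, RigidTransform, SpotSet
from .fibril_alignment import CenterlineSpline, FibrilTrace
from .mechanics import (
    AspirationMeasurement,
    ForceTrace,
    PlateGeometry,
    effective_resistance,
    strain,
    youngs_modulus,
)
from .network_gaps import NetworkMask
from .recoil import CutGeometry, Kymograph

__all__ = [
    "DEFAULT_LN_SEMI_AXES",
    "DEFAULT_HEV_CYLINDERS",
    "gen_relaxation_trace",
    "gen_network_mask",
    "gen_madm_cells",
    "gen_fibril_bundle",
    "gen_recoil_movie",
    "gen_aspiration",
    "RelaxationTruth",
    "NetworkTruth",
    "MadmTruth",
    "FibrilTruth",
    "RecoilTruth",
    "AspirationTruth",
]

DEFAULT_LN_SEMI_AXES = (420.0, 260.0, 260.0)  # um
DEFAULT_HEV_CYLINDERS = (
    ((-350.0, 0.0, 0.0), (350.0, 0.0, 0.0), 20.0),
    ((-300.0, 80.0, -60.0), (300.0, 80.0, -60.0), 20.0),
    ((-300.0, -80.0, 60.0), (300.0, -80.0, 60.0), 20.0),
)

_DEFAULT_GEOMETRY = dict(h0=2.0, h_eq=1.5, L=2.4, R1=1.0, R2=1.0, R3=0.5)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Stress relaxation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationTruth:
    F_eq: float
    A1: float
    tau1: float
    A2: float
    tau2: float
    sigma: float  # N/m
    E: float  # Pa
    eps: float
    k1: float
    k2: float
    mu1: float
    mu2: float


def gen_relaxation_trace(
    F_eq: float = 40.0,
    A1: float = 30.0,
    tau1: float = 5.0,
    A2: float = 20.0,
    tau2: float = 300.0,
    noise_sd: float = 0.4,
    duration: float = 1200.0,
    dt: float = 1.0,
    geometry: PlateGeometry | None = None,
    seed: int = 0,
) -> tuple[ForceTrace, PlateGeometry, RelaxationTruth]:
    """Synthetic plate-compression relaxation trace.

    ``F(t) = F_eq + A1 exp(-t/tau1) + A2 exp(-t/tau2)`` plus Gaussian noise
    of absolute standard deviation ``noise_sd`` (uN; the default is 1% of the
    default equilibrium force).  The default geometry corresponds to a 25%
    strain compression.  Returns the trace, the geometry and the generating
    parameters together with the bulk quantities they imply.
    """
    if tau1 >= tau2:
        raise ValueError("tau1 must be smaller than tau2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    geom = geometry or PlateGeometry(**_DEFAULT_GEOMETRY)
    (rng,) = _streams(seed, 1)
    t = np.arange(0.0, duration + dt / 2, dt)
    F = F_eq + A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2)
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    F = np.clip(F, 0.0, None)
    eps = strain(geom.h0, geom.h_eq)
    k1 = (A1 / (np.pi * geom.R3**2)) / eps
    k2 = (A2 / (np.pi * geom.R3**2)) / eps
    truth = RelaxationTruth(
        F_eq=F_eq, A1=A1, tau1=tau1, A2=A2, tau2=tau2,
        sigma=effective_resistance(F_eq, geom),
        E=youngs_modulus(F_eq, geom.R3, eps), eps=eps,
        k1=k1, k2=k2, mu1=k1 * tau1, mu2=k2 * tau2,
    )
    return ForceTrace(t, F, strain_onset_t=0.0), geom, truth


# ---------------------------------------------------------------------------
# Network masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTruth:
    gap_side_px: int  # inscribed gap size (pitch - strand_width)
    lattice_pitch: int
    strand_width: int


def gen_network_mask(
    mode: str = "2d",
    shape: tuple = None,
    lattice_pitch: int = 20,
    strand_width: int = 4,
    pixel_size: float = 0.5,
    jitter_px: int = 0,
    seed: int = 0,
) -> tuple[NetworkMask, NetworkTruth]:
    """Square-lattice reticular network mask with known gap size.

    Strands of ``strand_width`` px run along both in-plane axes every
    ``lattice_pitch`` px, leaving square gaps of side
    ``pitch - strand_width``; ``jitter_px`` randomly offsets each strand.
    In 3D mode the lattice is extruded along z (tube lattice), so the
    inscribed sphere of a gap matches the 2D inscribed circle.
    """
    if strand_width >= lattice_pitch:
        raise ValueError("lattice_pitch must exceed strand_width")
    if shape is None:
        shape = (128, 128) if mode == "2d" else (32, 96, 96)
    (rng,) = _streams(seed, 1)

    def lattice_1d(n: int) -> np.ndarray:
        on = np.zeros(n, dtype=bool)
        for s in range(0, n, lattice_pitch):
            off = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            a = max(0, s + off)
            on[a:a + strand_width] = True
        return on

    if mode == "2d":
        rows = lattice_1d(shape[0])
        cols = lattice_1d(shape[1])
        net = rows[:, None] | cols[None, :]
    elif mode == "3d":
        rows = lattice_1d(shape[1])
        cols = lattice_1d(shape[2])
        plane = rows[:, None] | cols[None, :]
        net = np.broadcast_to(plane, shape).copy()
    else:
        raise ValueError("mode must be '2d' or '3d'")
    truth = NetworkTruth(gap_side_px=lattice_pitch - strand_width,
                         lattice_pitch=lattice_pitch, strand_width=strand_width)
    return NetworkMask(net, pixel_size=pixel_size), truth


# ---------------------------------------------------------------------------
# Clustered labeled cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MadmTruth:
    cells: CellSet  # true (registered) cell positions and lineages
    parent_of: np.ndarray  # -1 for singletons, else parent index
    channel_transform: RigidTransform


def gen_madm_cells(
    ln_semi_axes: tuple = DEFAULT_LN_SEMI_AXES,
    hev_cylinders: tuple = DEFAULT_HEV_CYLINDERS,
    n_parents: int = 10,
    offspring_per_parent: int = 10,
    dispersion_sd_um: float = 8.0,
    n_singletons: int = 0,
    channel_transform: RigidTransform | None = None,
    voxel_size: float = 10.0,
    edge_margin: float = 100.0,
    seed: int = 0,
) -> tuple[SpotSet, SpotSet, RegionMasks, MadmTruth]:
    """Two-channel labeled-cell point pattern inside the node phantom.

    Parents are uniform over the placement region (node interior eroded by
    ``edge_margin``, minus vessel volumes); each parent gets
    ``offspring_per_parent`` offspring displaced by an isotropic Gaussian of
    standard deviation ``dispersion_sd_um``; parents alternate green/red
    lineage, as do the uniformly placed singletons.  The red channel is
    rigidly moved by ``channel_transform`` to emulate spectral misalignment
    (identity by default).  With ``offspring_per_parent=1`` or singletons
    only, the pattern is completely spatially random.
    """
    masks = RegionMasks.from_ellipsoid(
        ln_semi_axes, list(hev_cylinders), voxel_size=voxel_size,
        edge_margin=edge_margin)
    transform = channel_transform or RigidTransform.identity()
    rng_place, rng_disp = _streams(seed, 2)
    region = masks.placement_region()

    positions = []
    lineages = []
    parent_of = []
    if n_parents:
        parents = masks.sample_uniform(n_parents, rng_place, region)
        for i, p in enumerate(parents):
            lineage = "green" if i % 2 == 0 else "red"
            offs = p + rng_disp.normal(0.0, dispersion_sd_um,
                                       size=(offspring_per_parent, 3))
            positions.append(offs)
            lineages.extend([lineage] * offspring_per_parent)
            parent_of.extend([i] * offspring_per_parent)
    if n_singletons:
        singles = masks.sample_uniform(n_singletons, rng_place, region)
        positions.append(singles)
        lineages.extend(["green" if i % 2 == 0 else "red"
                         for i in range(n_singletons)])
        parent_of.extend([-1] * n_singletons)
    pos = np.vstack(positions) if positions else np.empty((0, 3))
    lineages = np.array(lineages)
    cells = CellSet(pos, lineages)

    green = SpotSet("green", pos[lineages == "green"])
    red_true = pos[lineages == "red"]
    red = SpotSet("red", transform.apply(red_true) if len(red_true) else red_true)
    truth = MadmTruth(cells=cells, parent_of=np.asarray(parent_of, dtype=int),
                      channel_transform=transform)
    return green, red, masks, truth


# ---------------------------------------------------------------------------
# Fibril bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FibrilTruth:
    centerline: CenterlineSpline
    half_angle_deg: float


_STRAIGHT_SUPPORTS = np.array(
    [[0.0, 0.0, 0.0], [400.0, 0.0, 0.0], [800.0, 0.0, 0.0], [1200.0, 0.0, 0.0]])


def gen_fibril_bundle(
    centerline_supports: np.ndarray | None = None,
    n_fibrils: int = 60,
    half_angle_deg: float = 20.0,
    fibril_length: float = 150.0,
    n_points: int = 11,
    lateral_jitter: float = 15.0,
    seed: int = 0,
) -> tuple[list[FibrilTrace], FibrilTruth]:
    """Bundle of straight fibrils at a fixed angle to a known centerline.

    Fibril midpoints sit at uniform arc positions on the centerline (nm) with
    a small lateral jitter; each fibril's direction is the local centerline
    tangent tilted by ``half_angle_deg`` about a uniformly random azimuth, so
    the true per-fibril alignment angle equals ``half_angle_deg`` exactly.
    """
    if not (0.0 <= half_angle_deg < 90.0):
        raise ValueError("half_angle_deg must be in [0, 90)")
    supports = (_STRAIGHT_SUPPORTS if centerline_supports is None
                else np.asarray(centerline_supports, dtype=float))
    spline = CenterlineSpline(supports)
    rng_pos, rng_dir = _streams(seed, 2)
    theta = np.radians(half_angle_deg)
    fibrils = []
    for i in range(n_fibrils):
        u = rng_pos.uniform(0.05, 0.95)
        base = spline.evaluate(u)
        t = spline.tangent(u)
        t = t / np.linalg.norm(t)
        # orthonormal frame around the tangent
        helper = np.array([0.0, 0.0, 1.0])
        if abs(t @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n1 = np.cross(t, helper)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        phi = rng_dir.uniform(0.0, 2 * np.pi)
        direction = (np.cos(theta) * t
                     + np.sin(theta) * (np.cos(phi) * n1 + np.sin(phi) * n2))
        mid = base + rng_pos.normal(0.0, lateral_jitter) * n1 \
            + rng_pos.normal(0.0, lateral_jitter) * n2
        s = np.linspace(-fibril_length / 2, fibril_length / 2, n_points)
        pts = mid + s[:, None] * direction
        fibrils.append(FibrilTrace(pts, id=f"fibril_{i}"))
    return fibrils, FibrilTruth(centerline=spline, half_angle_deg=half_angle_deg)


# ---------------------------------------------------------------------------
# Recoil movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoilTruth:
    v_um_s: float
    cut_frame: int
    cut_col_px: int
    px_size: float
    frame_interval: float


def gen_recoil_movie(
    v_um_s: float = 2.0,
    px_size: float = 0.2,
    frame_interval: float = 0.2,
    n_frames: int = 25,
    cut_frame: int = 5,
    shape: tuple[int, int] = (64, 256),
    cut_col_px: int = 60,
    texture_sd: float = 30.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, Kymograph, CutGeometry, RecoilTruth]:
    """Movie of a textured band retracting from a vertical cut at constant v.

    Frames before ``cut_frame`` are static; afterwards the band (columns to
    the right of the cut) translates rightward at ``v_um_s``, exposing dark
    background.  The band carries a smooth random texture (so the field
    pathway has features to correlate) on a bright plateau (so the kymograph
    pathway sees a strong edge); per-frame Gaussian noise is added last.
    Returns the frame stack, the kymograph along the recoil axis (columns x
    time, averaged over rows), the cut geometry and the ground truth.
    """
    if v_um_s < 0:
        raise ValueError("v must be >= 0")
    H, W = shape
    rng_tex, rng_noise = _streams(seed, 2)
    tex = ndimage.gaussian_filter(rng_tex.normal(0.0, 1.0, size=(H, W)), 2.0)
    tex = 100.0 + texture_sd * tex / max(tex.std(), 1e-12)
    background = 10.0
    rows = np.arange(H)
    cols = np.arange(W)
    frames = np.empty((n_frames, H, W))
    for k in range(n_frames):
        shift_px = v_um_s * max(0, k - cut_frame) * frame_interval / px_size
        rr, cc = np.meshgrid(rows, cols - shift_px, indexing="ij")
        band = ndimage.map_coordinates(tex, [rr, cc], order=3, mode="nearest")
        frame = np.where(cols[None, :] >= cut_col_px + shift_px, band, background)
        frame = ndimage.gaussian_filter(frame, 1.0)
        if noise_sd > 0:
            frame = frame + rng_noise.normal(0.0, noise_sd, size=frame.shape)
        frames[k] = frame
    kymo = Kymograph(intensity=frames.mean(axis=1).T, px_size=px_size,
                     frame_interval=frame_interval, cut_frame=cut_frame)
    x_cut = cut_col_px * px_size
    cut = CutGeometry(
        cut_line=np.array([[0.0, x_cut], [H * px_size, x_cut]]),
        roi=(0.0, x_cut, H * px_size, W * px_size),
    )
    truth = RecoilTruth(v_um_s=v_um_s, cut_frame=cut_frame,
                        cut_col_px=cut_col_px, px_size=px_size,
                        frame_interval=frame_interval)
    return frames, kymo, cut, truth


# ---------------------------------------------------------------------------
# Aspiration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AspirationTruth:
    E: float  # Pa
    h_noiseless: float  # um


def gen_aspiration(
    E_true: float,
    delta_P: float = 750.0,
    d: float = 15.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[AspirationMeasurement, AspirationTruth]:
    """Aspiration tongue height for a known capsule modulus.

    Inverts Laplace's law: ``h = d sqrt(delta_P / E_true)``, optionally with
    multiplicative Gaussian measurement noise on h.  Noiseless measurements
    round-trip through the modulus computation exactly.
    """
    if E_true <= 0 or delta_P <= 0 or d <= 0:
        raise ValueError("E_true, delta_P and d must be > 0")
    (rng,) = _streams(seed, 1)
    h = d * np.sqrt(delta_P / E_true)
    h_meas = h * (1.0 + rng.normal(0.0, noise_frac)) if noise_frac > 0 else h
    return (AspirationMeasurement(delta_P=delta_P, d=d, h=float(h_meas)),
            AspirationTruth(E=E_true, h_noiseless=float(h)))
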