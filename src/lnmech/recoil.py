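"""Post-ablation recoil velocimetry from kymographs and frame pairs.

Severing a tensed structure with a pulsed laser makes the cut edges retract;
the initial recoil velocity is proportional to the tension released.  Two
read-outs are implemented:

* **Kymograph pathway** — a space x time intensity image along the recoil
  axis shows the retracting edge as a sloped streak.  The edge is localized
  per frame at the maximum spatial intensity gradient (sub-pixel refined by
  parabolic interpolation) and the recoil velocity is the least-squares slope
  of the edge track over the first frames after the cut.

* **Field pathway** — displacement between a bandpass-filtered pre-cut frame
  and a post-cut frame is estimated per interrogation window by normalized
  cross-correlation with parabolic sub-pixel peak refinement (particle image
  velocimetry).  The recoil is the mean velocity component perpendicular to
  the cut line over valid vectors inside a region of interest around the cut,
  with motion away from the cut counted positive.

Image convention: axis 0 is space/rows (y), axis 1 is time (kymographs) or
columns (frames).  Physical positions are in um, velocities in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Kymograph",
    "EdgeTrack",
    "CutGeometry",
    "VelocityField",
    "EdgeNotFoundError",
    "UndefinedRecoilError",
    "extract_edge",
    "recoil_velocity",
    "piv_displacement",
    "perpendicular_recoil",
]


class EdgeNotFoundError(RuntimeError):
    """Raised when no intensity edge stands out of the noise floor."""


class UndefinedRecoilError(RuntimeError):
    """Raised when no valid velocity vector lies inside the region of
    interest."""


@dataclass(frozen=True)
class Kymograph:
    """Space x time intensity image along the recoil axis."""

    intensity: np.ndarray  # (space, time)
    px_size: float  # um / px
    frame_interval: float  # s / frame
    cut_frame: int

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", arr)
        if arr.ndim != 2:
            raise ValueError("kymograph must be 2D (space x time)")
        if self.px_size <= 0 or self.frame_interval <= 0:
            raise ValueError("px_size and frame_interval must be > 0")
        if not (0 <= self.cut_frame < arr.shape[1]):
            raise ValueError("cut_frame outside the time range")


@dataclass(frozen=True)
class EdgeTrack:
    """Edge position (um) per analyzed frame; t = 0 at the cut."""

    t: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        if len(self.t) != len(self.position):
            raise ValueError("one position per time point required")


@dataclass(frozen=True)
class CutGeometry:
    """Cut line (two endpoints, um, (row, col)) and rectangular roi
    (row_min, col_min, row_max, col_max) in um."""

    cut_line: np.ndarray  # (2, 2)
    roi: tuple  # (rmin, cmin, rmax, cmax)

    def __post_init__(self):
        cl = np.asarray(self.cut_line, dtype=float)
        object.__setattr__(self, "cut_line", cl)
        if cl.shape != (2, 2) or np.allclose(cl[0], cl[1]):
            raise ValueError("cut_line needs two distinct endpoints")
        rmin, cmin, rmax, cmax = self.roi
        if rmax <= rmin or cmax <= cmin:
            raise ValueError("roi is empty")


@dataclass(frozen=True)
class VelocityField:
    """PIV result: window-center positions (um), velocity vectors (um/s)
    and per-vector validity."""

    positions: np.ndarray  # (n, 2) as (row, col) um
    vectors: np.ndarray  # (n, 2) um/s
    valid: np.ndarray  # (n,) bool


# ---------------------------------------------------------------------------
# Kymograph pathway
# ---------------------------------------------------------------------------

def _subpixel_peak_1d(values: np.ndarray, i: int) -> float:
    """Parabolic refinement of a peak at integer index i."""
    if i == 0 or i == len(values) - 1:
        return float(i)
    c0, c1, c2 = values[i - 1], values[i], values[i + 1]
    denom = c0 - 2 * c1 + c2
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (c0 - c2) / denom)


def extract_edge(kymo: Kymograph, smooth_sigma: float = 1.0,
                 snr_threshold: float = 6.0) -> EdgeTrack:
    """Track the dominant intensity edge in every post-cut frame.

    Per frame, the edge is the location of maximum absolute spatial gradient
    of the (lightly smoothed) intensity profile, refined to sub-pixel
    accuracy by a parabolic fit.  Frames whose strongest gradient does not
    exceed ``snr_threshold`` robust noise standard deviations raise
    :class:`EdgeNotFoundError`.
    """
    frames = range(kymo.cut_frame, kymo.intensity.shape[1])
    t = []
    pos = []
    for j in frames:
        profile = ndimage.gaussian_filter1d(kymo.intensity[:, j], smooth_sigma)
        grad = np.abs(np.gradient(profile))
        med = np.median(grad)
        noise = 1.4826 * np.median(np.abs(grad - med))
        peak = grad.max()
        if noise == 0:
            if peak == 0:
                raise EdgeNotFoundError(f"flat profile in frame {j}")
        elif (peak - med) / noise < snr_threshold:
            raise EdgeNotFoundError(
                f"no gradient above the noise floor in frame {j}")
        i = int(np.argmax(grad))
        pos.append(_subpixel_peak_1d(grad, i) * kymo.px_size)
        t.append((j - kymo.cut_frame) * kymo.frame_interval)
    return EdgeTrack(t=np.asarray(t), position=np.asarray(pos))


def recoil_velocity(track: EdgeTrack, window_frames: int = 5,
                    baseline_slope: float = 0.0) -> float:
    """Recoil velocity (um/s): least-squares slope of the edge track over the
    first ``window_frames`` points after the cut.

    ``baseline_slope`` (um/s) subtracts a pre-cut drift slope when one was
    measured; the default reports the raw post-cut slope.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if window_frames > len(track.t):
        raise ValueError("window extends beyond the track")
    t = track.t[:window_frames]
    x = track.position[:window_frames]
    slope = float(np.polyfit(t, x, 1)[0])
    return slope - baseline_slope


# ---------------------------------------------------------------------------
# Field pathway (PIV)
# ---------------------------------------------------------------------------

def bandpass(image: np.ndarray, sigma_low: float = 1.0,
             sigma_high: float = 8.0) -> np.ndarray:
    """Difference-of-Gaussians bandpass: keeps structure between the two
    length scales (px)."""
    img = np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(img, sigma_low) - ndimage.gaussian_filter(
        img, sigma_high)


def _ncc_shift(a: np.ndarray, b: np.ndarray,
               max_shift_frac: float = 0.25) -> tuple[np.ndarray, float]:
    """Cyclic normalized cross-correlation shift of b relative to a.

    Returns the sub-pixel displacement (row, col) maximizing the correlation
    and the normalized peak height (1 for a perfect cyclic copy).

    The window contents are not periodic, so the raw cyclic correlation at
    lag ``l`` is attenuated by the overlap fraction ``1 - |l|/m``, which
    biases the peak toward zero lag.  The peak is therefore located on the
    overlap-corrected correlation, with the search restricted to
    ``|l| <= max_shift_frac * m`` per axis (the usual quarter-window rule)
    so the correction cannot amplify spurious large-lag peaks.
    """
    a = a - a.mean()
    b = b - b.mean()
    sa = a.std()
    sb = b.std()
    n = a.size
    corr = np.fft.ifftn(np.fft.fftn(b) * np.conj(np.fft.fftn(a))).real
    weight = np.ones_like(corr)
    allowed = np.ones(corr.shape, dtype=bool)
    for ax, m in enumerate(corr.shape):
        lag = np.minimum(np.arange(m), m - np.arange(m))
        shape = [1] * corr.ndim
        shape[ax] = m
        weight = weight * (1.0 - lag / m).reshape(shape)
        allowed &= (lag <= m * max_shift_frac).reshape(shape)
    corru = np.where(allowed, corr / weight, -np.inf)
    peak_idx = np.unravel_index(np.argmax(corru), corru.shape)
    peak = corr[peak_idx] / (n * sa * sb)
    shift = []
    for ax, i in enumerate(peak_idx):
        # 1-D corrected-correlation profile through the peak along this axis
        sl = list(peak_idx)
        sl[ax] = slice(None)
        prof = corru[tuple(sl)]
        m = corr.shape[ax]
        c0 = prof[(i - 1) % m]
        c1 = prof[i]
        c2 = prof[(i + 1) % m]
        if not (np.isfinite(c0) and np.isfinite(c2)):
            s = float(i) if i <= m / 2 else float(i - m)
            shift.append(s)
            continue
        denom = c0 - 2 * c1 + c2
        frac = 0.0 if denom == 0 else 0.5 * (c0 - c2) / denom
        s = i + frac
        if s > m / 2:
            s -= m
        shift.append(s)
    return np.asarray(shift), float(peak)


def piv_displacement(
    frame_pre: np.ndarray,
    frame_post: np.ndarray,
    window_px: int = 32,
    overlap: float = 0.5,
    px_size: float = 1.0,
    frame_interval: float = 1.0,
    bandpass_sigmas: tuple[float, float] = (1.0, 8.0),
    min_peak: float = 0.3,
) -> VelocityField:
    """Block-wise PIV between a pre-cut and a post-cut frame.

    Both frames are difference-of-Gaussians bandpass filtered, tiled into
    ``window_px`` interrogation windows with the given fractional overlap,
    and each window's displacement is the sub-pixel peak of the normalized
    cross-correlation.  Windows with (near) zero variance or a correlation
    peak below ``min_peak`` are flagged invalid.  Displacements convert to
    velocities via ``px_size`` (um/px) and ``frame_interval`` (s between the
    two frames).
    """
    pre = np.asarray(frame_pre, dtype=float)
    post = np.asarray(frame_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("frames must have equal shape")
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    pre_f = bandpass(pre, *bandpass_sigmas)
    post_f = bandpass(post, *bandpass_sigmas)
    step = max(1, int(round(window_px * (1.0 - overlap))))
    positions = []
    vectors = []
    valid = []
    eps_var = 1e-12 * max(1.0, pre_f.var())
    for r0 in range(0, pre.shape[0] - window_px + 1, step):
        for c0 in range(0, pre.shape[1] - window_px + 1, step):
            wa = pre_f[r0:r0 + window_px, c0:c0 + window_px]
            wb = post_f[r0:r0 + window_px, c0:c0 + window_px]
            center = ((r0 + window_px / 2.0) * px_size,
                      (c0 + window_px / 2.0) * px_size)
            positions.append(center)
            if wa.var() <= eps_var or wb.var() <= eps_var:
                vectors.append((0.0, 0.0))
                valid.append(False)
                continue
            shift, peak = _ncc_shift(wa, wb)
            ok = peak >= min_peak
            vectors.append(tuple(shift * px_size / frame_interval))
            valid.append(ok)
    return VelocityField(
        positions=np.asarray(positions),
        vectors=np.asarray(vectors),
        valid=np.asarray(valid, dtype=bool),
    )


def perpendicular_recoil(field: VelocityField, cut: CutGeometry) -> float:
    """Mean velocity component perpendicular to the cut line (um/s).

    Averages ``v . n_hat`` over valid vectors inside the roi, where ``n_hat``
    is the unit normal of the cut line oriented toward the roi centroid, so
    motion away from the cut is positive.
    """
    p0, p1 = cut.cut_line
    along = p1 - p0
    normal = np.array([-along[1], along[0]], dtype=float)
    normal /= np.linalg.norm(normal)
    rmin, cmin, rmax, cmax = cut.roi
    centroid = np.array([(rmin + rmax) / 2.0, (cmin + cmax) / 2.0])
    midpoint = (p0 + p1) / 2.0
    if np.dot(normal, centroid - midpoint) < 0:
        normal = -normal
    inside = (
        (field.positions[:, 0] >= rmin) & (field.positions[:, 0] <= rmax)
        & (field.positions[:, 1] >= cmin) & (field.positions[:, 1] <= cmax)
    )
    sel = inside & field.valid
    if not sel.any():
        raise UndefinedRecoilError("no valid velocity vector inside the roi")
    return float(np.mean(field.vectors[sel] @ normal))
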