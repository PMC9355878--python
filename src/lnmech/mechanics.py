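"""Inversion of plate-compression and micropipette measurements into tissue mechanics.

An explanted lymph node compressed between parallel plates to a fixed strain
relaxes towards a force equilibrium.  The relaxation is described by a
generalized Kelvin body (two spring--dashpot branches in addition to the
equilibrium spring), whose force response at constant strain is a double
exponential decay

    F(t) = F_eq + A1 * exp(-t / tau1) + A2 * exp(-t / tau2),   tau1 < tau2.

From the fitted asymptote ``F_eq`` and the manually measured node geometry the
organ-scale quantities follow:

* effective resistance  sigma = (F_eq / (pi R3^2)) / (1/R1 + 1/R2)   [N/m]
* stress                s     = F_eq / (pi R3^2)                      [Pa]
* strain                eps   = 1 - h_eq / h0
* Young's modulus       E     = s / eps                               [Pa]
* branch viscosities    mu_i  = k_i * tau_i   with   k_i = (A_i / (pi R3^2)) / eps
* node volume           V     = 4/3 pi R1 (h0 / 2)^2                  [mm^3]

The capsule is probed separately by micropipette aspiration; Laplace's law
gives the capsule Young's modulus E = dP / (h/d)^2 from the aspirated tongue
height ``h``, the pipette inner diameter ``d`` and the applied pressure step
``dP``.  Passive capsule tension is the product of capsule modulus and
thickness.

Bench units are used throughout the public API: forces in uN, lengths in mm
(geometry) or um (pipette, capsule), times in s, moduli in Pa.  uN/mm^2 equals
Pa exactly, so stress-like quantities need no numeric conversion; conversions
that do change magnitude (mm -> m, um -> m) are explicit and centralized here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ForceTrace",
    "PlateGeometry",
    "KelvinFit",
    "TissueMechanics",
    "AspirationMeasurement",
    "CapsuleMechanics",
    "InvalidGeometryError",
    "InvalidInputError",
    "FitFailureError",
    "fit_relaxation",
    "strain",
    "effective_resistance",
    "youngs_modulus",
    "viscosities",
    "ln_volume_from_sideview",
    "aspiration_modulus",
    "passive_tension",
    "analyze_compression",
]

MM_PER_M = 1000.0  # 1/mm -> 1/m multiplies by this
UM_PER_M = 1e6


class InvalidInputError(ValueError):
    """Raised for malformed measurement data (non-monotone time, bad strain...)."""


class InvalidGeometryError(InvalidInputError):
    """Raised when plate/node geometry violates its physical constraints."""


class FitFailureError(RuntimeError):
    """Raised when the double-exponential fit fails to converge from any start."""


@dataclass(frozen=True)
class ForceTrace:
    """A stress-relaxation measurement: force on the upper plate over time.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    F : array of float
        Measured force in uN, same length as ``t``, non-negative.
    strain_onset_t : float
        Time (s) at which the compression ramp completed; the relaxation fit
        uses only samples at ``t >= strain_onset_t``.
    """

    t: np.ndarray
    F: np.ndarray
    strain_onset_t: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "F", F)
        if t.ndim != 1 or F.ndim != 1 or len(t) != len(F):
            raise InvalidInputError("t and F must be 1-D arrays of equal length")
        if len(t) < 10:
            raise InvalidInputError("a relaxation trace needs at least 10 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if np.any(F < 0):
            raise InvalidInputError("forces must be non-negative")


@dataclass(frozen=True)
class PlateGeometry:
    """Manually measured side-view geometry of the compressed node (all mm).

    ``h0``/``h_eq`` are the node heights before compression and at force
    equilibrium, ``L`` the pre-compression length, ``R1``/``R2`` the two
    curvature radii of the free surface and ``R3`` the plate-contact radius.
    """

    h0: float
    h_eq: float
    L: float
    R1: float
    R2: float
    R3: float

    def __post_init__(self):
        for name in ("h0", "h_eq", "L", "R1", "R2", "R3"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.h_eq > self.h0:
            raise InvalidGeometryError("h_eq cannot exceed h0")


@dataclass(frozen=True)
class KelvinFit:
    """Double-exponential decomposition of a relaxation trace (uN / s).

    ``tau1 < tau2`` by construction; ``viscosity_undetermined`` is set when
    the slow timescale exceeds half the recording span and the slow-branch
    viscosity therefore cannot be trusted (such measurements were excluded
    upstream in the original protocol; here they are flagged, not dropped).
    """

    F_eq: float
    A1: float
    A2: float
    tau1: float
    tau2: float
    rss: float
    viscosity_undetermined: bool = False

    def evaluate(self, t: np.ndarray, t0: float = 0.0) -> np.ndarray:
        """Model force at times ``t`` (s), with the decay clock starting at ``t0``."""
        dt = np.asarray(t, dtype=float) - t0
        return (
            self.F_eq
            + self.A1 * np.exp(-dt / self.tau1)
            + self.A2 * np.exp(-dt / self.tau2)
        )


@dataclass(frozen=True)
class TissueMechanics:
    """Derived bulk mechanical parameters of one compressed node."""

    sigma: float  # N/m
    stress_s: float  # Pa
    strain_eps: float
    E: float  # Pa
    k1: float  # Pa
    k2: float  # Pa
    mu1: float  # Pa s
    mu2: float  # Pa s  (reported as "the viscosity")
    volume: float  # mm^3
    fit: KelvinFit = field(repr=False, default=None)


@dataclass(frozen=True)
class AspirationMeasurement:
    """One micropipette aspiration: pressure step dP (Pa), pipette inner
    diameter d (um) and aspirated tongue height h (um)."""

    delta_P: float
    d: float
    h: float

    def __post_init__(self):
        if self.delta_P <= 0:
            raise InvalidInputError("delta_P must be > 0")
        if self.d <= 0:
            raise InvalidInputError("pipette diameter must be > 0")
        if self.h < 0:
            raise InvalidInputError("tongue height cannot be negative")


@dataclass(frozen=True)
class CapsuleMechanics:
    """Capsule modulus (Pa), thickness (um) and derived passive tension (N/m)."""

    E_capsule: float
    thickness: float
    passive_tension: float


# ---------------------------------------------------------------------------
# Relaxation fitting
# ---------------------------------------------------------------------------

def _double_exp(dt, F_eq, A1, tau1, A2, tau2):
    return F_eq + A1 * np.exp(-dt / tau1) + A2 * np.exp(-dt / tau2)


def fit_relaxation(
    trace: ForceTrace,
    n_starts: int = 8,
    tau_range: tuple[float, float] = (1.0, 1000.0),
) -> KelvinFit:
    """Fit ``F(t) = F_eq + A1 exp(-t/tau1) + A2 exp(-t/tau2)`` to a trace.

    Double exponentials are ill-conditioned, so the trust-region least-squares
    fit is restarted from ``n_starts`` initial (tau1, tau2) pairs log-spaced
    over ``tau_range`` and the lowest-residual solution kept.  Branches are
    canonicalized to ``tau1 < tau2``.  Only samples at
    ``t >= strain_onset_t`` enter the fit; the decay clock starts at the
    strain onset.

    Raises
    ------
    FitFailureError
        If no start converges.
    """
    sel = trace.t >= trace.strain_onset_t
    t = trace.t[sel] - trace.strain_onset_t
    F = trace.F[sel]
    if len(t) < 6:
        raise InvalidInputError("too few samples after strain onset")
    span = float(t[-1] - t[0])

    # Degenerate flat trace: asymptote only, zero amplitudes, zero residual.
    if np.ptp(F) < 1e-12 * max(1.0, abs(F[0])):
        return KelvinFit(F_eq=float(F[0]), A1=0.0, A2=0.0, tau1=1.0, tau2=2.0, rss=0.0)

    F_eq0 = float(F[-1])
    amp0 = max(float(F[0] - F[-1]), 1e-9)
    lo, hi = tau_range
    # Log-spaced (tau1, tau2) start pairs with tau1 < tau2.
    taus = np.geomspace(lo, hi, n_starts)
    starts = []
    for i in range(n_starts):
        t1 = taus[i]
        t2 = min(hi, t1 * 20.0)
        starts.append((t1, t2))

    best = None
    lower = [0.0, 0.0, 1e-6, 0.0, 1e-6]
    upper = [np.inf] * 5
    for t1, t2 in starts:
        p0 = [F_eq0, 0.6 * amp0, t1, 0.4 * amp0, t2]
        try:
            popt, _ = curve_fit(
                _double_exp, t, F, p0=p0, bounds=(lower, upper),
                maxfev=20000, method="trf",
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_double_exp(t, *popt) - F) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError(
            f"double-exponential fit did not converge from any of {n_starts} "
            f"starts (trace span {span:.1f} s, {len(t)} samples)"
        )
    (F_eq, A1, tau1, A2, tau2), rss = best
    if tau1 > tau2:  # canonical branch order
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    undetermined = bool(tau2 > span / 2.0)
    if undetermined:
        warnings.warn(
            "fitted slow timescale exceeds half the recording span; "
            "viscosity flagged undetermined",
            stacklevel=2,
        )
    return KelvinFit(
        F_eq=float(F_eq), A1=float(A1), A2=float(A2),
        tau1=float(tau1), tau2=float(tau2), rss=rss,
        viscosity_undetermined=undetermined,
    )


# ---------------------------------------------------------------------------
# Geometry-derived quantities
# ---------------------------------------------------------------------------

def strain(h0: float, h_eq: float) -> float:
    """Compressive strain ``eps = 1 - h_eq/h0`` from heights in mm."""
    if h0 <= 0 or h_eq <= 0:
        raise InvalidGeometryError("heights must be > 0")
    if h_eq > h0:
        raise InvalidGeometryError("h_eq cannot exceed h0 (negative strain)")
    return 1.0 - h_eq / h0


def _contact_stress(F_eq_uN: float, R3_mm: float) -> float:
    """Plate-contact stress s = F_eq / (pi R3^2) in Pa (uN/mm^2 == Pa)."""
    if R3_mm <= 0:
        raise InvalidGeometryError("R3 must be > 0")
    if F_eq_uN < 0:
        raise InvalidInputError("F_eq must be >= 0")
    return F_eq_uN / (math.pi * R3_mm**2)


def effective_resistance(F_eq: float, geom: PlateGeometry) -> float:
    """Effective resistance sigma = s / (1/R1 + 1/R2) in N/m.

    ``F_eq`` in uN, radii in mm.  The stress s is in Pa; curvatures 1/R are
    converted from 1/mm to 1/m, so sigma = s / ((1/R1 + 1/R2) * 1000).
    """
    s = _contact_stress(F_eq, geom.R3)
    curvature_per_m = (1.0 / geom.R1 + 1.0 / geom.R2) * MM_PER_M
    return s / curvature_per_m


def youngs_modulus(F_eq: float, R3: float, eps: float) -> float:
    """Young's modulus E = s / eps in Pa (F_eq in uN, R3 in mm)."""
    if eps <= 0:
        raise InvalidInputError("strain must be > 0 to derive a modulus")
    return _contact_stress(F_eq, R3) / eps


def viscosities(fit: KelvinFit, geom: PlateGeometry, eps: float) -> tuple[float, float]:
    """Branch viscosities (mu1, mu2) in Pa s from a Kelvin fit.

    Each decay amplitude is converted to a stress amplitude over the plate
    contact and divided by the applied strain to give the branch stiffness
    ``k_i = (A_i / (pi R3^2)) / eps`` (Pa); then ``mu_i = k_i * tau_i``,
    consistent with the relaxation timescales ``tau_i = mu_i / k_i``.
    mu1 is the fast (seconds) branch, mu2 the slow (minutes) branch; mu2 is
    the value reported as the tissue viscosity.
    """
    if eps <= 0:
        raise InvalidInputError("strain must be > 0")
    if fit.A1 < 0 or fit.A2 < 0:
        raise FitFailureError("negative decay amplitude: fit quality insufficient")
    k1 = _contact_stress(fit.A1, geom.R3) / eps
    k2 = _contact_stress(fit.A2, geom.R3) / eps
    return k1 * fit.tau1, k2 * fit.tau2


def ln_volume_from_sideview(R1: float, h0: float) -> float:
    """Node volume V = 4/3 pi R1 (h0/2)^2 in mm^3 from the t=0 side view."""
    if R1 <= 0 or h0 <= 0:
        raise InvalidGeometryError("R1 and h0 must be > 0")
    return (4.0 / 3.0) * math.pi * R1 * (h0 / 2.0) ** 2


# ---------------------------------------------------------------------------
# Capsule: aspiration and passive tension
# ---------------------------------------------------------------------------

def aspiration_modulus(m: AspirationMeasurement) -> float:
    """Capsule Young's modulus from Laplace's law: E = dP / (h/d)^2 (Pa)."""
    if m.h == 0:
        raise InvalidInputError("no aspiration (h = 0): modulus undefined")
    return m.delta_P / (m.h / m.d) ** 2


def passive_tension(E_capsule: float, thickness: float) -> float:
    """Passive capsule tension = E_capsule (Pa) x thickness (um -> m), in N/m."""
    if E_capsule < 0 or thickness < 0:
        raise InvalidInputError("modulus and thickness must be non-negative")
    return E_capsule * thickness / UM_PER_M


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def analyze_compression(trace: ForceTrace, geom: PlateGeometry) -> TissueMechanics:
    """Full inversion of one plate-compression measurement.

    Fits the relaxation, then derives strain, stress, effective resistance,
    Young's modulus, branch stiffnesses/viscosities and the node volume.
    """
    fit = fit_relaxation(trace)
    eps = strain(geom.h0, geom.h_eq)
    s = _contact_stress(fit.F_eq, geom.R3)
    sigma = effective_resistance(fit.F_eq, geom)
    E = youngs_modulus(fit.F_eq, geom.R3, eps)
    mu1, mu2 = viscosities(fit, geom, eps)
    k1 = _contact_stress(fit.A1, geom.R3) / eps
    k2 = _contact_stress(fit.A2, geom.R3) / eps
    V = ln_volume_from_sideview(geom.R1, geom.h0)
    return TissueMechanics(
        sigma=sigma, stress_s=s, strain_eps=eps, E=E,
        k1=k1, k2=k2, mu1=mu1, mu2=mu2, volume=V, fit=fit,
    )
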