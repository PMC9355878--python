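"""Compartment volumetrics and small intensity ratio computations.

Fully specified ratio/fraction procedures used alongside the mechanical
measurements: exclusive compartment volume fractions (with the stated
overlap-subtraction order), nuclear-to-cytoplasmic intensity ratio of the
mechanosensitive transcription factors YAP/TAZ, capsule thickness averaging,
and control-normalized intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompartmentMasks",
    "CompartmentVolumes",
    "NCRatioMeasurement",
    "exclusive_compartments",
    "nc_ratio",
    "capsule_thickness",
    "normalize_to_controls",
]

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class CompartmentMasks:
    """Binary T-zone, follicle and lymphatic volumes in a shared frame."""

    t_zone: np.ndarray
    follicles: np.ndarray
    lymphatics: np.ndarray
    voxel_volume: float  # um^3

    def __post_init__(self):
        t = np.asarray(self.t_zone, dtype=bool)
        b = np.asarray(self.follicles, dtype=bool)
        l = np.asarray(self.lymphatics, dtype=bool)
        if not (t.shape == b.shape == l.shape):
            raise ValueError("masks must share a shape")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be > 0")
        object.__setattr__(self, "t_zone", t)
        object.__setattr__(self, "follicles", b)
        object.__setattr__(self, "lymphatics", l)


@dataclass(frozen=True)
class CompartmentVolumes:
    """Exclusive absolute volumes (mm^3) and fractions of their sum."""

    absolute: dict  # name -> mm^3
    fractions: dict  # name -> fraction


@dataclass(frozen=True)
class NCRatioMeasurement:
    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float

    @property
    def nuclear_localized(self) -> bool:
        """True when the signal is enriched in the nucleus (ratio > 1)."""
        return self.ratio > 1.0


def exclusive_compartments(masks: CompartmentMasks) -> CompartmentVolumes:
    """Exclusive compartment volumes with overlap subtraction.

    Overlaps are eliminated in the fixed order: lymphatics are subtracted
    from both the T-zone and follicle masks, and the T-zone from the follicle
    mask.  A voxel in both lymphatics and T-zone therefore counts as
    lymphatic only.  Fractions are of the sum of the three exclusive volumes.
    """
    L = masks.lymphatics
    T = masks.t_zone & ~L
    B = masks.follicles & ~L & ~T
    counts = {"t_zone": int(T.sum()), "follicles": int(B.sum()),
              "lymphatics": int(L.sum())}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all compartments empty: fractions undefined")
    absolute = {k: v * masks.voxel_volume / UM3_PER_MM3 for k, v in counts.items()}
    fractions = {k: v / total for k, v in counts.items()}
    return CompartmentVolumes(absolute=absolute, fractions=fractions)


def nc_ratio(nuclear_mask: np.ndarray, cyto_mask: np.ndarray,
             image: np.ndarray) -> NCRatioMeasurement:
    """Nuclear-to-cytoplasmic mean intensity ratio of one cell.

    Masks must be disjoint and nonempty; ratio > 1 flags nuclear enrichment
    (the "equal ratio" reference line is 1).
    """
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cyt = np.asarray(cyto_mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if not nuc.any() or not cyt.any():
        raise ValueError("masks must be nonempty")
    if (nuc & cyt).any():
        raise ValueError("nuclear and cytoplasmic masks overlap")
    n_mean = float(img[nuc].mean())
    c_mean = float(img[cyt].mean())
    if c_mean == 0:
        raise ZeroDivisionError("zero cytoplasmic mean: ratio undefined")
    return NCRatioMeasurement(nuclear_mean=n_mean, cytoplasmic_mean=c_mean,
                              ratio=n_mean / c_mean)


def capsule_thickness(measurements) -> float:
    """Average capsule thickness (um) over >= 3 per-node measurements."""
    m = np.asarray(measurements, dtype=float)
    if len(m) < 3:
        raise ValueError("capsule thickness needs at least 3 measurements")
    return float(m.mean())


def normalize_to_controls(samples, controls) -> np.ndarray:
    """Divide each sample intensity by the mean of the control intensities."""
    c = np.asarray(controls, dtype=float)
    s = np.asarray(samples, dtype=float)
    if len(c) == 0:
        raise ValueError("at least one control required")
    mean = c.mean()
    if mean == 0:
        raise ZeroDivisionError("zero control mean: normalization undefined")
    return s / mean
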