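"""File formats: force-trace CSV, geometry JSON, mask TIFF, spot CSV, SWC traces.

All readers return the package's in-memory types; all physical units follow
the bench conventions (s, uN, mm for compression; um for coordinates and
pixel sizes; nm for fibril traces).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .clonal_clusters import SpotSet
from .fibril_alignment import FibrilTrace
from .mechanics import ForceTrace, PlateGeometry
from .network_gaps import NetworkMask, PoreSizeDistribution

__all__ = [
    "read_force_trace",
    "write_force_trace",
    "read_geometry",
    "write_geometry",
    "read_mask",
    "write_mask",
    "read_spots",
    "write_spots",
    "read_fibrils_swc",
    "write_fibrils_swc",
    "write_distribution",
]


def read_force_trace(path, strain_onset_t: float = 0.0) -> ForceTrace:
    """Read a 2-column relaxation trace CSV with header (t_s, F_uN)."""
    df = pd.read_csv(path)
    return ForceTrace(df["t_s"].to_numpy(), df["F_uN"].to_numpy(),
                      strain_onset_t=strain_onset_t)


def write_force_trace(path, trace: ForceTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "F_uN": trace.F}).to_csv(path, index=False)


_GEO_KEYS = {"h0_mm": "h0", "h_eq_mm": "h_eq", "L_mm": "L",
             "R1_mm": "R1", "R2_mm": "R2", "R3_mm": "R3"}


def read_geometry(path) -> PlateGeometry:
    """Read plate geometry JSON: {h0_mm, h_eq_mm, L_mm, R1_mm, R2_mm, R3_mm}."""
    with open(path) as fh:
        raw = json.load(fh)
    return PlateGeometry(**{v: float(raw[k]) for k, v in _GEO_KEYS.items()})


def write_geometry(path, geom: PlateGeometry) -> None:
    raw = {k: getattr(geom, v) for k, v in _GEO_KEYS.items()}
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)


def read_mask(path, pixel_size: float, z_spacing: float | None = None) -> NetworkMask:
    """Read a single- or multi-page TIFF mask (0 = gap, nonzero = network)."""
    arr = tifffile.imread(path)
    return NetworkMask(arr > 0, pixel_size=pixel_size, z_spacing=z_spacing)


def write_mask(path, mask: NetworkMask) -> None:
    tifffile.imwrite(path, (mask.voxels.astype(np.uint8) * 255))


def read_spots(path, channel: str) -> SpotSet:
    """Read spot coordinates CSV with columns (x_um, y_um, z_um)."""
    df = pd.read_csv(path)
    return SpotSet(channel, df[["x_um", "y_um", "z_um"]].to_numpy())


def write_spots(path, spots: SpotSet) -> None:
    pd.DataFrame(spots.coords, columns=["x_um", "y_um", "z_um"]).to_csv(
        path, index=False)


def read_fibrils_swc(path) -> list[FibrilTrace]:
    """Read SWC-like whitespace traces: columns (id, parent, x_nm, y_nm, z_nm).

    ``parent == -1`` starts a new fibril; subsequent points chain onto the
    previous one.
    """
    fibrils = []
    current: list = []
    label = ""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        pid, parent = fields[0], int(fields[1])
        xyz = [float(v) for v in fields[2:5]]
        if parent == -1:
            if len(current) >= 2:
                fibrils.append(FibrilTrace(np.array(current), id=label))
            current = [xyz]
            label = pid
        else:
            current.append(xyz)
    if len(current) >= 2:
        fibrils.append(FibrilTrace(np.array(current), id=label))
    return fibrils


def write_fibrils_swc(path, fibrils: list[FibrilTrace]) -> None:
    lines = []
    for f in fibrils:
        for i, p in enumerate(f.points):
            parent = -1 if i == 0 else i - 1
            lines.append(f"{f.id or 'f'} {parent} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_distribution(path, dist: PoreSizeDistribution) -> None:
    pd.DataFrame({
        "diameter_um": dist.diameters,
        "area_fraction": dist.area_fraction,
        "weighted_fraction": dist.weighted_fraction,
    }).to_csv(path, index=False)


def dataclass_to_json(path, obj) -> None:
    """Dump any result dataclass to JSON (arrays become lists)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj,
                  fh, default=default, indent=1)
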