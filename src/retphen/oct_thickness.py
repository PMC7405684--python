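"""Retinal layer thicknesses from segmented OCT boundary curves.

Boundary segmentation itself is done upstream (commercial OCT software in
practice, the synthetic generator here); this module only turns named
boundary depth curves into per-layer thicknesses sampled at fixed lateral
distances from the optic disc.

Conventions
-----------
Depth increases away from the vitreous, so at every lateral position the
boundaries must be strictly ordered ILM < RNFGC/IPL < IPL/INL < OPL < ELM
< RPE.  A layer thickness is the depth difference between its lower and
upper bounding curve, measured along the A-scan (depth) axis.  Lateral
positions between grid samples are linearly interpolated.  Thicknesses are
sampled at 100, 200, 300 and 400 um on both sides of the disc center.

The RNFL and the ganglion-cell layer are never separated (their OCT
reflectance profiles are too similar to segment apart) and are carried as
the combined "RNFGC" complex.  The ELM boundary is kept in the data model
for completeness but none of the seven reported layers uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOUNDARY_ORDER",
    "LAYER_BOUNDS",
    "OFFSETS_UM",
    "OctBoundaries",
    "layer_thickness",
    "thickness_profile",
    "animal_profile",
    "axial_resolution_in_diopters",
]

#: Boundary names ordered from vitreous to choroid.
BOUNDARY_ORDER = ("ILM", "RNFGC/IPL", "IPL/INL", "OPL", "ELM", "RPE")

#: Layer name -> (upper boundary, lower boundary).
LAYER_BOUNDS: dict[str, tuple[str, str]] = {
    "total": ("ILM", "RPE"),
    "inner": ("ILM", "OPL"),
    "outer": ("OPL", "RPE"),
    "RNFGC": ("ILM", "RNFGC/IPL"),
    "IPL": ("RNFGC/IPL", "IPL/INL"),
    "INL": ("IPL/INL", "OPL"),
    "RNFGC+IPL": ("ILM", "IPL/INL"),
}

#: Lateral sampling offsets from the disc center, in micrometers.
OFFSETS_UM = (-400.0, -300.0, -200.0, -100.0, 100.0, 200.0, 300.0, 400.0)


class BoundaryOrderError(ValueError):
    """Raised when boundary depth curves cross or touch."""


@dataclass
class OctBoundaries:
    """Named boundary depth curves depth(lateral) in micrometers.

    Parameters
    ----------
    lateral_um
        Monotonically increasing lateral grid, um.
    depths
        Mapping boundary name -> depth array (same length as the grid).
        Must contain every name in :data:`BOUNDARY_ORDER`.
    disc_center_um
        Lateral position of the optic-disc center. Sampling offsets are
        taken relative to this position.
    """

    lateral_um: np.ndarray
    depths: dict[str, np.ndarray] = field(default_factory=dict)
    disc_center_um: float = 0.0

    def __post_init__(self) -> None:
        self.lateral_um = np.asarray(self.lateral_um, dtype=float)
        if self.lateral_um.ndim != 1 or self.lateral_um.size < 2:
            raise ValueError("lateral grid must be 1-D with >= 2 samples")
        if np.any(np.diff(self.lateral_um) <= 0):
            raise ValueError("lateral grid must be strictly increasing")
        missing = [b for b in BOUNDARY_ORDER if b not in self.depths]
        if missing:
            raise ValueError(f"missing boundaries: {missing}")
        self.depths = {k: np.asarray(v, dtype=float) for k, v in self.depths.items()}
        for name, d in self.depths.items():
            if d.shape != self.lateral_um.shape:
                raise ValueError(f"boundary {name!r} does not match the lateral grid")
        self.validate_ordering()

    def validate_ordering(self) -> None:
        """Check strict vitreous-to-choroid ordering at every grid point."""
        for upper, lower in zip(BOUNDARY_ORDER[:-1], BOUNDARY_ORDER[1:]):
            if not np.all(self.depths[upper] < self.depths[lower]):
                raise BoundaryOrderError(
                    f"boundaries {upper!r} and {lower!r} cross or touch"
                )

    def depth_at(self, name: str, lateral_um: float) -> float:
        """Linearly interpolated depth of one boundary at a lateral position."""
        lo, hi = self.lateral_um[0], self.lateral_um[-1]
        if not lo <= lateral_um <= hi:
            raise ValueError(
                f"lateral position {lateral_um} um outside boundary support "
                f"[{lo}, {hi}] um"
            )
        return float(np.interp(lateral_um, self.lateral_um, self.depths[name]))


def layer_thickness(boundaries: OctBoundaries, layer: str, offset_um: float) -> float:
    """Thickness of one layer at one lateral offset from the disc center.

    ``offset_um`` is signed; its magnitude must be one of 100, 200, 300 or
    400 um (the standard sampling distances).
    """
    if abs(offset_um) not in (100.0, 200.0, 300.0, 400.0):
        raise ValueError("offset magnitude must be one of 100, 200, 300, 400 um")
    try:
        upper, lower = LAYER_BOUNDS[layer]
    except KeyError:
        raise ValueError(f"unknown layer {layer!r}; one of {sorted(LAYER_BOUNDS)}")
    x = boundaries.disc_center_um + offset_um
    du = boundaries.depth_at(upper, x)
    dl = boundaries.depth_at(lower, x)
    if dl <= du:
        raise BoundaryOrderError(
            f"boundary ordering violated for layer {layer!r} at {offset_um} um"
        )
    return dl - du


def thickness_profile(boundaries: OctBoundaries) -> pd.DataFrame:
    """All seven layers at all eight offsets for one eye.

    Returns a tidy frame with columns ``layer``, ``offset_um``,
    ``thickness_um`` (7 x 8 = 56 rows).
    """
    rows = [
        (layer, off, layer_thickness(boundaries, layer, off))
        for layer in LAYER_BOUNDS
        for off in OFFSETS_UM
    ]
    return pd.DataFrame(rows, columns=["layer", "offset_um", "thickness_um"])


def animal_profile(eye_profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-animal profile: mean of the available eyes, cell by cell."""
    if not eye_profiles:
        raise ValueError("no eye profiles given")
    cat = pd.concat(eye_profiles, ignore_index=True)
    out = (
        cat.groupby(["layer", "offset_um"], sort=False, as_index=False)["thickness_um"]
        .mean()
    )
    return out


def axial_resolution_in_diopters(
    resolution_um: float = 80.0, um_per_diopter: float = 6.5
) -> int:
    """Refractive-error equivalent of an axial-length resolution limit.

    In the mouse eye a 5.4-6.5 um change in axial length corresponds to a
    1 dioptre change in refractive error, so an 80 um axial resolution can
    only resolve refractive differences of about 12 D.
    """
    if resolution_um <= 0 or um_per_diopter <= 0:
        raise ValueError("resolution and conversion factor must be positive")
    return int(round(resolution_um / um_per_diopter))
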