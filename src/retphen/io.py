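"""Readers for the on-disk interchange formats.

Counterparts of the writers in :mod:`retphen.synthetic_data`: vessel
datasets (16-bit TIFF + JSON with centerlines and reference circle), ERG
sweep tables (CSV + JSON sidecar) and OCT boundary curves (JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .erg_waveform import ErgTrace, average_sweeps
from .oct_thickness import OctBoundaries
from .vessel_caliber import ReferenceCircle, VesselTrace

__all__ = ["read_vessel_dataset", "read_erg_trace", "read_erg_directory", "read_oct_boundaries"]


def read_vessel_dataset(
    json_path: str | Path,
) -> tuple[np.ndarray, list[VesselTrace], ReferenceCircle]:
    """Load a vessel dataset: image, traces and reference circle."""
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    img = tifffile.imread(json_path.parent / meta["image"]).astype(float)
    scale = float(meta["pixel_scale_um_per_px"])
    rc = meta["reference_circle"]
    circle = ReferenceCircle(
        center_px=tuple(rc["center_px"]),
        diameter_um=float(rc["diameter_um"]),
        pixel_scale_um_per_px=scale,
    )
    traces = [
        VesselTrace(
            id=v["id"],
            vessel_class=v["class"],
            points=np.asarray(v["points_px"], dtype=float),
            source="manual",
        )
        for v in meta["vessels"]
    ]
    return img, traces, circle


def read_erg_trace(csv_path: str | Path) -> ErgTrace:
    """Load one sweep table + sidecar and return the sweep-averaged trace."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    sweep_cols = [c for c in df.columns if c.startswith("sweep_")]
    if not sweep_cols:
        raise ValueError(f"{csv_path} has no sweep columns")
    t = df["time_ms"].to_numpy(dtype=float)
    sweeps = [
        ErgTrace(
            time_ms=t,
            voltage_uv=df[c].to_numpy(dtype=float),
            flash_onset_ms=float(meta["flash_onset_ms"]),
            intensity_log=float(meta["intensity_log_cd_s_m2"]),
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
        )
        for c in sweep_cols
    ]
    return average_sweeps(sweeps)


def read_erg_directory(directory: str | Path) -> list[ErgTrace]:
    """Load every sweep CSV in a directory as one intensity series."""
    directory = Path(directory)
    csvs = sorted(directory.glob("*.csv"))
    if not csvs:
        raise FileNotFoundError(f"no sweep CSVs in {directory}")
    return [read_erg_trace(p) for p in csvs]


def read_oct_boundaries(json_path: str | Path) -> OctBoundaries:
    """Load segmented boundary curves from JSON."""
    meta = json.loads(Path(json_path).read_text())
    names = list(meta["boundaries"])
    lat = np.asarray(meta["boundaries"][names[0]]["lateral_um"], dtype=float)
    depths = {}
    for name, rec in meta["boundaries"].items():
        if not np.array_equal(np.asarray(rec["lateral_um"], dtype=float), lat):
            raise ValueError("boundaries use inconsistent lateral grids")
        depths[name] = np.asarray(rec["depth_um"], dtype=float)
    return OctBoundaries(
        lateral_um=lat, depths=depths, disc_center_um=float(meta["disc_center_um"])
    )
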