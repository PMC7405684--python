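"""Ground-truth generators for vessel images, ERG sweeps and OCT geometry.

Every analysis stage in this package is exercised against data with
analytically known answers, because the source study deposits no raw
data.  Three generators emulate the three modalities:

* **Vessel images** — bright vessels of known physical width on a noisy
  background with an optional linear shading gradient.  Rendering uses
  4x supersampled rasterization followed by box downsampling so that
  "true width" is meaningful at subpixel precision.  Cross sections are
  rectangular (sharp-walled) or Gaussian (FWHM = true width).
* **ERG sweeps** — voltage(t) = -P3(t) + B(t) + OP(t) + noise, where P3
  is the Lamb-Pugh activation response, B a log-normal-shaped unimodal
  bump scaled to the Naka-Rushton amplitude at the flash intensity, and
  OP a Gaussian-windowed sinusoid (Gabor packet) centered on the B-wave
  rising phase.  Noise is white Gaussian per sweep.  The B template is a
  smooth positive low-frequency bump chosen for spectral separation from
  the OP band; it claims no physiological fidelity.
* **OCT boundaries** — smooth polynomial depth curves per boundary with
  closed-form layer thicknesses at the eight standard lateral offsets.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .erg_waveform import ErgTrace, average_sweeps, lamb_pugh_model, naka_rushton
from .oct_thickness import BOUNDARY_ORDER, OFFSETS_UM, OctBoundaries
from .vessel_caliber import ReferenceCircle, VesselTrace

__all__ = [
    "SyntheticVessel",
    "SyntheticVesselSpec",
    "SyntheticErgSpec",
    "SyntheticOctSpec",
    "generate_vessel_image",
    "generate_erg_sweeps",
    "generate_erg_trace",
    "generate_erg_series",
    "erg_model_voltage",
    "generate_oct_boundaries",
    "random_oct_spec",
    "write_vessel_dataset",
    "write_erg_dataset",
    "write_oct_json",
]

SUPERSAMPLE = 4  # rasterization grid refinement
GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma


# ---------------------------------------------------------------------------
# vessel images
# ---------------------------------------------------------------------------


@dataclass
class SyntheticVessel:
    points_px: np.ndarray  # (N, 2) centerline polyline, x right / y down
    true_width_um: float
    vessel_class: str = "arteriole"
    peak_brightness: float = 80.0  # added above background
    profile_shape: str = "rectangular"  # "rectangular" | "gaussian"

    def __post_init__(self) -> None:
        self.points_px = np.asarray(self.points_px, dtype=float)
        if self.true_width_um <= 0:
            raise ValueError("true width must be positive")
        if self.profile_shape not in ("rectangular", "gaussian"):
            raise ValueError("profile shape must be rectangular or gaussian")


@dataclass
class SyntheticVesselSpec:
    image_size: tuple[int, int] = (256, 256)  # (H, W) pixels
    pixel_scale_um_per_px: float = 2.0
    vessels: list[SyntheticVessel] = field(default_factory=list)
    background_level: float = 100.0
    background_gradient: float = 0.0  # units per px along x
    noise_sd: float = 0.0
    reference_circle_diameter_um: float = 1720.0  # P6 convention
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        h, w = self.image_size
        for v in self.vessels:
            p = v.points_px
            if np.any(p[:, 0] < 0) or np.any(p[:, 0] > w - 1) or np.any(
                p[:, 1] < 0
            ) or np.any(p[:, 1] > h - 1):
                raise ValueError("vessel polyline leaves the image bounds")

    @property
    def reference_circle(self) -> ReferenceCircle:
        h, w = self.image_size
        return ReferenceCircle(
            center_px=((w - 1) / 2.0, (h - 1) / 2.0),
            diameter_um=self.reference_circle_diameter_um,
            pixel_scale_um_per_px=self.pixel_scale_um_per_px,
        )


def _segment_distance_field(
    xs: np.ndarray, ys: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Distance from grid points (xs, ys broadcastable) to segment p0-p1."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.hypot(xs - p0[0], ys - p0[1])
    t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xs - (p0[0] + t * d[0]), ys - (p0[1] + t * d[1]))


def _polyline_distance(
    xs: np.ndarray, ys: np.ndarray, pts: np.ndarray, reach_px: float
) -> np.ndarray:
    """Min distance to a polyline, computed segment-wise within bounding boxes."""
    dist = np.full(np.broadcast_shapes(xs.shape, ys.shape), np.inf)
    X = np.broadcast_to(xs, dist.shape)
    Y = np.broadcast_to(ys, dist.shape)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        x_lo = min(p0[0], p1[0]) - reach_px
        x_hi = max(p0[0], p1[0]) + reach_px
        y_lo = min(p0[1], p1[1]) - reach_px
        y_hi = max(p0[1], p1[1]) + reach_px
        sel = (X >= x_lo) & (X <= x_hi) & (Y >= y_lo) & (Y <= y_hi)
        if not sel.any():
            continue
        d = _segment_distance_field(X[sel], Y[sel], p0, p1)
        dist[sel] = np.minimum(dist[sel], d)
    return dist


def generate_vessel_image(
    spec: SyntheticVesselSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the vessel image and return it with a ground-truth table.

    The image is float64, shape ``spec.image_size``; brightness =
    background + gradient * x + sum of vessel cross sections + Gaussian
    noise.  The ground-truth frame has one row per vessel with columns
    ``vessel_id, vessel_class, true_width_um, true_width_px,
    profile_shape``.  Identical specs and seeds give identical images.
    """
    h, w = spec.image_size
    ss = SUPERSAMPLE
    # supersampled grid of subpixel centers, in output-pixel coordinates
    xs = (np.arange(w * ss) + 0.5) / ss - 0.5
    ys = (np.arange(h * ss) + 0.5) / ss - 0.5
    X = xs[None, :]
    Y = ys[:, None]
    img_ss = np.full((h * ss, w * ss), float(spec.background_level))
    img_ss += spec.background_gradient * X
    rows = []
    for k, v in enumerate(spec.vessels):
        width_px = v.true_width_um / spec.pixel_scale_um_per_px
        if v.profile_shape == "rectangular":
            reach = width_px / 2.0 + 2.0
        else:
            sigma = width_px / GAUSS_FWHM_FACTOR
            reach = 4.0 * sigma + 2.0
        d = _polyline_distance(X, Y, v.points_px, reach)
        if v.profile_shape == "rectangular":
            img_ss += v.peak_brightness * (d <= width_px / 2.0)
        else:
            img_ss += v.peak_brightness * np.exp(-0.5 * (d / sigma) ** 2)
        rows.append(
            dict(
                vessel_id=f"v{k:02d}",
                vessel_class=v.vessel_class,
                true_width_um=v.true_width_um,
                true_width_px=width_px,
                profile_shape=v.profile_shape,
            )
        )
    img = img_ss.reshape(h, ss, w, ss).mean(axis=(1, 3))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img, pd.DataFrame(rows)


def vessel_traces(spec: SyntheticVesselSpec) -> list[VesselTrace]:
    """The generator's centerlines as analysis-ready traces."""
    return [
        VesselTrace(
            id=f"v{k:02d}",
            vessel_class=v.vessel_class,
            points=v.points_px,
            source="synthetic",
        )
        for k, v in enumerate(spec.vessels)
    ]


# ---------------------------------------------------------------------------
# ERG waveforms
# ---------------------------------------------------------------------------


@dataclass
class SyntheticErgSpec:
    """Composition parameters of the synthetic flash response.

    Amplitude parameters mirror the analysis-side models: (R_max, t_c,
    t_d) drive the Lamb-Pugh P3 component, (Vmax, K, n) the Naka-Rushton
    scaling of the B-wave bump.  ``k_linear`` is in linear cd.s/m^2.
    """

    intensities_log: tuple[float, ...] = tuple(
        round(-4.7 + 0.3 * k, 1) for k in range(20)
    )
    sampling_rate_hz: float = 2000.0
    flash_onset_ms: float = 60.0
    duration_ms: float = 400.0
    r_max_uv: float = 300.0
    tc_ms: float = 18.0
    td_ms: float = 4.0
    vmax_uv: float = 400.0
    k_linear: float = 0.01
    n_exponent: float = 1.0
    b_peak_ms: float = 60.0  # B-template peak time post flash
    b_width_ms: float = 60.0  # B-template approximate FWHM
    op_freq_hz: float = 120.0
    op_envelope_ms: float = 10.0  # Gaussian envelope sigma
    op_pp_uv: float = 40.0  # peak-to-peak packet amplitude
    noise_sd_uv: float = 0.0
    n_sweeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.r_max_uv, self.vmax_uv, self.k_linear) < 0:
            raise ValueError("amplitude parameters must be non-negative")
        if self.tc_ms <= 0 or self.td_ms < 0:
            raise ValueError("tc must be positive and td non-negative")
        if self.noise_sd_uv < 0 or self.n_sweeps < 1:
            raise ValueError("invalid noise/sweep settings")
        if self.flash_onset_ms < 50.0:
            raise ValueError("need >= 50 ms of prestimulus baseline")


def _b_template(t_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak log-normal-shaped bump, zero for t <= 0."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    m = t > 0
    s = width_ms / (GAUSS_FWHM_FACTOR * peak_ms)  # small-s FWHM matching
    out[m] = np.exp(-0.5 * (np.log(t[m] / peak_ms) / s) ** 2)
    return out


def _op_packet(
    t_ms: np.ndarray, center_ms: float, freq_hz: float, sigma_ms: float, pp_uv: float
) -> np.ndarray:
    """Gabor packet: Gaussian-windowed sinusoid, peak-to-peak pp_uv."""
    t = np.asarray(t_ms, dtype=float)
    return (
        0.5
        * pp_uv
        * np.exp(-0.5 * ((t - center_ms) / sigma_ms) ** 2)
        * np.sin(2.0 * np.pi * freq_hz * (t - center_ms) / 1000.0)
    )


def erg_model_voltage(spec: SyntheticErgSpec, intensity_log: float) -> np.ndarray:
    """Noiseless composite voltage on the spec's time grid (uV)."""
    t = erg_time_grid(spec)
    tp = t - spec.flash_onset_ms  # time from flash onset
    ilin = 10.0**intensity_log
    p3 = lamb_pugh_model(tp, ilin, spec.r_max_uv, spec.tc_ms, spec.td_ms)
    b_amp = float(
        naka_rushton(np.asarray([ilin]), spec.vmax_uv, spec.k_linear, spec.n_exponent)[0]
    )
    b = b_amp * _b_template(tp, spec.b_peak_ms, spec.b_width_ms)
    op_center = 0.6 * spec.b_peak_ms  # on the B-wave rising phase
    op = _op_packet(tp, op_center, spec.op_freq_hz, spec.op_envelope_ms, spec.op_pp_uv)
    return -p3 + b + op


def erg_time_grid(spec: SyntheticErgSpec) -> np.ndarray:
    dt = 1000.0 / spec.sampling_rate_hz
    n = int(round(spec.duration_ms / dt))
    return np.arange(n) * dt


def generate_erg_sweeps(
    spec: SyntheticErgSpec, intensity_log: float
) -> list[ErgTrace]:
    """n_sweeps single-flash sweeps at one intensity, with seeded noise."""
    if not any(abs(intensity_log - i) < 1e-9 for i in spec.intensities_log):
        raise ValueError(f"intensity {intensity_log} not in the spec's protocol")
    t = erg_time_grid(spec)
    clean = erg_model_voltage(spec, intensity_log)
    idx = int(
        np.argmin([abs(intensity_log - i) for i in spec.intensities_log])
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
    sweeps = []
    for _ in range(spec.n_sweeps):
        v = clean.copy()
        if spec.noise_sd_uv > 0:
            v = v + rng.normal(0.0, spec.noise_sd_uv, size=v.shape)
        sweeps.append(
            ErgTrace(
                time_ms=t,
                voltage_uv=v,
                flash_onset_ms=spec.flash_onset_ms,
                intensity_log=intensity_log,
                sampling_rate_hz=spec.sampling_rate_hz,
                n_sweeps_averaged=1,
            )
        )
    return sweeps


def generate_erg_trace(spec: SyntheticErgSpec, intensity_log: float) -> ErgTrace:
    """Sweep-averaged trace at one intensity."""
    return average_sweeps(generate_erg_sweeps(spec, intensity_log))


def generate_erg_series(spec: SyntheticErgSpec) -> list[ErgTrace]:
    """One averaged trace per protocol intensity."""
    return [generate_erg_trace(spec, i) for i in spec.intensities_log]


# ---------------------------------------------------------------------------
# OCT geometry
# ---------------------------------------------------------------------------


@dataclass
class SyntheticOctSpec:
    """Polynomial boundary depth curves with closed-form thicknesses.

    ``boundary_poly_um`` maps each boundary name to ascending polynomial
    coefficients [c0, c1, c2, ...] of depth(u) in um, where u is the
    lateral position relative to the disc center in mm (millimeters keep
    the higher-order coefficients of order one).  Boundaries must not
    cross anywhere on the lateral grid.
    """

    lateral_extent_um: float = 1200.0  # half-extent each side of the disc
    grid_step_um: float = 10.0
    disc_center_um: float = 0.0
    boundary_poly_um: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "ILM": (0.0,),
            "RNFGC/IPL": (35.0,),
            "IPL/INL": (85.0,),
            "OPL": (120.0,),
            "ELM": (190.0,),
            "RPE": (220.0,),
        }
    )
    seed: int = 0

    def depth_fn(self, name: str, lateral_um: np.ndarray) -> np.ndarray:
        u_mm = (np.asarray(lateral_um, dtype=float) - self.disc_center_um) / 1000.0
        coeffs = self.boundary_poly_um[name]
        return np.polynomial.polynomial.polyval(u_mm, np.asarray(coeffs, float))


def generate_oct_boundaries(
    spec: SyntheticOctSpec,
) -> tuple[OctBoundaries, pd.DataFrame]:
    """Evaluate the boundary curves and tabulate analytic thicknesses.

    Returns the sampled boundaries plus a ground-truth table of the
    seven layer thicknesses at the eight standard offsets, computed
    directly from the depth polynomials (not from the sampled grid).
    Crossing boundaries are rejected.
    """
    lat = np.arange(
        spec.disc_center_um - spec.lateral_extent_um,
        spec.disc_center_um + spec.lateral_extent_um + spec.grid_step_um / 2,
        spec.grid_step_um,
    )
    depths = {b: spec.depth_fn(b, lat) for b in BOUNDARY_ORDER}
    boundaries = OctBoundaries(
        lateral_um=lat, depths=depths, disc_center_um=spec.disc_center_um
    )  # raises BoundaryOrderError on crossing curves
    from .oct_thickness import LAYER_BOUNDS

    rows = []
    for layer, (upper, lower) in LAYER_BOUNDS.items():
        for off in OFFSETS_UM:
            x = spec.disc_center_um + off
            thick = float(spec.depth_fn(lower, x) - spec.depth_fn(upper, x))
            rows.append(dict(layer=layer, offset_um=off, thickness_um=thick))
    return boundaries, pd.DataFrame(rows)


def random_oct_spec(seed: int, bump_fraction: float = 0.4) -> SyntheticOctSpec:
    """Random smooth non-crossing geometry for property testing.

    Boundary constants are strictly-increasing random depths; each curve
    gets random linear/quadratic terms bounded so perturbations never
    exceed ``bump_fraction`` of the smallest inter-boundary gap over the
    lateral extent, which guarantees ordering.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(15.0, 60.0, size=len(BOUNDARY_ORDER) - 1)
    consts = np.concatenate([[rng.uniform(-20, 20)], gaps]).cumsum()
    extent_mm = 1.2
    min_gap = float(gaps.min())
    # |c1*u + c2*u^2| <= (|c1| + |c2|*extent)*extent; budget half the bound each
    amp = bump_fraction * min_gap / 2.0
    poly = {}
    for name, c0 in zip(BOUNDARY_ORDER, consts):
        c1 = rng.uniform(-1, 1) * amp / extent_mm
        c2 = rng.uniform(-1, 1) * amp / extent_mm**2
        poly[name] = (float(c0), float(c1), float(c2))
    return SyntheticOctSpec(boundary_poly_um=poly, seed=seed)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def write_vessel_dataset(
    spec: SyntheticVesselSpec, out_dir: str | Path, stem: str = "retina"
) -> Path:
    """Write ``<stem>.tif`` (16-bit grayscale) and ``<stem>.json``.

    The JSON carries the centerlines, true widths, pixel scale, reference
    circle and the image filename; returns the JSON path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img, truth = generate_vessel_image(spec)
    img16 = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    tifffile.imwrite(out_dir / f"{stem}.tif", img16)
    circle = spec.reference_circle
    payload = {
        "image": f"{stem}.tif",
        "pixel_scale_um_per_px": spec.pixel_scale_um_per_px,
        "reference_circle": {
            "center_px": list(circle.center_px),
            "diameter_um": circle.diameter_um,
        },
        "vessels": [
            {
                "id": row.vessel_id,
                "class": row.vessel_class,
                "points_px": spec.vessels[k].points_px.tolist(),
                "true_width_um": row.true_width_um,
            }
            for k, row in enumerate(truth.itertuples())
        ],
    }
    path = out_dir / f"{stem}.json"
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_erg_dataset(spec: SyntheticErgSpec, out_dir: str | Path) -> list[Path]:
    """Write one sweep CSV + JSON sidecar per protocol intensity.

    CSV header is ``time_ms,sweep_001,...``; the sidecar carries
    ``intensity_log_cd_s_m2``, ``flash_onset_ms`` and ``sampling_rate_hz``.
    Returns the CSV paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, intensity in enumerate(spec.intensities_log):
        sweeps = generate_erg_sweeps(spec, intensity)
        df = pd.DataFrame({"time_ms": sweeps[0].time_ms})
        for k, s in enumerate(sweeps, start=1):
            df[f"sweep_{k:03d}"] = s.voltage_uv
        stem = f"flash_{idx:02d}"
        csv_path = out_dir / f"{stem}.csv"
        df.to_csv(csv_path, index=False)
        (out_dir / f"{stem}.json").write_text(
            json.dumps(
                {
                    "intensity_log_cd_s_m2": intensity,
                    "flash_onset_ms": spec.flash_onset_ms,
                    "sampling_rate_hz": spec.sampling_rate_hz,
                },
                indent=1,
            )
        )
        paths.append(csv_path)
    return paths


def write_oct_json(boundaries: OctBoundaries, path: str | Path) -> Path:
    """Write boundary curves as JSON (name -> lateral/depth arrays)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "disc_center_um": boundaries.disc_center_um,
        "boundaries": {
            name: {
                "lateral_um": boundaries.lateral_um.tolist(),
                "depth_um": boundaries.depths[name].tolist(),
            }
            for name in BOUNDARY_ORDER
        },
    }
    path.write_text(json.dumps(payload))
    return path
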