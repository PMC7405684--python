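"""Vessel caliber from traced centerlines on flat-mount images.

Implements a hybrid manual/automatic diameter measurement for retinal
flat-mount vasculature: vessels are traced by hand (or synthesized) as
centerline polylines; the algorithm thins each trace to a single-pixel
chain, thickens it to a generous mask, rescales image brightness from the
two modes of the under-mask histogram, samples brightness profiles
perpendicular to the local tangent at every chain pixel, pools all
profiles whose chain point lies inside a fixed reference circle into an
ensemble average, and reads the vessel width at the mid-brightness level
of that ensemble.  Pooling many perpendicular slices dilutes the random
effect of side branches crossing individual slices.

Also provides per-retina/per-mouse summaries (mean width and count per
vessel class) and two conventional vasculature metrics, arc-over-chord
tortuosity and box-counting fractal dimension.  The latter two are
standard formulations, not re-implementations of any particular
commercial grader's (e.g. SIVA's) unpublished formulas, and will not
numerically match such tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "VesselTrace",
    "ReferenceCircle",
    "WidthResult",
    "VesselConfig",
    "VesselMeasurementError",
    "thin_centerline",
    "dilate_centerline",
    "normalize_brightness",
    "estimate_tangents",
    "extract_perpendicular_slices",
    "clip_to_circle",
    "ensemble_average",
    "width_at_midbrightness",
    "measure_vessel",
    "measure_retina",
    "summarize_retina",
    "summarize_mouse",
    "tortuosity",
    "fractal_dimension",
]

VESSEL_CLASSES = ("arteriole", "venule")


class VesselMeasurementError(RuntimeError):
    """A vessel could not be measured; carries the vessel id."""

    def __init__(self, vessel_id: str, message: str):
        super().__init__(f"vessel {vessel_id!r}: {message}")
        self.vessel_id = vessel_id


@dataclass
class VesselTrace:
    """A manually or synthetically traced vessel centerline.

    ``points`` is an ordered (N, 2) polyline in pixel coordinates
    (x right, y down, origin at the top-left pixel center), covering only
    the main branch central to any major bifurcation.
    """

    id: str
    vessel_class: str  # "arteriole" | "venule"
    points: np.ndarray
    source: str = "manual"  # "manual" | "synthetic"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"vessel class must be one of {VESSEL_CLASSES}")
        if len(self.points) < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("trace has repeated consecutive points")


@dataclass(frozen=True)
class ReferenceCircle:
    """Fixed-diameter circle within which slices are pooled.

    The study convention uses 1.72 mm diameter at P6 and 2.05 mm at P9,
    visually centered on the retina.
    """

    center_px: tuple[float, float]  # (x, y)
    diameter_um: float
    pixel_scale_um_per_px: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel scale must be positive")

    @property
    def radius_px(self) -> float:
        return self.diameter_um / 2.0 / self.pixel_scale_um_per_px


@dataclass
class WidthResult:
    vessel_id: str
    ensemble_profile: np.ndarray  # brightness vs signed offset
    offsets_px: np.ndarray  # signed perpendicular offsets, px
    n_slices: int
    width_px: float
    width_um: float
    mid_brightness_level: float


@dataclass(frozen=True)
class VesselConfig:
    """Tunables of the caliber pipeline (all lengths in pixels).

    ``nominal_radius_px`` is the expected vessel half-width; the thickened
    mask radius defaults to twice it ("generously cover") and the slice
    half-length to three times it.
    """

    nominal_radius_px: float = 8.0
    dilate_radius_px: float | None = None  # default: 2 * nominal radius
    half_length_px: float | None = None  # default: 3 * nominal radius
    step_px: float = 0.25  # perpendicular sampling step
    tangent_half_window_px: int = 7  # tangent-filter half-window
    min_slices: int = 20  # fewer pooled slices -> unreliable width
    hist_bins: int = 64  # brightness-histogram resolution
    dark_vessels: bool = False  # invert polarity for bright-field images
    background_fraction: float = 0.2  # outer profile fraction used as background

    @property
    def effective_dilate_radius_px(self) -> float:
        return (
            self.dilate_radius_px
            if self.dilate_radius_px is not None
            else 2.0 * self.nominal_radius_px
        )

    @property
    def effective_half_length_px(self) -> float:
        return (
            self.half_length_px
            if self.half_length_px is not None
            else 3.0 * self.nominal_radius_px
        )


# ---------------------------------------------------------------------------
# centerline geometry
# ---------------------------------------------------------------------------


def thin_centerline(trace: VesselTrace) -> np.ndarray:
    """Rasterize the polyline to a single-pixel 8-connected ordered chain.

    The polyline is sampled densely (0.25-px arc steps) and each sample
    rounded to its pixel, so every chain pixel lies within sqrt(2)/2 px of
    the continuous polyline.  Returns an (M, 2) integer array of unique
    (x, y) pixels following the polyline, endpoints preserved.
    """
    pts = trace.points
    if np.all(np.rint(pts) == np.rint(pts[0])):
        raise VesselMeasurementError(trace.id, "degenerate trace (all points identical)")
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    su = np.arange(0.0, s[-1], 0.25)
    su = np.append(su, s[-1])  # keep the exact endpoint
    dense_x = np.interp(su, s, pts[:, 0])
    dense_y = np.interp(su, s, pts[:, 1])
    pix = np.column_stack([np.rint(dense_x), np.rint(dense_y)]).astype(int)
    seen: set[tuple[int, int]] = set()
    out = []
    for p in map(tuple, pix):
        if p not in seen:
            seen.add(p)
            out.append(p)
    return np.asarray(out, dtype=int)


def dilate_centerline(
    chain: np.ndarray, radius_px: float, image_shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of all pixels within ``radius_px`` of the chain."""
    h, w = image_shape
    on = np.zeros((h, w), dtype=bool)
    xs = np.clip(chain[:, 0], 0, w - 1)
    ys = np.clip(chain[:, 1], 0, h - 1)
    on[ys, xs] = True
    if radius_px <= 0:
        return on
    dist = ndimage.distance_transform_edt(~on)
    return dist <= radius_px


def estimate_tangents(chain: np.ndarray, half_window_px: int = 7) -> np.ndarray:
    """Unit tangent at every chain point.

    The chain is resampled uniformly in arc length (1-px spacing) and each
    coordinate differentiated with a local-quadratic (Savitzky-Golay)
    filter of window ``2 * half_window_px + 1``.  Arc-length resampling
    removes the parametrization asymmetry of the pixel staircase (diagonal
    steps are sqrt(2) long) and the quadratic fit tracks curvature, so the
    estimate stays accurate at the chain ends where the fit is one-sided.
    """
    if len(chain) < 2:
        raise ValueError("chain too short for tangents")
    pts = chain.astype(float)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    su = np.arange(0.0, s[-1] + 1e-9, 1.0)
    ru = np.column_stack([np.interp(su, s, pts[:, 0]), np.interp(su, s, pts[:, 1])])
    size = 2 * half_window_px + 1
    if size >= len(ru) or half_window_px <= 0:
        d = np.gradient(ru, axis=0)
    else:
        d = np.column_stack(
            [
                signal.savgol_filter(ru[:, k], size, polyorder=2, deriv=1, mode="interp")
                for k in (0, 1)
            ]
        )
    norms = np.linalg.norm(d, axis=1)
    norms[norms == 0] = 1.0
    d = d / norms[:, None]
    idx = np.clip(np.searchsorted(su, s), 0, len(su) - 1)
    return d[idx]


def clip_to_circle(chain: np.ndarray, circle: ReferenceCircle) -> np.ndarray:
    """Indices of chain points strictly inside the reference circle.

    Points exactly on the circle are excluded (a measure-zero tie-break).
    """
    cx, cy = circle.center_px
    d = np.hypot(chain[:, 0] - cx, chain[:, 1] - cy)
    inside = np.flatnonzero(d < circle.radius_px)
    if inside.size == 0:
        raise ValueError("vessel outside reference circle")
    return inside


# ---------------------------------------------------------------------------
# brightness normalization and slicing
# ---------------------------------------------------------------------------


def normalize_brightness(
    image: np.ndarray, thick_mask: np.ndarray, config: VesselConfig = VesselConfig()
) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine brightness rescale from the under-mask histogram modes.

    The histogram of pixels under the thickened mask is bimodal for a
    vessel on a background: the lower mode is the background level, the
    upper mode the vessel level (for dark-vessel images the image is
    inverted first).  Each mode is refined to the mean of the pixels in
    its histogram bin, then the image is mapped affinely so background -> 0
    and vessel -> 1.  Returns the rescaled image and the (background,
    vessel) levels on the input scale.
    """
    if not np.any(thick_mask):
        raise ValueError("empty mask")
    img = np.asarray(image, dtype=float)
    if config.dark_vessels:
        img = -img
    vals = img[thick_mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        raise ValueError("no vessel contrast (constant brightness under mask)")
    counts, edges = np.histogram(vals, bins=config.hist_bins, range=(vmin, vmax))
    # light smoothing so sampling noise does not fragment the modes
    sm = np.convolve(counts.astype(float), [0.25, 0.5, 0.25], mode="same")
    peaks = [
        k
        for k in range(len(sm))
        if sm[k] > 0
        and (k == 0 or sm[k] >= sm[k - 1])
        and (k == len(sm) - 1 or sm[k] >= sm[k + 1])
    ]
    # ties within plateaus broken toward the extremes
    if len(peaks) < 2 or peaks[0] == peaks[-1]:
        raise ValueError("no vessel contrast (under-mask histogram is unimodal)")
    lo_bin, hi_bin = peaks[0], peaks[-1]

    def _bin_mean(k: int) -> float:
        lo, hi = edges[k], edges[k + 1]
        sel = (vals >= lo) & (vals <= hi if k == len(counts) - 1 else vals < hi)
        return float(vals[sel].mean())

    background = _bin_mean(lo_bin)
    vessel = _bin_mean(hi_bin)
    if vessel <= background:
        raise ValueError("no vessel contrast (modes not separated)")
    rescaled = (img - background) / (vessel - background)
    if config.dark_vessels:
        return rescaled, (-background, -vessel)
    return rescaled, (background, vessel)


def extract_perpendicular_slices(
    image: np.ndarray,
    chain: np.ndarray,
    tangents: np.ndarray,
    half_length_px: float,
    step_px: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brightness profiles along the normal through each chain pixel.

    Profiles are sampled at ``step_px`` steps over signed offsets
    [-half_length, +half_length] with bilinear interpolation; profiles
    whose support leaves the image are dropped.

    Returns ``(profiles, offsets_px, kept_indices)`` where ``profiles``
    has one row per kept chain point.
    """
    n_half = int(round(half_length_px / step_px))
    offsets = np.arange(-n_half, n_half + 1) * step_px
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    # sample positions: (n_points, n_offsets)
    xs = chain[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    ys = chain[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    h, w = image.shape
    ok = np.all((xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1), axis=1)
    kept = np.flatnonzero(ok)
    if kept.size == 0:
        raise ValueError("all perpendicular slices leave the image")
    prof = ndimage.map_coordinates(
        np.asarray(image, dtype=float),
        np.stack([ys[kept].ravel(), xs[kept].ravel()]),
        order=1,
        mode="nearest",
    ).reshape(kept.size, offsets.size)
    return prof, offsets, kept


def ensemble_average(profiles: np.ndarray, min_slices: int = 20) -> np.ndarray:
    """Pointwise mean profile across slices; the width's central tendency."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] < min_slices:
        raise ValueError(
            f"only {profiles.shape[0]} slices pooled; {min_slices} required"
        )
    return profiles.mean(axis=0)


# ---------------------------------------------------------------------------
# width extraction
# ---------------------------------------------------------------------------


def width_at_midbrightness(
    ensemble_profile: np.ndarray,
    offsets_px: np.ndarray,
    pixel_scale_um_per_px: float,
    vessel_id: str = "",
    n_slices: int = 0,
    background_fraction: float = 0.2,
) -> WidthResult:
    """Full width of the ensemble profile at the mid-brightness level.

    The local background is the mean of the outermost
    ``background_fraction`` of offsets (split between the two tails), the
    peak is the profile maximum, and the mid-brightness level is their
    midpoint — a definition invariant to affine intensity changes and
    meaningful for both plateau-like and Gaussian-like cross sections.
    The width is the distance between the linearly interpolated crossings
    of that level flanking the lobe that contains the global peak.
    """
    p = np.asarray(ensemble_profile, dtype=float)
    x = np.asarray(offsets_px, dtype=float)
    if p.shape != x.shape or p.size < 5:
        raise ValueError("profile and offsets must match and have >= 5 samples")
    n_tail = max(int(round(p.size * background_fraction / 2)), 1)
    background = float(np.mean(np.concatenate([p[:n_tail], p[-n_tail:]])))
    i_peak = int(np.argmax(p))
    peak = float(p[i_peak])
    if peak <= background:
        raise ValueError("profile has no central lobe above background")
    level = (background + peak) / 2.0

    above = p >= level
    # count lobes (maximal runs above the level)
    edges = np.flatnonzero(np.diff(above.astype(int)))
    n_lobes = int(above[0]) + np.sum(np.diff(above.astype(int)) == 1)
    if n_lobes > 1:
        warnings.warn(
            f"profile has {n_lobes} lobes above mid-brightness; using the lobe "
            "containing the global peak",
            stacklevel=2,
        )
    # walk outward from the peak to the first crossings
    i = i_peak
    while i > 0 and above[i - 1]:
        i -= 1
    j = i_peak
    while j < p.size - 1 and above[j + 1]:
        j += 1
    if i == 0 or j == p.size - 1:
        raise ValueError("profile not enclosed: mid-brightness crossing missing on a flank")
    # linear interpolation between the last sample below and first above
    xl = x[i - 1] + (level - p[i - 1]) / (p[i] - p[i - 1]) * (x[i] - x[i - 1])
    xr = x[j] + (level - p[j]) / (p[j + 1] - p[j]) * (x[j + 1] - x[j])
    width_px = float(xr - xl)
    if width_px <= 0:
        raise ValueError("non-positive width; profile malformed")
    return WidthResult(
        vessel_id=vessel_id,
        ensemble_profile=p,
        offsets_px=x,
        n_slices=n_slices,
        width_px=width_px,
        width_um=width_px * pixel_scale_um_per_px,
        mid_brightness_level=level,
    )


def measure_vessel(
    image: np.ndarray,
    trace: VesselTrace,
    circle: ReferenceCircle,
    config: VesselConfig = VesselConfig(),
) -> WidthResult:
    """Full caliber pipeline for one traced vessel.

    thin -> thicken -> brightness-normalize -> tangents -> perpendicular
    slices -> clip to reference circle -> ensemble average ->
    mid-brightness width.  Deterministic; errors carry the vessel id.
    """
    try:
        chain = thin_centerline(trace)
        mask = dilate_centerline(chain, config.effective_dilate_radius_px, image.shape)
        norm_img, _levels = normalize_brightness(image, mask, config)
        tangents = estimate_tangents(chain, config.tangent_half_window_px)
        inside = clip_to_circle(chain, circle)
        profiles, offsets, kept = extract_perpendicular_slices(
            norm_img,
            chain[inside],
            tangents[inside],
            config.effective_half_length_px,
            config.step_px,
        )
        ensemble = ensemble_average(profiles, config.min_slices)
        result = width_at_midbrightness(
            ensemble,
            offsets,
            circle.pixel_scale_um_per_px,
            vessel_id=trace.id,
            n_slices=profiles.shape[0],
            background_fraction=config.background_fraction,
        )
    except VesselMeasurementError:
        raise
    except ValueError as e:
        raise VesselMeasurementError(trace.id, str(e)) from e
    return result


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def measure_retina(
    image: np.ndarray,
    traces: list[VesselTrace],
    circle: ReferenceCircle,
    config: VesselConfig = VesselConfig(),
) -> pd.DataFrame:
    """Per-vessel width table for one retina.

    Columns: ``vessel_id, vessel_class, n_slices, width_px, width_um``.
    """
    rows = []
    for tr in traces:
        res = measure_vessel(image, tr, circle, config)
        rows.append(
            dict(
                vessel_id=tr.id,
                vessel_class=tr.vessel_class,
                n_slices=res.n_slices,
                width_px=res.width_px,
                width_um=res.width_um,
            )
        )
    return pd.DataFrame(
        rows, columns=["vessel_id", "vessel_class", "n_slices", "width_px", "width_um"]
    )


def summarize_retina(per_vessel: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean width and vessel count for one retina.

    A class with no traced vessels gets count 0 and an absent (NaN) mean,
    never 0.
    """
    if per_vessel.empty:
        raise ValueError("no vessels measured")
    rows = []
    for cls in VESSEL_CLASSES:
        sub = per_vessel[per_vessel.vessel_class == cls]
        rows.append(
            dict(
                vessel_class=cls,
                vessel_count=int(len(sub)),
                mean_width_um=float(sub.width_um.mean()) if len(sub) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def summarize_mouse(retina_summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-mouse values: means of the retina-level values when two retinas exist."""
    if not retina_summaries:
        raise ValueError("no retina summaries")
    cat = pd.concat(retina_summaries, ignore_index=True)
    return (
        cat.groupby("vessel_class", sort=False, as_index=False)
        .agg(vessel_count=("vessel_count", "mean"), mean_width_um=("mean_width_um", "mean"))
    )


# ---------------------------------------------------------------------------
# conventional vasculature metrics
# ---------------------------------------------------------------------------


def tortuosity(trace: VesselTrace | np.ndarray) -> float:
    """Arc-length over chord-length tortuosity (>= 1; 1 for a straight vessel)."""
    pts = trace.points if isinstance(trace, VesselTrace) else np.asarray(trace, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0:
        raise ValueError("zero chord length (closed curve)")
    return arc / chord


def fractal_dimension(mask: np.ndarray, min_octaves: int = 4) -> float:
    """Box-counting fractal dimension of a binary vessel mask.

    Least-squares slope of log N(eps) against log(1/eps) over dyadic box
    sizes 1, 2, 4, ... spanning at least ``min_octaves`` octaves.  Box
    sizes are capped at a quarter of the pattern span; larger boxes are
    dominated by boundary quantization and bias the slope.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    span = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    sizes = []
    s = 1
    while s <= span / 4:
        sizes.append(s)
        s *= 2
    if len(sizes) < min_octaves + 1:
        raise ValueError(
            f"mask span {span} px too small for {min_octaves} octaves of box sizes"
        )
    counts = []
    y0, x0 = ys.min(), xs.min()
    for s in sizes:
        boxes = set(zip(((ys - y0) // s).tolist(), ((xs - x0) // s).tolist()))
        counts.append(len(boxes))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(slope)
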