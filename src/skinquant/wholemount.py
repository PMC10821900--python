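"""Whole-mount field quantification.

The measurement chain mirrors how migrated epidermal melanocytes are scored
on whole-mount skin:

1. :func:`detect_follicles` — hair follicles autofluoresce in the red
   channel; background-correct, smooth at follicle scale, threshold and
   count connected components.  The count is the denominator of the
   migration rate.
2. :func:`estimate_bleed` — the same autofluorescence contaminates the
   green channel.  The bleed coefficient (green-vs-red slope over the
   follicle footprint) is fitted robustly so rare GFP spots inside the mask
   cannot bias it.
3. :func:`unmix_green` — scaled subtraction of the red channel "balances"
   the autofluorescence and leaves the nuclear GFP points.
4. :func:`detect_mcsc_spots` — multiscale Laplacian-of-Gaussian blob
   detection of the point-like H2B-GFP nuclei; the count is the numerator.
5. :func:`quantify_field` composes the stages into one per-field record and
   can render a QC overlay for human audit (detections are never edited by
   hand inside the pipeline).

All detection is deterministic given its configuration; this module uses no
random numbers.  Coordinates are 0-based ``(x, y)`` = (column, row).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import theilslopes
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops
from skimage.morphology import disk

from ._errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from .simulate import TwoChannelField

__all__ = [
    "FollicleConfig",
    "BleedConfig",
    "SpotConfig",
    "WholemountConfig",
    "FollicleDetections",
    "UnmixModel",
    "SpotDetections",
    "ImageRecord",
    "FieldQuantification",
    "detect_follicles",
    "estimate_bleed",
    "unmix_green",
    "detect_mcsc_spots",
    "quantify_field",
]


@dataclass(frozen=True)
class FollicleConfig:
    """Follicle (red-channel blob) detection parameters.

    ``threshold_method`` is ``"otsu"`` (default), ``"quantile"`` (fixed
    upper quantile of the smoothed image) or ``"absolute"``.
    """

    background_percentile: float = 25.0
    smooth_sigma_px: float = 4.0
    threshold_method: str = "otsu"
    threshold_quantile: float = 0.95
    threshold_abs: float | None = None
    opening_radius_px: int = 2
    min_area_px: int = 30
    max_area_px: int = 20000
    exclude_border_touching: bool = False
    low_contrast_range: float = 1.0  # 1–99 percentile span below this → flat image
    roi: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1)


@dataclass(frozen=True)
class BleedConfig:
    """Red→green bleed-through (crosstalk) estimation parameters."""

    method: str = "theil_sen"  # or "lad"
    max_pixels: int = 1000
    min_pixels: int = 100
    mask_dilation_px: int = 3


@dataclass(frozen=True)
class SpotConfig:
    """Point-signal (GFP nucleus) detection parameters.

    The detector takes the maximum scale-normalised negative LoG response
    over ``n_sigma`` scales in ``[min_sigma_px, max_sigma_px]`` and keeps
    local maxima above ``k_mad`` robust standard deviations
    (1.4826 x MAD) of the response, with non-maximum suppression at
    ``min_separation_px`` (brighter peak wins; ties broken row-major, i.e.
    lexicographic (y, x)).
    """

    min_sigma_px: float = 1.0
    max_sigma_px: float = 4.0
    n_sigma: int = 4
    threshold_mode: str = "relative"  # or "absolute"
    k_mad: float = 5.0
    threshold_abs: float | None = None
    min_separation_px: float = 8.0
    subpixel: bool = True


@dataclass(frozen=True)
class WholemountConfig:
    follicle: FollicleConfig = FollicleConfig()
    bleed: BleedConfig = BleedConfig()
    spot: SpotConfig = SpotConfig()


@dataclass
class FollicleDetections:
    """Connected-component follicle detections on one field."""

    centroids: list[tuple[float, float]]
    equivalent_radii_px: list[float]
    count: int
    field_id: str = ""
    flags: list[str] = dc_field(default_factory=list)
    mask: np.ndarray | None = None  # accepted-component footprint

    def __post_init__(self) -> None:
        if self.count != len(self.centroids):
            raise ValidationError("count must equal len(centroids)")


@dataclass
class UnmixModel:
    """Fitted bleed model: green ~ alpha * red + intercept."""

    alpha: float
    intercept: float
    n_pixels_used: int
    fit_diagnostic: float  # robust residual scale (1.4826 x MAD)


@dataclass
class SpotDetections:
    centroids: list[tuple[float, float]]
    peak_intensities: list[float]
    count: int
    field_id: str = ""
    flags: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count != len(self.centroids):
            raise ValidationError("count must equal len(centroids)")


@dataclass
class ImageRecord:
    """Per-field counts feeding the migration rate (melanocytes / follicles)."""

    field_id: str
    mouse_id: str
    n_follicles: int
    n_mcsc: int

    def __post_init__(self) -> None:
        if self.n_follicles < 0 or self.n_mcsc < 0:
            raise ValidationError("counts must be >= 0")


@dataclass
class FieldQuantification:
    """Full result of :func:`quantify_field`: the record plus diagnostics."""

    record: ImageRecord
    follicles: FollicleDetections
    spots: SpotDetections
    unmix: UnmixModel
    flags: list[str]
    overlay: np.ndarray | None = None


def _as_image(arr: np.ndarray, name: str) -> np.ndarray:
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D array")
    if not np.isfinite(img).all():
        raise ValidationError(f"{name} contains non-finite values")
    if (img < 0).any():
        raise ValidationError(f"{name} contains negative intensities")
    return img


def detect_follicles(red: np.ndarray, config: FollicleConfig | None = None,
                     field_id: str = "") -> FollicleDetections:
    """Count hair follicles from red-channel autofluorescence.

    Pipeline: percentile background subtraction → Gaussian smoothing at
    follicle scale → threshold (Otsu by default) → binary opening →
    connected components → area gate.  Components touching the border are
    kept when their centroid lies inside the field (always true for a
    connected component), unless ``exclude_border_touching`` is set.

    A flat field (1–99 percentile span below ``low_contrast_range``)
    returns zero detections with a ``low_contrast`` flag rather than an
    error.
    """
    cfg = config or FollicleConfig()
    img = _as_image(red, "red")
    if cfg.roi is not None:
        x0, y0, x1, y1 = cfg.roi
        if not (0 <= x0 < x1 <= img.shape[1] and 0 <= y0 < y1 <= img.shape[0]):
            raise ValidationError("config ROI does not fit the image")
        img = img[y0:y1, x0:x1]

    p1, p99 = np.percentile(img, [1.0, 99.0])
    if p99 - p1 < cfg.low_contrast_range:
        return FollicleDetections([], [], 0, field_id, flags=["low_contrast"],
                                  mask=np.zeros(img.shape, dtype=bool))

    bg = np.percentile(img, cfg.background_percentile)
    sm = ndi.gaussian_filter(img - bg, cfg.smooth_sigma_px)
    if cfg.threshold_method == "otsu":
        thr = threshold_otsu(sm)
    elif cfg.threshold_method == "quantile":
        thr = np.quantile(sm, cfg.threshold_quantile)
    elif cfg.threshold_method == "absolute":
        if cfg.threshold_abs is None:
            raise ValidationError("threshold_abs required for absolute mode")
        thr = cfg.threshold_abs
    else:
        raise ValidationError(f"unknown threshold_method {cfg.threshold_method!r}")

    binm = sm > thr
    if cfg.opening_radius_px > 0:
        binm = ndi.binary_opening(binm, structure=disk(cfg.opening_radius_px))
    lbl = label(binm, connectivity=2)

    centroids: list[tuple[float, float]] = []
    radii: list[float] = []
    accepted = np.zeros(img.shape, dtype=bool)
    h, w = img.shape
    for rp in regionprops(lbl):
        if not (cfg.min_area_px <= rp.area <= cfg.max_area_px):
            continue
        if cfg.exclude_border_touching:
            y0b, x0b, y1b, x1b = rp.bbox
            if y0b == 0 or x0b == 0 or y1b == h or x1b == w:
                continue
        cy, cx = rp.centroid
        centroids.append((float(cx), float(cy)))
        radii.append(float(np.sqrt(rp.area / np.pi)))
        accepted[lbl == rp.label] = True

    return FollicleDetections(centroids, radii, len(centroids), field_id,
                              mask=accepted)


def _lad_fit(x: np.ndarray, y: np.ndarray, n_iter: int = 50,
             tol: float = 1e-10) -> tuple[float, float]:
    """Least-absolute-deviation line via iteratively reweighted least squares."""
    a, b = np.polyfit(x, y, 1)
    for _ in range(n_iter):
        r = np.abs(y - a * x - b)
        wgt = 1.0 / np.maximum(r, 1e-8)
        sw = wgt.sum()
        mx, my = (wgt * x).sum() / sw, (wgt * y).sum() / sw
        den = (wgt * (x - mx) ** 2).sum()
        a_new = (wgt * (x - mx) * (y - my)).sum() / den
        b_new = my - a_new * mx
        if abs(a_new - a) < tol and abs(b_new - b) < tol:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return float(a), float(b)


def estimate_bleed(red: np.ndarray, green: np.ndarray, follicle_mask: np.ndarray,
                   config: BleedConfig | None = None) -> UnmixModel:
    """Fit the red→green bleed coefficient over follicle-footprint pixels.

    A robust slope (Theil–Sen by default, LAD optional) of green versus red
    is used so that the occasional GFP spot lying on a follicle does not
    bias the coefficient.  Pixels are subsampled with a deterministic
    stride to at most ``max_pixels``.
    """
    cfg = config or BleedConfig()
    r = _as_image(red, "red")
    g = _as_image(green, "green")
    if r.shape != g.shape or follicle_mask.shape != r.shape:
        raise ValidationError("red, green and follicle_mask shapes must match")
    idx = np.flatnonzero(np.asarray(follicle_mask, dtype=bool).ravel())
    if idx.size < cfg.min_pixels:
        raise InsufficientDataError(
            f"bleed mask holds {idx.size} pixels; need >= {cfg.min_pixels}")
    stride = max(1, idx.size // cfg.max_pixels)
    sel = idx[::stride][:cfg.max_pixels]
    rv, gv = r.ravel()[sel], g.ravel()[sel]
    if np.ptp(rv) == 0:
        raise DegenerateFitError("zero red variance inside the bleed mask")

    if cfg.method == "theil_sen":
        slope, intercept, _, _ = theilslopes(gv, rv)
    elif cfg.method == "lad":
        slope, intercept = _lad_fit(rv, gv)
    else:
        raise ValidationError(f"unknown bleed method {cfg.method!r}")
    slope = max(float(slope), 0.0)
    resid = gv - slope * rv - intercept
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return UnmixModel(alpha=slope, intercept=float(intercept),
                      n_pixels_used=int(sel.size), fit_diagnostic=scale)


def unmix_green(green: np.ndarray, red: np.ndarray,
                model: UnmixModel) -> np.ndarray:
    """Balance green-channel autofluorescence by scaled red subtraction.

    Returns ``max(green - alpha*red - intercept, 0)`` elementwise; on a
    bleed-only field this is zero everywhere and on a field with GFP spots
    it is the pure spot image.
    """
    g = _as_image(green, "green")
    r = _as_image(red, "red")
    if g.shape != r.shape:
        raise ValidationError("green and red shapes must match")
    return np.clip(g - model.alpha * r - model.intercept, 0.0, None)


def _log_filter_norm(sigma: float) -> float:
    """L2 norm of the scale-normalised negative-LoG filter at ``sigma``."""
    n = int(np.ceil(6 * sigma)) * 2 + 1
    impulse = np.zeros((n, n))
    impulse[n // 2, n // 2] = 1.0
    return float(np.sqrt(np.sum((sigma * sigma * ndi.gaussian_laplace(impulse, sigma)) ** 2)))


def detect_mcsc_spots(corrected_green: np.ndarray,
                      config: SpotConfig | None = None,
                      field_id: str = "") -> SpotDetections:
    """Detect point-like H2B-GFP nuclei in the bleed-corrected green channel.

    Multiscale LoG response → local maxima above threshold → non-maximum
    suppression at ``min_separation_px`` → optional sub-pixel refinement by
    centre of mass in a 3x3 response window.  Zero detections is a valid
    result.
    """
    cfg = config or SpotConfig()
    img = np.asarray(corrected_green, dtype=np.float64)
    if img.ndim != 2 or not np.isfinite(img).all():
        raise ValidationError("corrected_green must be a finite 2-D array")
    if np.ptp(img) == 0:
        return SpotDetections([], [], 0, field_id, flags=["low_contrast"])

    sigmas = np.geomspace(cfg.min_sigma_px, cfg.max_sigma_px, cfg.n_sigma)
    if cfg.threshold_mode == "relative":
        # Background sigma of the (possibly zero-censored) corrected image:
        # the upper half-spread p90 - p50 equals 1.2816 sigma for Gaussian
        # noise and is immune both to censoring of the lower tail and to
        # rare bright spots.  Each scale's response is divided by
        # sigma_bg * ||filter||_2 — its exact standard deviation under iid
        # noise — so the multiscale maximum is a z-score and ``k_mad``
        # thresholds in robust-sigma units at every scale alike.
        p50, p90 = np.percentile(img, [50.0, 90.0])
        sigma_bg = (p90 - p50) / 1.2816
        if sigma_bg <= 0:
            # Noise-free image: any strictly positive response is signal.
            sigma_bg = None
        resp = None
        for s in sigmas:
            r = -(s * s) * ndi.gaussian_laplace(img, s)
            z = r / (sigma_bg * _log_filter_norm(s)) if sigma_bg else r
            resp = z if resp is None else np.maximum(resp, z)
        thr = cfg.k_mad if sigma_bg else max(1e-9 * img.max(), 1e-12)
    elif cfg.threshold_mode == "absolute":
        if cfg.threshold_abs is None:
            raise ValidationError("threshold_abs required for absolute mode")
        resp = None
        for s in sigmas:
            r = -(s * s) * ndi.gaussian_laplace(img, s)
            resp = r if resp is None else np.maximum(resp, r)
        thr = cfg.threshold_abs
    else:
        raise ValidationError(f"unknown threshold_mode {cfg.threshold_mode!r}")

    peaks = peak_local_max(resp, min_distance=int(round(cfg.min_separation_px)),
                           threshold_abs=thr, exclude_border=False)
    centroids: list[tuple[float, float]] = []
    intensities: list[float] = []
    h, w = img.shape
    for py, px in peaks:
        cx, cy = float(px), float(py)
        if cfg.subpixel and 0 < py < h - 1 and 0 < px < w - 1:
            win = resp[py - 1:py + 2, px - 1:px + 2]
            wpos = np.clip(win - win.min(), 0.0, None)
            tot = wpos.sum()
            if tot > 0:
                dy, dx = np.mgrid[-1:2, -1:2]
                cy = py + float((wpos * dy).sum() / tot)
                cx = px + float((wpos * dx).sum() / tot)
        centroids.append((cx, cy))
        intensities.append(float(img[py, px]))
    return SpotDetections(centroids, intensities, len(centroids), field_id)


def _render_overlay(field: TwoChannelField, follicles: FollicleDetections,
                    spots: SpotDetections) -> np.ndarray:
    """RGB QC overlay: channels as colours, detections drawn on top."""
    from skimage.draw import circle_perimeter, disk as disk_px

    def norm(a: np.ndarray) -> np.ndarray:
        hi = np.percentile(a, 99.5)
        lo = np.percentile(a, 1.0)
        return np.clip((a - lo) / max(hi - lo, 1e-9), 0.0, 1.0)

    h, w = field.shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    rgb[..., 1] = norm(field.green)
    rgb[..., 0] = norm(field.red)
    for (cx, cy), r in zip(follicles.centroids, follicles.equivalent_radii_px):
        rr, cc = circle_perimeter(int(round(cy)), int(round(cx)),
                                  max(int(round(r)), 2), shape=(h, w))
        rgb[rr, cc] = (0.2, 0.4, 1.0)
    for cx, cy in spots.centroids:
        rr, cc = disk_px((int(round(cy)), int(round(cx))), 3, shape=(h, w))
        rgb[rr, cc] = (1.0, 1.0, 1.0)
    return (rgb * 255).astype(np.uint8)


def quantify_field(field: TwoChannelField,
                   config: WholemountConfig | None = None,
                   return_overlay: bool = False) -> FieldQuantification:
    """Run the full per-field chain and return counts plus diagnostics.

    Stage failures downgrade gracefully: if the bleed fit cannot run (too
    few follicle pixels, degenerate red) the green channel is used
    uncorrected and the record is flagged, so a multi-field run continues.
    """
    cfg = config or WholemountConfig()
    flags: list[str] = []

    follicles = detect_follicles(field.red, cfg.follicle, field.field_id)
    flags.extend(follicles.flags)

    model = UnmixModel(alpha=0.0, intercept=0.0, n_pixels_used=0,
                       fit_diagnostic=float("nan"))
    if follicles.mask is not None and follicles.mask.any():
        mask = ndi.binary_dilation(follicles.mask,
                                   structure=disk(cfg.bleed.mask_dilation_px))
        try:
            model = estimate_bleed(field.red, field.green, mask, cfg.bleed)
            # A bleed fraction must be < 1; a larger slope means the
            # channels are mislabelled or the signal model is wrong.
            if model.alpha >= 1.0:
                flags.append("implausible_alpha")
        except (InsufficientDataError, DegenerateFitError):
            flags.append("bleed_fit_failed")
    else:
        flags.append("no_follicle_mask")

    corrected = unmix_green(field.green, field.red, model)
    spots = detect_mcsc_spots(corrected, cfg.spot, field.field_id)
    flags.extend(f for f in spots.flags if f not in flags)

    record = ImageRecord(field_id=field.field_id, mouse_id=field.mouse_id,
                         n_follicles=follicles.count, n_mcsc=spots.count)
    overlay = _render_overlay(field, follicles, spots) if return_overlay else None
    return FieldQuantification(record=record, follicles=follicles, spots=spots,
                               unmix=model, flags=flags, overlay=overlay)
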