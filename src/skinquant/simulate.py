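"""Synthetic two-channel skin image generator with exact ground truth.

Emulates the statistical structure of UVB-irradiated mouse dorsal skin as
seen by wide-field whole-mount fluorescence imaging:

* the **red channel** carries hair-follicle autofluorescence — bright,
  quasi-regularly spaced blobs (~320 per field at the default geometry);
* the **green channel** carries sparse, point-like nuclear GFP signals from
  melanocytes that have migrated into the interfollicular epidermis, plus a
  bleed-through copy of the red follicle signal (spectral crosstalk), a
  constant background, and detector noise.

Every stochastic element is recorded in a :class:`SyntheticTruth` so that
detection, unmixing and counting can be validated against exact ground
truth.  Section-style stain/DAPI image pairs and two-channel spot sets for
colocalization analysis are generated with the same philosophy: the truth
(mask areas, cell counts, colocalized fraction) is enforced by construction,
not estimated after the fact.

All generators take an explicit seed and are bit-reproducible; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from ._errors import PlacementError, ValidationError

__all__ = [
    "FieldParams",
    "TwoChannelField",
    "SyntheticTruth",
    "SectionPairTruth",
    "generate_wholemount",
    "generate_mouse_dataset",
    "generate_section_pair",
    "generate_coloc_pair",
]

# Follicle centres may not sit closer than this multiple of the largest
# follicle radius; keeps blobs resolvable, as in real whole-mount fields.
_MIN_SEP_FACTOR = 2.5
_PLACEMENT_RETRIES = 50


@dataclass(frozen=True)
class FieldParams:
    """Geometry and signal model of one synthetic whole-mount field.

    Defaults reproduce the acquisition geometry of the quantified
    experiments: ~320 autofluorescent follicles per field, 20–25 fields per
    mouse, sparse nuclear GFP points in the green channel, and red→green
    bleed-through removed later by scaled subtraction.

    Parameters
    ----------
    width_px, height_px : int
        Field size in pixels.
    pixel_size_um : float
        Physical pixel size (µm/px).
    n_follicles : int
        Number of follicle blobs placed in the red channel.
    follicle_radius_px : (float, float)
        Uniform range of follicle radii.
    follicle_peak_intensity : (float, float)
        Uniform range of follicle peak amplitudes above background.
    mcsc_rate : float
        Expected epidermal melanocytes *per follicle*; the per-field count
        is drawn as Poisson(``n_follicles * mcsc_rate``).
    spot_sigma_px : float
        Gaussian point-spread sigma of a nuclear GFP spot.
    spot_peak_intensity : (float, float)
        Uniform range of spot peak amplitudes.
    bleed_alpha : float
        Fraction of the (noise-free, background-subtracted) red signal
        leaking into the green channel; in [0, 1).
    bg_level : float
        Constant background added to both channels.
    noise_sd : float
        Additive Gaussian detector noise sigma (0 disables noise).
    poisson_noise : bool
        Optionally replace additive noise with shot noise on the clean
        signal (off by default).
    seed : int
        Seed for all randomness of this field.
    """

    width_px: int = 2048
    height_px: int = 2048
    pixel_size_um: float = 1.0
    n_follicles: int = 320
    follicle_radius_px: tuple[float, float] = (12.0, 20.0)
    follicle_peak_intensity: tuple[float, float] = (800.0, 1600.0)
    mcsc_rate: float = 0.05
    spot_sigma_px: float = 2.0
    spot_peak_intensity: tuple[float, float] = (900.0, 1800.0)
    bleed_alpha: float = 0.25
    bg_level: float = 100.0
    noise_sd: float = 15.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("field dimensions must be positive")
        if not np.isfinite(
            [self.pixel_size_um, self.mcsc_rate, self.spot_sigma_px,
             self.bleed_alpha, self.bg_level, self.noise_sd,
             *self.follicle_radius_px, *self.follicle_peak_intensity,
             *self.spot_peak_intensity]
        ).all():
            raise ValidationError("parameters must be finite")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.n_follicles < 0:
            raise ValidationError("n_follicles must be >= 0")
        rmin, rmax = self.follicle_radius_px
        if not (0 < rmin <= rmax):
            raise ValidationError("follicle_radius_px must satisfy 0 < min <= max")
        if not (0.0 <= self.bleed_alpha < 1.0):
            raise ValidationError("bleed_alpha must lie in [0, 1)")
        if self.noise_sd < 0 or self.mcsc_rate < 0 or self.bg_level < 0:
            raise ValidationError("noise_sd, mcsc_rate and bg_level must be >= 0")
        if self.spot_sigma_px <= 0:
            raise ValidationError("spot_sigma_px must be positive")
        # Placement feasibility: follicle footprints may not dominate the field.
        if self.n_follicles * math.pi * rmax**2 >= 0.5 * self.width_px * self.height_px:
            raise ValidationError(
                "n_follicles * pi * max_radius^2 must be < half the field area"
            )


@dataclass
class TwoChannelField:
    """One whole-mount field: green (GFP) and red (autofluorescence) planes."""

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float
    field_id: str
    mouse_id: str

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValidationError("green and red planes must share a shape")
        for name, arr in (("green", self.green), ("red", self.red)):
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} plane contains non-finite values")
            if (arr < 0).any():
                raise ValidationError(f"{name} plane contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for one synthetic field.

    Coordinates are 0-based ``(x, y)`` = (column, row) pixel positions.
    ``mcsc_peaks`` stores the spot amplitudes so the pure spot image can be
    reconstructed exactly for unmixing-decomposition tests.
    """

    follicle_centers: list[tuple[float, float]]
    follicle_radii: list[float]
    mcsc_positions: list[tuple[float, float]]
    bleed_alpha: float
    params: FieldParams
    mcsc_peaks: list[float] = dc_field(default_factory=list)

    @property
    def n_follicles(self) -> int:
        return len(self.follicle_centers)

    @property
    def n_mcsc(self) -> int:
        return len(self.mcsc_positions)


@dataclass
class SectionPairTruth:
    """Exact painted areas (and cell count) of a synthetic section pair."""

    stain_mask_area_px: int
    dapi_mask_area_px: int
    n_cells: int
    stain_mask: np.ndarray | None = None
    dapi_mask: np.ndarray | None = None


def _hex_grid(width: float, height: float, margin: float, spacing: float) -> np.ndarray:
    """Nodes of a hexagonal grid covering [margin, size-margin]^2."""
    dy = spacing * math.sqrt(3.0) / 2.0
    xs, ys = [], []
    row = 0
    y = margin
    while y <= height - margin:
        x0 = margin + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= width - margin:
            xs.append(x)
            ys.append(y)
            x += spacing
        y += dy
        row += 1
    return np.column_stack([xs, ys]) if xs else np.empty((0, 2))


def _place_follicles(params: FieldParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal layout with a hard minimum centre separation.

    Murine follicles are quasi-regularly spaced; a jittered grid avoids the
    pathological merges a uniform-random draw would produce at 320 per field.
    """
    n = params.n_follicles
    if n == 0:
        return np.empty((0, 2))
    rmax = params.follicle_radius_px[1]
    min_sep = _MIN_SEP_FACTOR * rmax
    margin = rmax + 1.0
    w, h = float(params.width_px), float(params.height_px)
    usable = max(w - 2 * margin, 1.0) * max(h - 2 * margin, 1.0)
    # Ideal hex spacing for n sites in the usable area, then shrink until
    # the grid holds at least n nodes.
    spacing = math.sqrt(usable / (n * math.sqrt(3.0) / 2.0))
    nodes = _hex_grid(w, h, margin, spacing)
    while len(nodes) < n and spacing > min_sep:
        spacing *= 0.97
        nodes = _hex_grid(w, h, margin, spacing)
    if len(nodes) < n:
        raise PlacementError(
            f"cannot place {n} follicles with separation >= {min_sep:.1f} px "
            f"in a {params.width_px}x{params.height_px} field"
        )
    # Jitter amplitude chosen so even worst-case diagonal moves cannot
    # violate the separation; verified anyway.
    jmax = max(0.0, (spacing - min_sep) / (2.0 * math.sqrt(2.0)))
    for _ in range(_PLACEMENT_RETRIES):
        idx = rng.choice(len(nodes), size=n, replace=False)
        centers = nodes[idx] + rng.uniform(-jmax, jmax, size=(n, 2))
        centers[:, 0] = np.clip(centers[:, 0], margin, w - margin)
        centers[:, 1] = np.clip(centers[:, 1], margin, h - margin)
        if n < 2:
            return centers
        dists, _ = cKDTree(centers).query(centers, k=2)
        if dists[:, 1].min() >= min_sep:
            return centers
    raise PlacementError("follicle placement failed after bounded retries")


def _paint_follicles(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    peaks: np.ndarray,
) -> np.ndarray:
    """Radially decaying (parabolic) disks added on a zero canvas."""
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    for (cx, cy), r, pk in zip(centers, radii, peaks):
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (r * r)
        img[y0:y1, x0:x1] += pk * np.clip(1.0 - r2, 0.0, None)
    return img


def _paint_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    peaks: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Isotropic Gaussian point-spread spots at sub-pixel positions."""
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    ext = int(math.ceil(4.0 * sigma)) + 1
    for (cx, cy), pk in zip(positions, peaks):
        x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, w)
        y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += pk * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma * sigma)
        )
    return img


def generate_wholemount(
    params: FieldParams,
    field_id: str | None = None,
    mouse_id: str = "sim",
) -> tuple[TwoChannelField, SyntheticTruth]:
    """Generate one two-channel whole-mount field with ground truth.

    Signal model (before noise)::

        red   = bg_level + follicle_blobs
        green = bg_level + bleed_alpha * follicle_blobs + gfp_spots

    so that ``green - bleed_alpha*red`` is spatially constant away from
    spots — the identity the bleed-correction stage relies on.  The
    melanocyte count is Poisson(``n_follicles * mcsc_rate``) with uniform
    positions; spot amplitudes are uniform in ``spot_peak_intensity``.
    Identical parameters (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height_px, params.width_px)

    centers = _place_follicles(params, rng)
    rmin, rmax = params.follicle_radius_px
    radii = rng.uniform(rmin, rmax, size=len(centers))
    pmin, pmax = params.follicle_peak_intensity
    peaks = rng.uniform(pmin, pmax, size=len(centers))
    blobs = _paint_follicles(shape, centers, radii, peaks)

    n_spots = int(rng.poisson(params.n_follicles * params.mcsc_rate))
    spot_margin = min(4.0 * params.spot_sigma_px,
                      0.25 * min(params.width_px, params.height_px))
    spot_xy = np.column_stack([
        rng.uniform(spot_margin, params.width_px - spot_margin, size=n_spots),
        rng.uniform(spot_margin, params.height_px - spot_margin, size=n_spots),
    ]) if n_spots else np.empty((0, 2))
    smin, smax = params.spot_peak_intensity
    spot_peaks = rng.uniform(smin, smax, size=n_spots)
    spots = _paint_spots(shape, spot_xy, spot_peaks, params.spot_sigma_px)

    red_clean = params.bg_level + blobs
    green_clean = params.bg_level + params.bleed_alpha * blobs + spots

    if params.poisson_noise:
        red = rng.poisson(np.clip(red_clean, 0, None)).astype(np.float64)
        green = rng.poisson(np.clip(green_clean, 0, None)).astype(np.float64)
    elif params.noise_sd > 0:
        red = red_clean + rng.normal(0.0, params.noise_sd, size=shape)
        green = green_clean + rng.normal(0.0, params.noise_sd, size=shape)
    else:
        red, green = red_clean, green_clean
    red = np.clip(red, 0.0, None)
    green = np.clip(green, 0.0, None)

    fid = field_id if field_id is not None else f"field_{params.seed}"
    field = TwoChannelField(green=green, red=red,
                            pixel_size_um=params.pixel_size_um,
                            field_id=fid, mouse_id=mouse_id)
    truth = SyntheticTruth(
        follicle_centers=[(float(x), float(y)) for x, y in centers],
        follicle_radii=[float(r) for r in radii],
        mcsc_positions=[(float(x), float(y)) for x, y in spot_xy],
        bleed_alpha=params.bleed_alpha,
        params=params,
        mcsc_peaks=[float(p) for p in spot_peaks],
    )
    return field, truth


def generate_mouse_dataset(
    params: FieldParams,
    n_fields: int = 20,
    base_seed: int = 0,
    mouse_id: str = "mouse",
) -> list[tuple[TwoChannelField, SyntheticTruth]]:
    """Generate the fields of one mouse (default 20, the lower end of the
    20–25 fields acquired per animal; 20 x 320 follicles = 6400, the
    per-mouse quantification basis).

    Field *i* uses seed ``base_seed + i``; fields are otherwise independent
    and share ``mouse_id``.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    out = []
    for i in range(n_fields):
        p = replace(params, seed=base_seed + i)
        out.append(generate_wholemount(p, field_id=f"{mouse_id}_f{i:03d}",
                                       mouse_id=mouse_id))
    return out


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth Gaussian random field used to carve organic-looking masks."""
    raw = rng.normal(size=shape)
    return ndi.gaussian_filter(raw, sigma=min(shape) / 8.0)


def _place_disjoint(
    n: int, shape: tuple[int, int], radius: float, min_sep: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = shape
    margin = radius + 2.0
    pts: list[tuple[float, float]] = []
    for _ in range(200 * max(n, 1)):
        if len(pts) == n:
            break
        cand = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
        if all((cand[0] - x) ** 2 + (cand[1] - y) ** 2 >= min_sep**2
               for x, y in pts):
            pts.append(cand)
    if len(pts) < n:
        raise PlacementError(f"could not place {n} disjoint cells")
    return np.asarray(pts)


def generate_section_pair(
    width_px: int = 512,
    height_px: int = 512,
    stain_fraction: float = 0.10,
    dapi_fraction: float = 0.40,
    n_cells: int = 0,
    seed: int = 0,
    bg_level: float = 20.0,
    fg_level: float = 200.0,
    noise_sd: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, SectionPairTruth]:
    """Synthetic stain/DAPI section pair with exactly painted mask areas.

    In the default *area mode* the DAPI mask is the top ``dapi_fraction`` of
    a smooth random field and the stain mask the top ``stain_fraction`` of
    the same field, so the stain region is a subset of the DAPI region and
    both areas are exact pixel counts.  With ``n_cells > 0`` (*cell mode*)
    the stain channel instead holds ``n_cells`` disjoint cell-sized disks
    and the DAPI mask is the union of the random-field region and the cells.

    Returns ``(stain_image, dapi_image, truth)``; truth carries the painted
    masks for mask-level tests.
    """
    if not (0.0 <= stain_fraction <= 1.0) or not (0.0 < dapi_fraction <= 1.0):
        raise ValidationError("fractions out of range")
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    if n_cells == 0 and stain_fraction > dapi_fraction:
        raise ValidationError("stain_fraction must not exceed dapi_fraction")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    npx = width_px * height_px
    f = _smooth_field(shape, rng)
    order = np.argsort(f, axis=None)[::-1]

    dapi_area = int(round(dapi_fraction * npx))
    dapi_mask = np.zeros(npx, dtype=bool)
    dapi_mask[order[:dapi_area]] = True
    dapi_mask = dapi_mask.reshape(shape)

    if n_cells > 0:
        cell_radius = 5.0
        pts = _place_disjoint(n_cells, shape, cell_radius, 4 * cell_radius, rng)
        stain_mask = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0:height_px, 0:width_px]
        for cx, cy in pts:
            stain_mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2
        dapi_mask |= stain_mask  # nuclei are DAPI+
    else:
        stain_area = int(round(stain_fraction * npx))
        stain_mask = np.zeros(npx, dtype=bool)
        stain_mask[order[:stain_area]] = True
        stain_mask = stain_mask.reshape(shape)

    stain_img = bg_level + fg_level * stain_mask.astype(np.float64)
    dapi_img = bg_level + fg_level * dapi_mask.astype(np.float64)
    if noise_sd > 0:
        stain_img = stain_img + rng.normal(0.0, noise_sd, size=shape)
        dapi_img = dapi_img + rng.normal(0.0, noise_sd, size=shape)
    stain_img = np.clip(stain_img, 0.0, None)
    dapi_img = np.clip(dapi_img, 0.0, None)

    truth = SectionPairTruth(
        stain_mask_area_px=int(stain_mask.sum()),
        dapi_mask_area_px=int(dapi_mask.sum()),
        n_cells=n_cells,
        stain_mask=stain_mask,
        dapi_mask=dapi_mask,
    )
    return stain_img, dapi_img, truth


def generate_coloc_pair(
    n_ref: int,
    coloc_fraction: float,
    offset_px: float = 1.0,
    seed: int = 0,
    width_px: int = 512,
    height_px: int = 512,
    match_radius_px: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two centroid sets with an enforced colocalized fraction.

    ``round(n_ref * coloc_fraction)`` reference spots receive a channel-b
    partner at distance ``offset_px`` (random angle); the remaining b-spots
    are placed at least ``5 * match_radius_px`` from every reference spot so
    the truth fraction is unambiguous at the matching radius.  Returns
    ``(spots_a, spots_b, truth_fraction)`` as (n,2) ``(x, y)`` arrays.
    """
    if n_ref < 0:
        raise ValidationError("n_ref must be >= 0")
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValidationError("coloc_fraction must lie in [0, 1]")
    if offset_px < 0 or match_radius_px <= 0:
        raise ValidationError("offset_px must be >= 0 and match_radius_px > 0")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    guard = 5.0 * match_radius_px
    if n_ref == 0:
        return np.empty((0, 2)), np.empty((0, 2)), 0.0
    spots_a = _place_disjoint(n_ref, shape, match_radius_px,
                              2 * guard + 2 * offset_px, rng)
    n_coloc = int(round(n_ref * coloc_fraction))
    theta = rng.uniform(0, 2 * math.pi, size=n_coloc)
    partners = spots_a[:n_coloc] + offset_px * np.column_stack(
        [np.cos(theta), np.sin(theta)])
    # Distractor b-spots, kept clear of every reference spot.
    n_extra = n_ref - n_coloc
    extras: list[np.ndarray] = []
    if n_extra:
        tree = cKDTree(spots_a)
        margin = match_radius_px + 2.0
        while len(extras) < n_extra:
            cand = np.array([rng.uniform(margin, width_px - margin),
                             rng.uniform(margin, height_px - margin)])
            if tree.query(cand)[0] >= guard:
                extras.append(cand)
    spots_b = np.vstack([partners] + ([np.asarray(extras)] if extras else [])) \
        if (n_coloc or extras) else np.empty((0, 2))
    return spots_a, spots_b, n_coloc / n_ref
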