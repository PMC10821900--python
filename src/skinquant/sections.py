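"""Sectioned-tissue quantification.

Three measurements used on stained skin sections:

* :func:`area_ratio` — relative staining level, the area of positive
  staining divided by the area of DAPI staining (e.g. Ly6G+ neutrophil
  infiltration, Cox-2 expression level).
* :func:`count_cells` — cells per image by thresholding and connected
  components with a cell-size gate (e.g. CD3+ T cells per image, epidermal
  melanocytes per frame).
* :func:`colocalization_fraction` — object-based colocalization: the
  fraction of reference spots (e.g. tdTomato+ melanocyte nuclei) with a
  partner spot (e.g. EdU+ nucleus) within a matching radius.

Deterministic; no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from ._errors import EmptyDAPIError, ValidationError

__all__ = [
    "SectionConfig",
    "AreaRatioResult",
    "FrameCount",
    "ColocResult",
    "area_ratio",
    "count_cells",
    "colocalization_fraction",
]


@dataclass(frozen=True)
class SectionConfig:
    """Thresholding and gating parameters for section images.

    Per-channel Otsu by default; set ``stain_threshold_abs`` /
    ``dapi_threshold_abs`` for absolute overrides.  ``watershed_split``
    separates touching cells in :func:`count_cells` via a distance-
    transform watershed.
    """

    stain_threshold_abs: float | None = None
    dapi_threshold_abs: float | None = None
    min_cell_area_px: int = 10
    max_cell_area_px: int = 2000
    watershed_split: bool = False
    watershed_min_distance_px: int = 5
    exclude_border_touching: bool = False


@dataclass
class AreaRatioResult:
    positive_area_px: int
    dapi_area_px: int
    ratio: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.dapi_area_px <= 0:
            raise ValidationError("dapi_area_px must be positive")


@dataclass
class FrameCount:
    image_id: str
    n_cells: int


@dataclass
class ColocResult:
    n_ref: int
    n_coloc: int
    fraction: float
    match_radius_px: float
    flags: list[str] = dc_field(default_factory=list)


def _foreground(img: np.ndarray, threshold_abs: float | None) -> np.ndarray:
    """Binary foreground; a constant channel has empty foreground."""
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or not np.isfinite(a).all():
        raise ValidationError("image must be a finite 2-D array")
    if threshold_abs is not None:
        return a > threshold_abs
    if np.ptp(a) < 1e-9:
        return np.zeros(a.shape, dtype=bool)
    return a > threshold_otsu(a)


def area_ratio(stain: np.ndarray, dapi: np.ndarray,
               config: SectionConfig | None = None,
               image_id: str = "") -> AreaRatioResult:
    """Positive-staining area over DAPI area for one section image pair.

    Raises :class:`EmptyDAPIError` when the DAPI foreground is empty — the
    ratio is undefined there, and a silent zero would bias group means.
    """
    cfg = config or SectionConfig()
    s = np.asarray(stain, dtype=np.float64)
    d = np.asarray(dapi, dtype=np.float64)
    if s.shape != d.shape:
        raise ValidationError("stain and dapi shapes must match")
    stain_fg = _foreground(s, cfg.stain_threshold_abs)
    dapi_fg = _foreground(d, cfg.dapi_threshold_abs)
    dapi_area = int(dapi_fg.sum())
    if dapi_area == 0:
        raise EmptyDAPIError("DAPI foreground empty; area ratio undefined")
    pos = int(stain_fg.sum())
    return AreaRatioResult(positive_area_px=pos, dapi_area_px=dapi_area,
                           ratio=pos / dapi_area, image_id=image_id)


def count_cells(stain: np.ndarray, config: SectionConfig | None = None,
                image_id: str = "") -> FrameCount:
    """Cells per image: threshold → components → cell-size gate → count."""
    cfg = config or SectionConfig()
    fg = _foreground(stain, cfg.stain_threshold_abs)
    if cfg.watershed_split and fg.any():
        dist = ndi.distance_transform_edt(fg)
        pk = peak_local_max(dist, min_distance=cfg.watershed_min_distance_px,
                            labels=fg, exclude_border=False)
        markers = np.zeros(fg.shape, dtype=np.int32)
        for i, (py, px) in enumerate(pk, start=1):
            markers[py, px] = i
        lbl = watershed(-dist, markers, mask=fg)
    else:
        lbl = label(fg, connectivity=2)
    h, w = fg.shape
    n = 0
    for rp in regionprops(lbl):
        if not (cfg.min_cell_area_px <= rp.area <= cfg.max_cell_area_px):
            continue
        if cfg.exclude_border_touching:
            y0, x0, y1, x1 = rp.bbox
            if y0 == 0 or x0 == 0 or y1 == h or x1 == w:
                continue
        n += 1
    return FrameCount(image_id=image_id, n_cells=n)


def colocalization_fraction(spots_ref, spots_other,
                            match_radius_px: float = 3.0) -> ColocResult:
    """Fraction of reference spots with an other-channel spot within radius.

    One-to-many matching: a single partner spot may validate several
    reference spots (duplicates are prevented upstream by non-maximum
    suppression in spot detection).  An empty reference set yields fraction
    0 with an ``empty_reference`` flag.
    """
    if match_radius_px <= 0:
        raise ValidationError("match_radius_px must be positive")
    ref = np.asarray(spots_ref, dtype=np.float64).reshape(-1, 2)
    oth = np.asarray(spots_other, dtype=np.float64).reshape(-1, 2)
    if len(ref) == 0:
        return ColocResult(0, 0, 0.0, match_radius_px, flags=["empty_reference"])
    if len(oth) == 0:
        return ColocResult(len(ref), 0, 0.0, match_radius_px)
    d, _ = cKDTree(oth).query(ref)
    n_coloc = int((d <= match_radius_px).sum())
    return ColocResult(n_ref=len(ref), n_coloc=n_coloc,
                       fraction=n_coloc / len(ref),
                       match_radius_px=match_radius_px)
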