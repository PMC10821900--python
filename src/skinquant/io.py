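"""File I/O: two-channel TIFFs, truth/result tables, provenance.

Conventions (overridable through :class:`~skinquant.config.ChannelMap`):
TIFF page 0 = green/stain, page 1 = red/DAPI; images are written as 16-bit
after clipping to [0, 65535]; tables are UTF-8 CSV with '.' decimals and
rates at 6 significant digits; field metadata comes from the filename
pattern ``<mouse>_<field>.tif`` or a sidecar CSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._errors import FormatError
from .config import ChannelMap
from .simulate import SyntheticTruth, TwoChannelField

__all__ = ["write_field", "read_field", "write_truth_csv",
           "write_table", "write_provenance"]

FLOAT_FORMAT = "%.6g"
_NAME_RE = re.compile(r"^(?P<mouse>.+)_(?P<field>[^_]+)$")


def write_field(field: TwoChannelField, path,
                channel_map: ChannelMap | None = None) -> Path:
    """Write a field as a 2-page 16-bit TIFF (green page first by default)."""
    cm = channel_map or ChannelMap()
    path = Path(path)
    pages = [None, None]
    pages[cm.green] = field.green
    pages[cm.red] = field.red
    stack = np.stack([np.clip(np.round(p), 0, 65535).astype(np.uint16)
                      for p in pages])
    tifffile.imwrite(path, stack)
    return path


def read_field(path, channel_map: ChannelMap | None = None,
               pixel_size_um: float = 1.0) -> TwoChannelField:
    """Read a two-channel TIFF into a :class:`TwoChannelField`.

    Accepts page-first ``(C, H, W)`` or channel-last ``(H, W, C)`` layouts;
    a single-plane file is a format error when a two-channel map is in
    force.  ``mouse_id``/``field_id`` are parsed from the filename stem
    (``<mouse>_<field>``; otherwise the stem is the field id).
    """
    cm = channel_map or ChannelMap()
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if arr.ndim == 2:
        raise FormatError(f"{path}: single plane, but a two-channel map "
                          "(green+red) is configured")
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 2 planes, got shape {arr.shape}")
    if arr.shape[0] <= 4 < arr.shape[-1]:
        planes = arr
    elif arr.shape[-1] <= 4:
        planes = np.moveaxis(arr, -1, 0)
    else:
        planes = arr
    n = planes.shape[0]
    if cm.green >= n or cm.red >= n:
        raise FormatError(f"{path}: channel map needs page "
                          f"{max(cm.green, cm.red)} but file has {n} planes")
    green = planes[cm.green].astype(np.float64)
    red = planes[cm.red].astype(np.float64)
    if green.shape != red.shape:
        raise FormatError(f"{path}: inconsistent plane shapes")
    m = _NAME_RE.match(path.stem)
    mouse_id = m.group("mouse") if m else path.stem
    field_id = path.stem
    return TwoChannelField(green=green, red=red, pixel_size_um=pixel_size_um,
                           field_id=field_id, mouse_id=mouse_id)


def write_truth_csv(truth: SyntheticTruth, out_dir, stem: str) -> None:
    """Ground-truth tables: one row per follicle and per melanocyte spot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    foll = pd.DataFrame(truth.follicle_centers, columns=["x_px", "y_px"])
    foll["radius_px"] = truth.follicle_radii
    foll.to_csv(out_dir / f"{stem}_follicles.csv", index=False,
                float_format=FLOAT_FORMAT)
    spots = pd.DataFrame(truth.mcsc_positions, columns=["x_px", "y_px"])
    spots["sigma_px"] = truth.params.spot_sigma_px
    spots["peak"] = truth.mcsc_peaks
    spots.to_csv(out_dir / f"{stem}_mcsc.csv", index=False,
                 float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_provenance(out_dir, cfg_hash: str, seed: int) -> Path:
    """Provenance block making every output directory exactly rerunnable."""
    import yaml

    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"config_sha256": cfg_hash, "seed": seed,
                        "software_version": __version__}, fh, sort_keys=True)
    return path
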