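"""Reading, writing and tiling of calibrated multichannel fluorescence fields.

A *field* is one multi-plane grayscale raster (nominally 16-bit) holding a
DAPI nuclear counterstain, a cleaved-caspase-3 (CC3) immunostain and a
gammaH2AX immunostain.  Channels are addressed by the canonical names
``"DAPI"``, ``"CC3"`` and ``"GH2AX"`` after mapping from file plane indices.

Conventions used throughout the package:

* coordinates are 0-based ``(row, column)``; rectangles are half-open;
* intensities are kept at native integer scale — no normalisation at I/O
  time, so configured thresholds are directly interpretable;
* physical calibration is the *linear* pixel pitch in microns per pixel
  edge; areas are ``pixel_count * microns_per_pixel**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

#: Canonical channel names every field must expose after mapping.
CANONICAL_CHANNELS = ("DAPI", "CC3", "GH2AX")

#: Default linear pixel pitch in microns per pixel edge for 20x scans.
DEFAULT_MICRONS_PER_PIXEL = 0.4622


class FieldIOError(ValueError):
    """Raised for malformed fields, channel maps or tile requests."""


def resolve_microns_per_pixel(value: float, unit: str = "um_per_px") -> float:
    """Return the linear pixel pitch in microns from a calibration value.

    Scanner metadata sometimes reports the calibration as a pixel *area*
    (``um2_per_px``) rather than the conventional linear pitch
    (``um_per_px``).  Both interpretations are supported explicitly so the
    choice is never silent.
    """
    if value <= 0:
        raise FieldIOError(f"calibration must be positive, got {value}")
    if unit == "um_per_px":
        return float(value)
    if unit == "um2_per_px":
        return float(math.sqrt(value))
    raise FieldIOError(f"unknown calibration unit {unit!r}")


@dataclass(frozen=True)
class ChannelMap:
    """Injective mapping from file plane index to canonical channel name."""

    entries: Mapping[int, str]

    def __post_init__(self) -> None:
        names = list(self.entries.values())
        if len(set(names)) != len(names):
            raise FieldIOError(f"channel map is not injective: {dict(self.entries)}")
        missing = set(CANONICAL_CHANNELS) - set(names)
        if missing:
            raise FieldIOError(f"channel map missing canonical channels: {sorted(missing)}")
        extra = set(names) - set(CANONICAL_CHANNELS)
        if extra:
            raise FieldIOError(f"channel map has unknown channel names: {sorted(extra)}")


DEFAULT_CHANNEL_MAP = ChannelMap({0: "DAPI", 1: "CC3", 2: "GH2AX"})


@dataclass(frozen=True)
class CalibratedField:
    """One image field: named channel rasters plus physical calibration.

    This is the unit of analysis — all per-cell statistics are computed
    per field.
    """

    field_id: str
    channels: Mapping[str, np.ndarray]
    microns_per_pixel: float
    bit_depth: int = 16
    source: str = "synthetic"
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise FieldIOError(f"microns_per_pixel must be positive, got {self.microns_per_pixel}")
        if set(self.channels) != set(CANONICAL_CHANNELS):
            raise FieldIOError(
                f"channels must be exactly {CANONICAL_CHANNELS}, got {sorted(self.channels)}"
            )
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise FieldIOError(f"channel rasters differ in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise FieldIOError(f"channel {name} is not 2-D")
            if not np.issubdtype(arr.dtype, np.integer):
                raise FieldIOError(f"channel {name} must be an integer raster, got {arr.dtype}")
            if arr.size and arr.min() < 0:
                raise FieldIOError(f"channel {name} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return self.microns_per_pixel**2


def read_field(
    path: str | Path,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
    field_id: str | None = None,
    group_label: str | None = None,
) -> CalibratedField:
    """Read a multi-plane TIFF/OME-TIFF into a :class:`CalibratedField`.

    Integer intensities are preserved bit-exactly.  Raises a distinct
    :class:`FieldIOError` for a missing file, a plane count below the
    mapped indices, or a non-injective map (checked at map construction).
    """
    path = Path(path)
    if not path.exists():
        raise FieldIOError(f"field file not found: {path}")
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None, ...]
    if planes.ndim != 3:
        raise FieldIOError(f"expected a stack of 2-D planes in {path}, got shape {planes.shape}")
    n_planes = planes.shape[0]
    for idx in channel_map.entries:
        if not 0 <= idx < n_planes:
            raise FieldIOError(
                f"channel index out of range: map references plane {idx} "
                f"but {path} has {n_planes} plane(s)"
            )
    channels = {name: np.asarray(planes[idx]) for idx, name in channel_map.entries.items()}
    bit_depth = 8 * next(iter(channels.values())).dtype.itemsize
    return CalibratedField(
        field_id=field_id or path.stem,
        channels=channels,
        microns_per_pixel=microns_per_pixel,
        bit_depth=bit_depth,
        source=str(path),
        group_label=group_label,
    )


def write_field(field: CalibratedField, path: str | Path) -> Path:
    """Write the field's channels as a multi-plane TIFF in canonical order."""
    path = Path(path)
    stack = np.stack([np.asarray(field.channels[name]) for name in CANONICAL_CHANNELS])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def extract_tile(
    field: CalibratedField,
    origin_xy: tuple[int, int],
    size_px: tuple[int, int] = (1000, 1000),
) -> CalibratedField:
    """Extract a fixed-size tile; the default size is 1,000 x 1,000 pixels.

    The tile rectangle (half-open, (row, col) origin) must lie fully inside
    the field — out-of-bounds requests raise rather than silently clip.
    Calibration and group label are inherited.
    """
    r0, c0 = origin_xy
    h, w = size_px
    H, W = field.shape
    if h <= 0 or w <= 0:
        raise FieldIOError(f"tile size must be positive, got {size_px}")
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise FieldIOError(
            f"tile bounds error: origin {origin_xy} size {size_px} "
            f"does not fit inside field of shape {(H, W)}"
        )
    channels = {name: arr[r0 : r0 + h, c0 : c0 + w].copy() for name, arr in field.channels.items()}
    return replace(
        field,
        field_id=f"{field.field_id}_tile_r{r0}c{c0}",
        channels=channels,
    )


# ---------------------------------------------------------------------------
# Per-cell tables

#: Stable column order for per-cell CSV tables.
CELL_TABLE_COLUMNS = [
    "field_id",
    "cell_label",
    "nuclear_area_um2",
    "cyto_cc3_mean",
    "cyto_cc3_pos",
    "puncta_count",
    "cc3_bleb_pos",
    "gh2ax_mean",
    "gh2ax_pos",
    "coloc_pos",
]

_BOOL_COLUMNS = ["cyto_cc3_pos", "cc3_bleb_pos", "gh2ax_pos", "coloc_pos"]


def validate_cell_table(table: pd.DataFrame) -> None:
    """Check cell-table invariants: unique (field_id, cell_label), positive areas."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FieldIOError(f"cell table missing columns: {missing}")
    if len(table) and table.duplicated(subset=["field_id", "cell_label"]).any():
        raise FieldIOError("cell table has duplicate (field_id, cell_label) rows")
    if len(table) and (table["nuclear_area_um2"] <= 0).any():
        raise FieldIOError("cell table has non-positive nuclear areas")


def write_cell_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-cell table as CSV with a stable column order.

    Re-reading with :func:`read_cell_table` reproduces the table exactly.
    """
    validate_cell_table(table)
    path = Path(path)
    out = table[CELL_TABLE_COLUMNS].copy()
    out.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FieldIOError(f"cell table not found: {path}")
    dtypes = {c: bool for c in _BOOL_COLUMNS}
    table = pd.read_csv(path, dtype=dtypes)
    if len(table) == 0:
        # header-only file: coerce to canonical dtypes
        table = table.astype(
            {
                "field_id": str,
                "cell_label": np.int64,
                "nuclear_area_um2": float,
                "cyto_cc3_mean": float,
                "puncta_count": np.int64,
                "gh2ax_mean": float,
                **{c: bool for c in _BOOL_COLUMNS},
            }
        )
    validate_cell_table(table)
    return table[CELL_TABLE_COLUMNS]
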