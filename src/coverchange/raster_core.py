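"""Shared domain types, grid conventions, mask handling, and raster I/O.

All rasters in one analysis live on a single :class:`Grid` (row-major,
(row 0, col 0) at top-left, pixel-center coordinates, 30 m pixels by
default).  Categorical rasters use integer codes 1..7 for the seven cover
classes with 0 reserved as nodata; continuous rasters carry an explicit
nodata sentinel.  Rasters are stored as TIFF files with the grid metadata
serialized as JSON in the ImageDescription tag, so a write -> read
roundtrip is the identity on values, grid, and nodata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "CLASS_CODES",
    "CLASS_LABELS",
    "CLASS_DISPLAY_NAMES",
    "NODATA",
    "CoverClass",
    "Grid",
    "ClassMap",
    "ElevationRaster",
    "MaskSet",
    "apply_mask",
    "read_class_map",
    "write_class_map",
    "read_continuous",
    "write_continuous",
    "read_mask",
    "write_mask",
]

NODATA = 0

# Fixed class order: tables print in this row order.
CLASS_LABELS = (
    "forest_shrubs",
    "mangrove",
    "bare_soil",
    "wetland",
    "pine_forest",
    "agriculture",
    "water",
)
CLASS_CODES = tuple(range(1, 8))

# Spelled the way the published tables spell them.
CLASS_DISPLAY_NAMES = {
    1: "Forest and shrubs",
    2: "Mangrove",
    3: "Soil without vegetation cover",
    4: "Wetland",
    5: "Pine forest",
    6: "Agriculture",
    7: "Water bodies",
}

_LABEL_TO_CODE = {lab: code for code, lab in zip(CLASS_CODES, CLASS_LABELS)}


@dataclass(frozen=True)
class CoverClass:
    """One of the seven land-cover classes; code 0 is nodata, not a class."""

    code: int
    label: str

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"invalid class code {self.code}")
        if _LABEL_TO_CODE.get(self.label) != self.code:
            raise ValueError(f"label {self.label!r} does not match code {self.code}")

    @classmethod
    def from_code(cls, code: int) -> "CoverClass":
        if code not in CLASS_CODES:
            raise ValueError(f"invalid class code {code}")
        return cls(code, CLASS_LABELS[code - 1])

    @classmethod
    def from_label(cls, label: str) -> "CoverClass":
        if label not in _LABEL_TO_CODE:
            raise ValueError(f"unknown class label {label!r}")
        return cls(_LABEL_TO_CODE[label], label)

    @property
    def display_name(self) -> str:
        return CLASS_DISPLAY_NAMES[self.code]


ALL_CLASSES = tuple(CoverClass.from_code(c) for c in CLASS_CODES)


@dataclass(frozen=True)
class Grid:
    """Raster grid: shape, pixel size in meters, and map-coordinate origin."""

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


def _require_same_grid(a: Grid, b: Grid, what: str) -> None:
    if a != b:
        raise ValueError(f"grid mismatch in {what}: {a} vs {b}")


@dataclass
class ClassMap:
    """Categorical raster of cover classes; 0 marks nodata."""

    grid: Grid
    values: np.ndarray
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("class map values must be integers")
        self.values = self.values.astype(np.uint8, copy=False)
        bad = np.setdiff1d(np.unique(self.values), [NODATA, *CLASS_CODES])
        if bad.size:
            raise ValueError(f"invalid class code {int(bad[0])}")

    @property
    def valid(self) -> np.ndarray:
        """Boolean raster of classified (non-nodata) pixels."""
        return self.values != NODATA

    def copy(self) -> "ClassMap":
        return ClassMap(self.grid, self.values.copy(), self.epoch_label)


@dataclass
class ElevationRaster:
    """Continuous elevation raster in meters with an explicit nodata sentinel."""

    grid: Grid
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("elevation shape does not match grid")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-finite elevation outside nodata")

    @property
    def valid(self) -> np.ndarray:
        return self.values != self.nodata


@dataclass
class MaskSet:
    """The four analysis masks: full region, protected areas, host-plant
    potential distribution (od), and their intersection."""

    grid: Grid
    full_region: np.ndarray
    protected: np.ndarray
    od: np.ndarray
    od_in_protected: np.ndarray

    def __post_init__(self) -> None:
        for name in ("full_region", "protected", "od", "od_in_protected"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.grid.shape:
                raise ValueError(f"mask {name} shape does not match grid")
            setattr(self, name, arr)
        if not np.array_equal(self.od_in_protected, self.od & self.protected):
            raise ValueError("od_in_protected must equal od AND protected")
        for name in ("protected", "od", "od_in_protected"):
            if np.any(getattr(self, name) & ~self.full_region):
                raise ValueError(f"mask {name} extends outside full_region")

    def items(self) -> list[tuple[str, np.ndarray]]:
        return [
            ("full_region", self.full_region),
            ("protected", self.protected),
            ("od", self.od),
            ("od_in_protected", self.od_in_protected),
        ]


def apply_mask(class_map: ClassMap, mask: np.ndarray) -> ClassMap:
    """Set pixels outside ``mask`` to nodata; inside-mask values unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != class_map.grid.shape:
        raise ValueError(
            f"grid mismatch in apply_mask: mask shape {mask.shape} "
            f"!= grid shape {class_map.grid.shape}"
        )
    out = class_map.values.copy()
    out[~mask] = NODATA
    return ClassMap(class_map.grid, out, class_map.epoch_label)


# ---------------------------------------------------------------------------
# TIFF I/O.  Grid metadata rides in the ImageDescription tag as JSON.


def _grid_meta(grid: Grid, extra: Mapping[str, object] | None = None) -> str:
    meta: dict[str, object] = {
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
    }
    if extra:
        meta.update(extra)
    return json.dumps(meta)


def _read_meta(path: Path) -> tuple[np.ndarray, dict]:
    if not Path(path).exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    return arr, meta


def _grid_from_meta(shape: tuple[int, int], meta: Mapping) -> Grid:
    return Grid(
        n_rows=shape[0],
        n_cols=shape[1],
        pixel_size=float(meta.get("pixel_size", 30.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def write_class_map(class_map: ClassMap, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        class_map.values.astype(np.uint8),
        description=_grid_meta(
            class_map.grid, {"epoch_label": class_map.epoch_label, "nodata": NODATA}
        ),
    )


def read_class_map(path: str | Path) -> ClassMap:
    arr, meta = _read_meta(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-band raster, got shape {arr.shape}")
    grid = _grid_from_meta(arr.shape, meta)
    return ClassMap(grid, arr.astype(np.int64), str(meta.get("epoch_label", "")))


def write_continuous(
    values: np.ndarray, grid: Grid, path: str | Path, nodata: float = -9999.0,
    extra_meta: Mapping[str, object] | None = None,
) -> None:
    """Write a float32 single- or multi-band raster (bands on axis 0)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta = {"nodata": nodata}
    if extra_meta:
        meta.update(extra_meta)
    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.float32),
        description=_grid_meta(grid, meta),
        photometric="minisblack",
    )


def read_continuous(path: str | Path) -> tuple[np.ndarray, Grid, dict]:
    arr, meta = _read_meta(Path(path))
    shape = arr.shape[-2:]
    return arr.astype(np.float64), _grid_from_meta(shape, meta), meta


def write_mask(mask: np.ndarray, grid: Grid, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.asarray(mask, dtype=np.uint8),
        description=_grid_meta(grid, {"kind": "mask"}),
    )


def read_mask(path: str | Path) -> tuple[np.ndarray, Grid]:
    arr, meta = _read_meta(Path(path))
    return arr.astype(bool), _grid_from_meta(arr.shape, meta)
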