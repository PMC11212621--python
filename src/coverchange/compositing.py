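"""QA-bitmask decoding, scene filtering, and per-pixel compositing.

Scenes carry a per-pixel quality bitmask whose low five bits flag fill,
dilated cloud, cirrus, cloud, and cloud shadow (the CFMASK / QA_PIXEL
layout of Landsat Collection 2).  A pixel observation is valid when none
of those bits is set.  One cloud-free image per epoch is built by
reducing, per pixel and band, the QA-valid observations across scenes;
the default reducer is the median (the mean is available as a config
switch) and the reducer name is recorded in the composite metadata.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from pathlib import Path

from .raster_core import (
    Grid,
    _require_same_grid,
    read_continuous,
    write_continuous,
)

__all__ = [
    "QA_BITS",
    "SpectralScene",
    "CompositeImage",
    "decode_qa",
    "qa_valid_mask",
    "filter_scenes",
    "composite",
    "read_scene_dir",
    "write_composite",
    "read_composite",
]

N_BANDS = 6

# bit index -> flag name, Collection-2 QA_PIXEL low bits
QA_BITS = {
    "fill": 0,
    "dilated_cloud": 1,
    "cirrus": 2,
    "cloud": 3,
    "cloud_shadow": 4,
}
_FLAG_MASK = sum(1 << b for b in QA_BITS.values())


@dataclass
class SpectralScene:
    """One dated multi-band reflectance acquisition with its QA band."""

    grid: Grid
    bands: np.ndarray  # (6, n_rows, n_cols) reflectance in [0, 1]
    qa: np.ndarray  # (n_rows, n_cols) integer bitmask
    acquisition_date: _dt.date = _dt.date(2000, 1, 1)
    cloud_cover_percent: float = 0.0

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        self.qa = np.asarray(self.qa)
        if self.bands.shape != (N_BANDS, *self.grid.shape):
            raise ValueError(
                f"bands shape {self.bands.shape} != (6, {self.grid.n_rows}, "
                f"{self.grid.n_cols})"
            )
        if self.qa.shape != self.grid.shape:
            raise ValueError("qa band does not share the scene grid")
        if not (0.0 <= self.cloud_cover_percent <= 100.0):
            raise ValueError("cloud_cover_percent outside [0, 100]")

    @property
    def valid(self) -> np.ndarray:
        return qa_valid_mask(self.qa)


@dataclass
class CompositeImage:
    """Cloud-free per-epoch image; bands defined only where ``valid``."""

    grid: Grid
    bands: np.ndarray  # (6, n_rows, n_cols)
    valid: np.ndarray  # (n_rows, n_cols) bool, >=1 unmasked observation
    epoch_label: str = ""
    reducer: str = "median"

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.bands.shape != (N_BANDS, *self.grid.shape):
            raise ValueError("composite bands shape mismatch")
        if self.valid.shape != self.grid.shape:
            raise ValueError("valid mask shape mismatch")


def decode_qa(qa_value: int) -> dict[str, bool]:
    """Decode one QA bitmask value into named flags plus overall validity.

    Unknown high bits are ignored; ``valid`` is true iff no low flag is set.
    """
    if qa_value < 0:
        raise ValueError("qa value must be non-negative")
    flags = {name: bool(qa_value >> bit & 1) for name, bit in QA_BITS.items()}
    flags["valid"] = not (qa_value & _FLAG_MASK)
    return flags


def qa_valid_mask(qa: np.ndarray) -> np.ndarray:
    """Vectorized validity: no fill/cloud/cirrus/dilated/shadow bit set."""
    return (np.asarray(qa).astype(np.int64) & _FLAG_MASK) == 0


def filter_scenes(
    scenes: list[SpectralScene],
    max_cloud_percent: float = 50.0,
    date_window: tuple[_dt.date, _dt.date] | None = None,
) -> list[SpectralScene]:
    """Keep scenes at or below the cloud threshold and inside the closed
    date window; raise if nothing survives."""
    kept = []
    for scene in scenes:
        if scene.cloud_cover_percent > max_cloud_percent:
            continue
        if date_window is not None:
            lo, hi = date_window
            if not (lo <= scene.acquisition_date <= hi):
                continue
        kept.append(scene)
    if not kept:
        raise ValueError("no scenes survive filtering")
    return kept


def composite(
    scenes: list[SpectralScene], reducer: str = "median", epoch_label: str = ""
) -> CompositeImage:
    """Per-pixel, per-band reduction of QA-valid observations.

    Even-count median is the mean of the two central values (numpy's
    convention).  Pixels with zero valid observations are marked invalid
    and carry NaN bands.
    """
    if not scenes:
        raise ValueError("composite requires at least one scene")
    if reducer not in ("median", "mean"):
        raise ValueError(f"unknown reducer {reducer!r}")
    grid = scenes[0].grid
    for s in scenes[1:]:
        _require_same_grid(grid, s.grid, "composite")

    stack = np.stack([s.bands for s in scenes])  # (n_scenes, 6, r, c)
    valid = np.stack([s.valid for s in scenes])  # (n_scenes, r, c)
    masked = np.where(valid[:, None, :, :], stack, np.nan)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixel stacks
        if reducer == "median":
            bands = np.nanmedian(masked, axis=0)
        else:
            bands = np.nanmean(masked, axis=0)
    any_valid = valid.any(axis=0)
    bands[:, ~any_valid] = np.nan
    return CompositeImage(grid, bands, any_valid, epoch_label, reducer)


def read_scene_dir(scenes_dir: str | Path, pattern: str = "scene_*") -> list[SpectralScene]:
    """Load scenes written by the world generator: ``<stem>.tif`` band stacks
    paired with ``<stem>_qa.tif`` QA rasters."""
    scenes_dir = Path(scenes_dir)
    scenes = []
    for band_path in sorted(scenes_dir.glob(f"{pattern}.tif")):
        if band_path.stem.endswith("_qa"):
            continue
        qa_path = band_path.with_name(band_path.stem + "_qa.tif")
        if not qa_path.exists():
            raise FileNotFoundError(f"missing QA raster for {band_path.name}")
        bands, grid, meta = read_continuous(band_path)
        qa, _, _ = read_continuous(qa_path)
        scenes.append(
            SpectralScene(
                grid=grid,
                bands=bands,
                qa=qa.astype(np.int64),
                acquisition_date=_dt.date.fromisoformat(
                    meta.get("acquisition_date", "2000-01-01")
                ),
                cloud_cover_percent=float(meta.get("cloud_cover_percent", 0.0)),
            )
        )
    if not scenes:
        raise FileNotFoundError(f"no scenes found under {scenes_dir}")
    return scenes


def write_composite(comp: CompositeImage, path: str | Path) -> None:
    """Invalid pixels are stored as NaN; reducer and epoch ride in metadata."""
    bands = comp.bands.copy()
    bands[:, ~comp.valid] = np.nan
    write_continuous(
        bands, comp.grid, path,
        extra_meta={"reducer": comp.reducer, "epoch_label": comp.epoch_label},
    )


def read_composite(path: str | Path) -> CompositeImage:
    bands, grid, meta = read_continuous(path)
    valid = ~np.isnan(bands[0])
    return CompositeImage(
        grid, bands, valid,
        epoch_label=str(meta.get("epoch_label", "")),
        reducer=str(meta.get("reducer", "median")),
    )
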