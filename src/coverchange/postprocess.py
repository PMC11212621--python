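"""Elevation-based correction of misclassified pixels.

Coastal classes predicted at implausible elevations are the canonical
misclassification a raster-calculator post-processing step targets: a
mangrove pixel at 150 m or a water pixel at 500 m is far more likely
mislabeled forest.  Rules are ordered (source class, comparator,
threshold in meters, target class) tuples applied in sequence; the
shipped defaults reassign mangrove above 20 m, wetland above 100 m, and
water above 400 m to forest and shrubs, and are fully overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster_core import CLASS_CODES, ClassMap, CoverClass, ElevationRaster

__all__ = ["ElevationRule", "DEFAULT_RULES", "apply_elevation_rules"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElevationRule:
    """Reassign source-class pixels whose elevation passes the comparison."""

    source_class: int
    comparator: str  # ">" or "<"
    threshold_m: float
    target_class: int

    def __post_init__(self) -> None:
        if self.source_class not in CLASS_CODES:
            raise ValueError(f"invalid class code {self.source_class}")
        if self.target_class not in CLASS_CODES:
            raise ValueError(f"invalid class code {self.target_class}")
        if self.source_class == self.target_class:
            raise ValueError("source and target class must differ")
        if self.comparator not in (">", "<"):
            raise ValueError("comparator must be '>' or '<'")

    def describe(self) -> str:
        src = CoverClass.from_code(self.source_class).label
        tgt = CoverClass.from_code(self.target_class).label
        return f"{src} {self.comparator} {self.threshold_m:g} m -> {tgt}"


DEFAULT_RULES = (
    ElevationRule(2, ">", 20.0, 1),   # mangrove above 20 m -> forest_shrubs
    ElevationRule(4, ">", 100.0, 1),  # wetland above 100 m -> forest_shrubs
    ElevationRule(7, ">", 400.0, 1),  # water above 400 m -> forest_shrubs
)


def apply_elevation_rules(
    class_map: ClassMap,
    elevation: ElevationRaster,
    rules: tuple[ElevationRule, ...] | list[ElevationRule] = DEFAULT_RULES,
) -> tuple[ClassMap, dict[str, int]]:
    """Apply rules in order; returns the corrected map and per-rule change counts.

    Nodata class pixels are untouched.  Pixels whose elevation is nodata are
    left unchanged and counted under ``"elevation_nodata_skipped"``.
    """
    if class_map.grid != elevation.grid:
        raise ValueError("grid mismatch between class map and elevation")
    values = class_map.values.astype(np.int64).copy()
    elev_ok = elevation.valid
    counts: dict[str, int] = {}
    skipped = 0
    for rule in rules:
        sel = values == rule.source_class
        if rule.comparator == ">":
            hit = elevation.values > rule.threshold_m
        else:
            hit = elevation.values < rule.threshold_m
        skipped += int((sel & ~elev_ok).sum())
        change = sel & hit & elev_ok
        values[change] = rule.target_class
        counts[rule.describe()] = int(change.sum())
        logger.info("rule %s changed %d pixel(s)", rule.describe(), counts[rule.describe()])
    counts["elevation_nodata_skipped"] = skipped
    return ClassMap(class_map.grid, values, class_map.epoch_label), counts
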