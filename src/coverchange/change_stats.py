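"""Composition tables, class-transition tables, and focal-class change maps.

Denominator conventions: a composition (how much of an area each class
covers, per epoch) is taken over that epoch's own classified pixels
inside the mask; a transition table (the 49 ordered source->destination
percentages, 7 "stable" plus 42 changes) is taken over pixels classified
in both epochs.  With that convention the marginal-reconstruction
identity — recovering each epoch's composition from the transition table
by row/column summation — is exact at count level.

Percentages are carried at full precision internally and rounded to two
decimals only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import (
    CLASS_CODES,
    CLASS_DISPLAY_NAMES,
    NODATA,
    ClassMap,
    apply_mask,
)

__all__ = [
    "CompositionTable",
    "TransitionTable",
    "FocalChangeMap",
    "composition",
    "transition_table",
    "reconstruct_marginals",
    "focal_change_map",
    "transition_row_label",
]

K = len(CLASS_CODES)


def transition_row_label(i: int, j: int) -> str:
    """Row label in the published style: 'Stable X' or 'X to y'."""
    if i == j:
        return f"Stable {CLASS_DISPLAY_NAMES[i].lower()}"
    src = CLASS_DISPLAY_NAMES[i]
    dst = CLASS_DISPLAY_NAMES[j].lower()
    return f"{src} to {dst}"


@dataclass
class CompositionTable:
    """Per-class percentage of classified area (0-100 scale)."""

    percentages: dict[int, float]  # class code -> percentage
    n_valid: int
    area_label: str = ""
    epoch_label: str = ""

    def to_series(self) -> pd.Series:
        return pd.Series(
            {CLASS_DISPLAY_NAMES[c]: self.percentages[c] for c in CLASS_CODES},
            name=f"{self.area_label} {self.epoch_label}".strip(),
        )


@dataclass
class TransitionTable:
    """49 ordered-pair percentages of both-epoch-valid area, with counts."""

    counts: np.ndarray  # (7, 7) pixel counts, rows = epoch-1 class
    area_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (K, K):
            raise ValueError("transition counts must be 7 x 7")
        if self.counts.sum() == 0:
            raise ValueError("empty both-valid pixel set")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.total

    def to_series(self) -> pd.Series:
        """Published row order: destination class outer, stable first."""
        pct = self.percentages
        out = {}
        for j in CLASS_CODES:
            out[transition_row_label(j, j)] = pct[j - 1, j - 1]
            for i in CLASS_CODES:
                if i != j:
                    out[transition_row_label(i, j)] = pct[i - 1, j - 1]
        return pd.Series(out, name=self.area_label)


@dataclass
class FocalChangeMap:
    """Categorical change raster for one focal class.

    Codes: 0 outside the both-valid area, 1 stable focal, 2 other
    (neither epoch focal), 100+c gain from class c, 200+c loss to class c.
    """

    grid: object
    values: np.ndarray
    focal_class: int

    def category_counts(self) -> dict[str, int]:
        focal = self.focal_class
        labels = {1: "stable_focal", 2: "other"}
        for c in CLASS_CODES:
            if c != focal:
                lab = CLASS_DISPLAY_NAMES[c].lower().replace(" ", "_")
                labels[100 + c] = f"gain_from_{lab}"
                labels[200 + c] = f"loss_to_{lab}"
        codes, counts = np.unique(self.values, return_counts=True)
        return {
            labels[int(k)]: int(n) for k, n in zip(codes, counts) if k in labels
        }


def _masked(class_map: ClassMap, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return class_map.values
    return apply_mask(class_map, mask).values


def composition(
    class_map: ClassMap, mask: np.ndarray | None = None,
    area_label: str = "",
) -> CompositionTable:
    """Percentage of each class among the classified pixels inside the mask."""
    values = _masked(class_map, mask)
    counts = np.bincount(values.ravel(), minlength=K + 1)[1:]
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no classified pixels inside mask")
    pct = 100.0 * counts / total
    return CompositionTable(
        {c: float(pct[c - 1]) for c in CLASS_CODES},
        n_valid=total,
        area_label=area_label,
        epoch_label=class_map.epoch_label,
    )


def transition_table(
    map1: ClassMap, map2: ClassMap, mask: np.ndarray | None = None,
    area_label: str = "",
) -> TransitionTable:
    """Ordered class-pair percentages over the both-epoch-valid area."""
    if map1.grid != map2.grid:
        raise ValueError("grid mismatch between epochs")
    v1 = _masked(map1, mask)
    v2 = _masked(map2, mask)
    both = (v1 != NODATA) & (v2 != NODATA)
    if not both.any():
        raise ValueError("no pixels classified in both epochs inside mask")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (v1[both].astype(np.int64) - 1, v2[both].astype(np.int64) - 1), 1)
    return TransitionTable(counts, area_label)


def reconstruct_marginals(tt: TransitionTable) -> tuple[dict[int, float], dict[int, float]]:
    """Epoch compositions implied by the transition table.

    Epoch-1 percentage of class i is its stable entry plus all i->j
    changes (row sum); epoch-2 of class j is stable plus all i->j gains
    (column sum).  Exact on counts by construction.
    """
    pct = tt.percentages
    epoch1 = {c: float(pct[c - 1].sum()) for c in CLASS_CODES}
    epoch2 = {c: float(pct[:, c - 1].sum()) for c in CLASS_CODES}
    return epoch1, epoch2


def focal_change_map(
    map1: ClassMap, map2: ClassMap, focal_class: int,
    mask: np.ndarray | None = None,
) -> FocalChangeMap:
    """Stable/gain/loss/other categorization of one class's change."""
    if focal_class not in CLASS_CODES:
        raise ValueError(f"invalid focal class {focal_class}")
    if map1.grid != map2.grid:
        raise ValueError("grid mismatch between epochs")
    v1 = _masked(map1, mask).astype(np.int64)
    v2 = _masked(map2, mask).astype(np.int64)
    both = (v1 != NODATA) & (v2 != NODATA)
    out = np.zeros(v1.shape, dtype=np.int64)
    is1 = v1 == focal_class
    is2 = v2 == focal_class
    out[both & is1 & is2] = 1
    out[both & ~is1 & ~is2] = 2
    gain = both & ~is1 & is2
    out[gain] = 100 + v1[gain]
    loss = both & is1 & ~is2
    out[loss] = 200 + v2[loss]
    return FocalChangeMap(map1.grid, out, focal_class)
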