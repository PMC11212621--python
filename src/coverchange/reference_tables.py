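"""Packaged reference tables and their cross-consistency computation.

The package ships a transcription of the composition and transition
tables of a published two-epoch (1985/2020) Landsat-based land-cover
survey of the Cuban archipelago: per-class area percentages for four
areas of interest in both epochs, and the 49 ordered class-pair change
percentages per area.  The fixtures are frozen with sha256 checksums so
they cannot drift silently, and the marginal-reconstruction identity —
summing each transition column block back into per-epoch compositions —
is the consistency computation that validates the transcription against
the printed values to within their two-decimal rounding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .change_stats import reconstruct_marginals  # noqa: F401  (rule documented here)
from .raster_core import CLASS_CODES, CLASS_DISPLAY_NAMES

__all__ = ["AREAS", "ReferenceTables", "load_reference_tables", "consistency_report"]

AREAS = ("cuba", "protected", "od", "od_in_protected")

_CHECKSUMS = {
    "reference_composition.csv": (
        "0832c7a94206dba05736e0aea7a487c38f859b491672333a5bb0b63fc23a9827"
    ),
    "reference_transitions.csv": (
        "981ea2dea8b408af0c96174e9f96cb910d6ad560338e1f0b0e4397235563dd9e"
    ),
}

SOURCE = (
    "Transcribed from the printed tables of a published two-epoch (1985/2020) "
    "Landsat-based land-cover change survey of the Cuban archipelago "
    "(seven cover classes, four areas of interest)."
)


@dataclass
class ReferenceTables:
    """Long-form composition table and per-area 7x7 transition matrices."""

    composition: pd.DataFrame  # class_code, class_label, area, epoch, percentage
    transitions: pd.DataFrame  # from_code, to_code, label, <area columns>
    source: str = SOURCE

    def composition_value(self, class_code: int, area: str, epoch: int) -> float:
        df = self.composition
        sel = (
            (df["class_code"] == class_code)
            & (df["area"] == area)
            & (df["epoch"] == epoch)
        )
        return float(df.loc[sel, "percentage"].iloc[0])

    def transition_matrix(self, area: str) -> np.ndarray:
        """7x7 percentage matrix for one area; rows = epoch-1 class."""
        if area not in AREAS:
            raise ValueError(f"unknown area {area!r}")
        mat = np.zeros((7, 7))
        for _, row in self.transitions.iterrows():
            mat[int(row["from_code"]) - 1, int(row["to_code"]) - 1] = row[area]
        return mat

    def transition_value(self, label: str, area: str) -> float:
        sel = self.transitions["label"] == label
        if not sel.any():
            raise ValueError(f"unknown transition row {label!r}")
        return float(self.transitions.loc[sel, area].iloc[0])


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("coverchange.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"corrupted fixture {name}: checksum {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_reference_tables() -> ReferenceTables:
    """Load the packaged transcription, verifying the frozen checksums."""
    comp = _read_checked("reference_composition.csv")
    trans = _read_checked("reference_transitions.csv")
    if len(trans) != 49 or len(comp) != 56:
        raise RuntimeError("fixture shape mismatch")
    return ReferenceTables(comp, trans)


def consistency_report(
    tables: ReferenceTables | None = None, outlier_threshold: float = 0.05
) -> pd.DataFrame:
    """Reconstructed vs printed composition for every (area, epoch, class).

    Epoch-1 composition of class i is the transition row sum; epoch-2 of
    class j the column sum.  Differences beyond ``outlier_threshold``
    percentage points (beyond two-decimal rounding) are flagged.
    """
    if tables is None:
        tables = load_reference_tables()
    rows = []
    for area in AREAS:
        mat = tables.transition_matrix(area)
        epoch1 = mat.sum(axis=1)
        epoch2 = mat.sum(axis=0)
        for code in CLASS_CODES:
            for epoch, recon in ((1985, epoch1[code - 1]), (2020, epoch2[code - 1])):
                printed = tables.composition_value(code, area, epoch)
                diff = abs(recon - printed)
                rows.append(
                    {
                        "area": area,
                        "epoch": epoch,
                        "class": CLASS_DISPLAY_NAMES[code],
                        "reconstructed": round(float(recon), 4),
                        "printed": printed,
                        "abs_diff": round(float(diff), 4),
                        "rounding_outlier": diff > outlier_threshold,
                    }
                )
    return pd.DataFrame(rows)
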