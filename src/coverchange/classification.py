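"""ROI sampling/splitting, feature extraction, and supervised classification.

The workflow mirrors standard practice for supervised land-cover mapping:
labeled regions of interest (ROIs) are sampled per class from a reference
map, split 70/30 into training and testing strata, the six composite
reflectance bands at the training pixels feed a random-forest classifier,
and the fitted model predicts a class for every valid composite pixel.

Default ROI counts are 300 for forest and shrubs, 50 for bare soil, and
100 for each remaining class (850 total).  ROIs here are single pixels
sampled without replacement from a reference map, which preserves the
statistical structure of manually digitized polygon ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .compositing import N_BANDS, CompositeImage
from .raster_core import CLASS_CODES, NODATA, ClassMap, Grid

__all__ = [
    "DEFAULT_ROI_COUNTS",
    "DEFAULT_VALIDATION_COUNTS",
    "ROISet",
    "ClassifierModel",
    "sample_rois",
    "split_rois",
    "extract_features",
    "train_classifier",
    "predict_map",
]

logger = logging.getLogger(__name__)

BAND_NAMES = tuple(f"B{i}" for i in range(1, N_BANDS + 1))

DEFAULT_ROI_COUNTS = {1: 300, 2: 100, 3: 50, 4: 100, 5: 100, 6: 100, 7: 100}
# validation: 100 per class except water bodies at 50
DEFAULT_VALIDATION_COUNTS = {1: 100, 2: 100, 3: 100, 4: 100, 5: 100, 6: 100, 7: 50}


@dataclass
class ROISet:
    """Labeled sample pixels with optional train/test roles.

    Backed by a DataFrame with columns row, col, class_code, role.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"row", "col", "class_code"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"ROI records need columns {sorted(required)}")
        if "role" not in self.records.columns:
            self.records = self.records.assign(role="")
        dup = self.records.duplicated(subset=["row", "col"])
        if dup.any():
            raise ValueError("duplicate (row, col) in ROI set")
        bad = set(self.records["class_code"]) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"invalid class code {sorted(bad)[0]} in ROI set")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, role: str) -> "ROISet":
        return ROISet(
            self.records[self.records["role"] == role].reset_index(drop=True),
            self.provenance,
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "ROISet":
        return cls(pd.read_csv(path), provenance)


@dataclass
class ClassifierModel:
    """Fitted model plus the metadata needed for auditable predictions."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    class_codes: tuple[int, ...]
    n_per_class: dict[int, int]
    seed: int
    hyperparameters: dict


def sample_rois(
    reference: ClassMap,
    counts_per_class: dict[int, int] | None = None,
    seed: int = 0,
    provenance: str = "reference map",
) -> ROISet:
    """Uniform random pixels without replacement within each class stratum."""
    counts = dict(DEFAULT_ROI_COUNTS if counts_per_class is None else counts_per_class)
    rng = np.random.default_rng(seed)
    frames = []
    for code, n in sorted(counts.items()):
        if n == 0:
            continue
        rows, cols = np.nonzero(reference.values == code)
        if rows.size == 0:
            raise ValueError(f"class {code} absent from reference map")
        if rows.size < n:
            raise ValueError(
                f"class {code} stratum has {rows.size} pixels, {n} requested"
            )
        pick = rng.choice(rows.size, size=n, replace=False)
        frames.append(
            pd.DataFrame(
                {"row": rows[pick], "col": cols[pick], "class_code": code}
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return ROISet(records.assign(role=""), provenance)


def split_rois(rois: ROISet, train_fraction: float = 0.7, seed: int = 0) -> ROISet:
    """Stratified random train/test split.

    Per class, the training count is round-half-up of count x fraction;
    the remainder goes to test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records = rois.records.copy()
    records["role"] = ""
    for code, idx in records.groupby("class_code").groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError(f"class {code} has {idx.size} ROIs, cannot split")
        n_train = int(np.floor(idx.size * train_fraction + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        records.loc[perm[:n_train], "role"] = "train"
        records.loc[perm[n_train:], "role"] = "test"
    return ROISet(records, rois.provenance)


def extract_features(
    composite: CompositeImage, rois: ROISet
) -> tuple[np.ndarray, np.ndarray, ROISet]:
    """One feature row (six band reflectances) per ROI at a valid pixel.

    ROIs on invalid composite pixels are dropped with a logged warning.
    Returns (features, labels, kept ROI set).
    """
    r = rois.records["row"].to_numpy()
    c = rois.records["col"].to_numpy()
    ok = composite.valid[r, c]
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("dropping %d ROI(s) on invalid composite pixels", n_drop)
    kept = rois.records[ok].reset_index(drop=True)
    feats = composite.bands[:, kept["row"], kept["col"]].T
    return (
        np.ascontiguousarray(feats),
        kept["class_code"].to_numpy(),
        ROISet(kept, rois.provenance),
    )


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the random-forest classifier (100 trees by default)."""
    labels = np.asarray(labels)
    codes = tuple(int(c) for c in np.unique(labels))
    if len(codes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    hp = {"n_estimators": 100}
    hp.update(hyperparameters or {})
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    model.fit(np.asarray(features), labels)
    counts = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    return ClassifierModel(
        model=model,
        feature_names=BAND_NAMES,
        class_codes=codes,
        n_per_class=counts,
        seed=seed,
        hyperparameters=hp,
    )


def predict_map(model: ClassifierModel, composite: CompositeImage) -> ClassMap:
    """Per-pixel predicted class; invalid composite pixels become nodata."""
    if composite.bands.shape[0] != len(model.feature_names):
        raise ValueError(
            f"composite has {composite.bands.shape[0]} bands, model expects "
            f"{len(model.feature_names)}"
        )
    out = np.zeros(composite.grid.shape, dtype=np.int64)
    valid = composite.valid
    if valid.any():
        feats = composite.bands[:, valid].T
        out[valid] = model.model.predict(np.ascontiguousarray(feats))
    out[~valid] = NODATA
    return ClassMap(composite.grid, out, composite.epoch_label)
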