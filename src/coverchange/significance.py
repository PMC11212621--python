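"""Bootstrap significance test for per-class composition change.

The observed statistic per class c is the composition change
Delta_c = pct_c(epoch 2) - pct_c(epoch 1) in percentage points, over each
epoch's classified pixels inside the mask.  The null distribution is
built by randomly re-assigning a category to every valid pixel in both
epochs, independently, for ``n_reps`` replicates (1000 by default), and
recomputing Delta_c.  Categories are drawn either from the pooled
two-epoch empirical class distribution (``pooled``, the default) or
uniformly over the seven classes (``uniform``).

A class's change is significantly non-random when the observed Delta_c
lies strictly above the 99th percentile or strictly below the 1st
percentile of its null distribution (linear-interpolation empirical
percentiles).  An empirical two-sided p-value with the add-one
convention, p = (1 + #{|Delta_null| >= |Delta_obs|}) / (n_reps + 1), is
reported alongside; it cannot be exactly zero at finite replicates.

Because pixels are re-assigned independently, each replicate's per-epoch
class counts are exactly one multinomial draw of the epoch's valid-pixel
count; the implementation samples those counts directly, which is
distributionally identical to materializing per-pixel random maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change_stats import composition
from .raster_core import CLASS_CODES, CLASS_DISPLAY_NAMES, NODATA, ClassMap, apply_mask

__all__ = ["ChangeSignificance", "bootstrap_change_test"]

K = len(CLASS_CODES)


@dataclass
class ChangeSignificance:
    """Observed per-class change with its bootstrap null summary."""

    observed_delta: dict[int, float]  # percentage points
    p1: dict[int, float]
    p99: dict[int, float]
    p_value: dict[int, float]
    significant: dict[int, bool]
    n_reps: int
    seed: int
    null_model: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in CLASS_CODES:
            rows.append(
                {
                    "class": CLASS_DISPLAY_NAMES[c],
                    "observed_delta_pp": self.observed_delta[c],
                    "null_p1": self.p1[c],
                    "null_p99": self.p99[c],
                    "p_value": self.p_value[c],
                    "significant": self.significant[c],
                }
            )
        df = pd.DataFrame(rows)
        df.attrs.update(
            n_reps=self.n_reps, seed=self.seed, null_model=self.null_model
        )
        return df


def _class_counts(values: np.ndarray) -> np.ndarray:
    return np.bincount(values.ravel(), minlength=K + 1)[1:]


def bootstrap_change_test(
    map1: ClassMap,
    map2: ClassMap,
    mask: np.ndarray | None = None,
    n_reps: int = 1000,
    null_model: str = "pooled",
    seed: int = 0,
) -> ChangeSignificance:
    """Bootstrap test of whether each class's composition change is non-random."""
    if null_model not in ("pooled", "uniform"):
        raise ValueError("null_model must be 'pooled' or 'uniform'")
    if n_reps < 100:
        warnings.warn(
            f"n_reps={n_reps} is low; percentile estimates will be coarse",
            stacklevel=2,
        )
    if map1.grid != map2.grid:
        raise ValueError("grid mismatch between epochs")
    v1 = map1.values if mask is None else apply_mask(map1, mask).values
    v2 = map2.values if mask is None else apply_mask(map2, mask).values
    c1 = _class_counts(v1[v1 != NODATA])
    c2 = _class_counts(v2[v2 != NODATA])
    n1, n2 = int(c1.sum()), int(c2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("empty mask: no classified pixels in one of the epochs")

    obs_delta = 100.0 * (c2 / n2 - c1 / n1)

    if null_model == "pooled":
        p = (c1 + c2) / (n1 + n2)
    else:
        p = np.full(K, 1.0 / K)

    rng = np.random.default_rng(seed)
    null1 = rng.multinomial(n1, p, size=n_reps) / n1
    null2 = rng.multinomial(n2, p, size=n_reps) / n2
    null_delta = 100.0 * (null2 - null1)  # (n_reps, K)

    p1 = np.percentile(null_delta, 1, axis=0)
    p99 = np.percentile(null_delta, 99, axis=0)
    pvals = (1 + (np.abs(null_delta) >= np.abs(obs_delta)[None, :]).sum(axis=0)) / (
        n_reps + 1
    )
    sig = (obs_delta > p99) | (obs_delta < p1)

    codes = CLASS_CODES
    return ChangeSignificance(
        observed_delta={c: float(obs_delta[c - 1]) for c in codes},
        p1={c: float(p1[c - 1]) for c in codes},
        p99={c: float(p99[c - 1]) for c in codes},
        p_value={c: float(pvals[c - 1]) for c in codes},
        significant={c: bool(sig[c - 1]) for c in codes},
        n_reps=n_reps,
        seed=seed,
        null_model=null_model,
    )
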