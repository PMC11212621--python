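"""End-to-end orchestration: simulate -> composite -> classify ->
postprocess -> assess -> change -> significance.

A :class:`RunConfig` carries every stage's parameters with mandatory
seeds, is schema-validated before any computation, and is serialized
into the output directory together with its hash, which every output
CSV names in a leading comment line — re-running from the serialized
config reproduces the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change_stats, classification, significance
from .accuracy import assess
from .compositing import composite, filter_scenes, write_composite
from .postprocess import DEFAULT_RULES, ElevationRule, apply_elevation_rules
from .raster_core import CLASS_DISPLAY_NAMES, Grid, write_class_map
from .synthetic_world import WorldBundle, WorldSpec, generate_world, write_world

__all__ = ["RunConfig", "run_all", "write_csv_with_hash"]

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline parameters; seeds are mandatory, never defaulted silently."""

    seed: int
    grid_size: int = 128
    world: dict = field(default_factory=dict)  # WorldSpec overrides
    max_cloud_percent: float = 50.0
    reducer: str = "median"
    roi_counts: dict[int, int] = field(
        default_factory=lambda: dict(classification.DEFAULT_ROI_COUNTS)
    )
    validation_counts: dict[int, int] = field(
        default_factory=lambda: dict(classification.DEFAULT_VALIDATION_COUNTS)
    )
    train_fraction: float = 0.7
    n_trees: int = 100
    elevation_rules: list[tuple] = field(
        default_factory=lambda: [
            (r.source_class, r.comparator, r.threshold_m, r.target_class)
            for r in DEFAULT_RULES
        ]
    )
    n_reps: int = 1000
    null_model: str = "pooled"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.reducer not in ("median", "mean"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.null_model not in ("pooled", "uniform"):
            raise ValueError(f"unknown null model {self.null_model!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {self.schema_version}")
        self.roi_counts = {int(k): int(v) for k, v in self.roi_counts.items()}
        self.validation_counts = {
            int(k): int(v) for k, v in self.validation_counts.items()
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text)
        doc["elevation_rules"] = [tuple(r) for r in doc.get("elevation_rules", [])]
        return cls(**doc)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def world_spec(self) -> WorldSpec:
        overrides = dict(self.world)
        grid = overrides.pop("grid", None) or Grid(self.grid_size, self.grid_size)
        return WorldSpec(grid=grid, seed=self.seed, **overrides)

    def rules(self) -> tuple[ElevationRule, ...]:
        return tuple(ElevationRule(s, cmp_, thr, t) for s, cmp_, thr, t in self.elevation_rules)


def write_csv_with_hash(df: pd.DataFrame, path: Path, config_hash: str, **kwargs) -> None:
    """CSV with a leading comment naming the generating config hash."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, **kwargs)


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    root = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline on a synthetic world; returns key results.

    Writes truth/predicted maps, per-area composition, transition,
    accuracy, and significance CSVs, the serialized config, and a log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    chash = config.config_hash
    seeds = _stage_seeds(config.seed)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("coverchange")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    results: dict = {"config_hash": chash}
    try:
        # --- simulate -----------------------------------------------------
        spec = config.world_spec()
        bundle = generate_world(spec)
        write_world(bundle, out / "world")
        logger.info("stage simulate: grid %s, %d scenes/epoch",
                    spec.grid.shape, spec.scenes_per_epoch)

        # --- composite ----------------------------------------------------
        composites = []
        for scenes, label in (
            (bundle.scenes_1, spec.epoch_labels[0]),
            (bundle.scenes_2, spec.epoch_labels[1]),
        ):
            kept = filter_scenes(scenes, config.max_cloud_percent)
            comp = composite(kept, config.reducer, label)
            write_composite(comp, out / f"composite_{label}.tif")
            logger.info(
                "stage composite %s: %d/%d scenes kept, %d/%d pixels valid",
                label, len(kept), len(scenes), int(comp.valid.sum()),
                comp.grid.n_pixels,
            )
            composites.append(comp)

        # --- classify + postprocess + assess, per epoch -------------------
        predicted = []
        accuracy_rows = []
        for epoch_i, (comp, truth) in enumerate(
            zip(composites, (bundle.truth_map_1, bundle.truth_map_2))
        ):
            rois = classification.sample_rois(
                truth, config.roi_counts, seed=seeds[0] + epoch_i
            )
            rois = classification.split_rois(
                rois, config.train_fraction, seed=seeds[1] + epoch_i
            )
            feats, labels, kept = classification.extract_features(
                comp, rois.subset("train")
            )
            model = classification.train_classifier(
                feats, labels, {"n_estimators": config.n_trees},
                seed=seeds[2] + epoch_i,
            )
            pred = classification.predict_map(model, comp)
            pred, rule_counts = apply_elevation_rules(
                pred, bundle.elevation, config.rules()
            )
            write_class_map(pred, out / f"predicted_{comp.epoch_label}.tif")
            logger.info("stage classify %s: rule changes %s",
                        comp.epoch_label, rule_counts)

            validation = classification.sample_rois(
                truth, config.validation_counts, seed=seeds[3] + epoch_i,
                provenance="validation",
            )
            cm, report = assess(pred, validation)
            write_csv_with_hash(
                cm.to_frame(), out / f"confusion_{comp.epoch_label}.csv", chash
            )
            accuracy_rows.append(
                {
                    "epoch": comp.epoch_label,
                    "overall_accuracy": report.overall_accuracy,
                    "kappa": report.kappa,
                    **{
                        f"producer_{CLASS_DISPLAY_NAMES[c]}": v
                        for c, v in report.per_class.items()
                    },
                }
            )
            predicted.append(pred)
            results[f"accuracy_{comp.epoch_label}"] = report
        write_csv_with_hash(
            pd.DataFrame(accuracy_rows), out / "accuracy.csv", chash, index=False
        )

        # --- change + significance per area of interest -------------------
        map1, map2 = predicted
        comp_cols = {}
        trans_cols = {}
        sig_frames = []
        for area, mask in bundle.masks.items():
            c1 = change_stats.composition(map1, mask, area_label=area)
            c2 = change_stats.composition(map2, mask, area_label=area)
            comp_cols[(area, map1.epoch_label)] = c1.to_series()
            comp_cols[(area, map2.epoch_label)] = c2.to_series()
            tt = change_stats.transition_table(map1, map2, mask, area_label=area)
            trans_cols[area] = tt.to_series()
            sig = significance.bootstrap_change_test(
                map1, map2, mask, n_reps=config.n_reps,
                null_model=config.null_model, seed=seeds[4],
            )
            frame = sig.to_frame()
            frame.insert(0, "area", area)
            sig_frames.append(frame)
            results[f"significance_{area}"] = sig
            results[f"transition_{area}"] = tt
        comp_df = pd.DataFrame(comp_cols)
        comp_df.columns = [f"{a} {e}" for a, e in comp_df.columns]
        write_csv_with_hash(
            comp_df.round(2), out / "composition.csv", chash,
            index_label="Classification type",
        )
        write_csv_with_hash(
            pd.DataFrame(trans_cols).round(2), out / "transitions.csv", chash,
            index_label="Type of change",
        )
        write_csv_with_hash(
            pd.concat(sig_frames, ignore_index=True).round(4),
            out / "significance.csv", chash, index=False,
        )
        results["bundle"] = bundle
        logger.info("run complete: outputs in %s", out)
        return results
    except Exception as exc:  # pragma: no cover - abort contract
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()
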