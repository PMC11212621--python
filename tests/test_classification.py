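"""ROI sampling/splitting, feature extraction, and the classifier."""

import logging

import numpy as np
import pytest

from coverchange import (
    Grid,
    WorldSpec,
    composite,
    filter_scenes,
    predict_map,
    sample_rois,
    split_rois,
    train_classifier,
)
from coverchange.classification import (
    DEFAULT_ROI_COUNTS,
    ROISet,
    extract_features,
)
from coverchange.raster_core import NODATA
from coverchange.synthetic_world import generate_truth_map, render_scenes


@pytest.fixture(scope="module")
def separable_setup():
    """Noise-free, cloud-free world: classes perfectly separable."""
    spec = WorldSpec(grid=Grid(64, 64), seed=21, noise_sd=0.0, cloud_fraction=0.0)
    truth = generate_truth_map(spec)
    comp = composite(render_scenes(truth, spec, 0, seed=1), epoch_label="1985")
    return spec, truth, comp


class TestSampleRois:
    def test_default_counts_total_850(self, bundle):
        rois = sample_rois(bundle.truth_map_1, seed=0)
        assert len(rois) == 850
        per_class = rois.records["class_code"].value_counts().to_dict()
        assert per_class == DEFAULT_ROI_COUNTS

    def test_zero_count_class_absent(self, bundle):
        counts = {**DEFAULT_ROI_COUNTS, 5: 0}
        rois = sample_rois(bundle.truth_map_1, counts, seed=0)
        assert 5 not in set(rois.records["class_code"])

    def test_same_seed_identical(self, bundle):
        a = sample_rois(bundle.truth_map_1, seed=3).records
        b = sample_rois(bundle.truth_map_1, seed=3).records
        assert a.equals(b)

    def test_labels_match_reference_map(self, bundle):
        rois = sample_rois(bundle.truth_map_1, seed=1)
        r = rois.records
        assert np.array_equal(
            bundle.truth_map_1.values[r["row"], r["col"]], r["class_code"]
        )

    def test_oversized_request_raises(self, checker_map):
        with pytest.raises(ValueError, match="stratum"):
            sample_rois(checker_map, {1: 1000}, seed=0)


class TestSplitRois:
    def test_70_30_on_100(self, bundle):
        rois = sample_rois(bundle.truth_map_1, {2: 100}, seed=0)
        split = split_rois(rois, seed=1)
        roles = split.records["role"].value_counts()
        assert roles["train"] == 70 and roles["test"] == 30

    def test_round_half_up_on_50(self, bundle):
        rois = sample_rois(bundle.truth_map_1, {3: 50}, seed=0)
        split = split_rois(rois, seed=1)
        roles = split.records["role"].value_counts()
        assert roles["train"] == 35 and roles["test"] == 15

    def test_partition(self, bundle):
        rois = sample_rois(bundle.truth_map_1, seed=2)
        split = split_rois(rois, seed=3)
        assert set(split.records["role"]) == {"train", "test"}
        assert len(split.subset("train")) + len(split.subset("test")) == len(rois)

    def test_stratified_per_class(self, bundle):
        split = split_rois(sample_rois(bundle.truth_map_1, seed=4), seed=5)
        train = split.subset("train").records["class_code"].value_counts()
        assert train[1] == 210  # round(300 * 0.7)
        assert train[3] == 35

    def test_tiny_class_cannot_split(self):
        import pandas as pd

        rois = ROISet(pd.DataFrame({"row": [0], "col": [0], "class_code": [1]}))
        with pytest.raises(ValueError, match="cannot split"):
            split_rois(rois)


class TestExtractFeatures:
    def test_all_valid_keeps_every_row(self, separable_setup):
        _, truth, comp = separable_setup
        rois = sample_rois(truth, seed=0)
        feats, labels, kept = extract_features(comp, rois)
        assert feats.shape == (850, 6)
        assert len(kept) == 850

    def test_values_are_composite_lookups(self, separable_setup):
        _, truth, comp = separable_setup
        rois = sample_rois(truth, {1: 10}, seed=0)
        feats, _, kept = extract_features(comp, rois)
        r = kept.records
        np.testing.assert_array_equal(
            feats, comp.bands[:, r["row"], r["col"]].T
        )

    def test_invalid_pixel_dropped_with_warning(self, separable_setup, caplog):
        _, truth, comp = separable_setup
        comp2 = type(comp)(comp.grid, comp.bands, comp.valid.copy(), "x")
        rois = sample_rois(truth, {1: 10}, seed=0)
        r0, c0 = rois.records.loc[0, ["row", "col"]]
        comp2.valid[r0, c0] = False
        with caplog.at_level(logging.WARNING, logger="coverchange.classification"):
            feats, _, kept = extract_features(comp2, rois)
        assert len(kept) == 9
        assert "dropping 1 ROI" in caplog.text


class TestClassifier:
    def test_separable_data_trains_perfectly(self, separable_setup):
        _, truth, comp = separable_setup
        rois = split_rois(sample_rois(truth, seed=0), seed=1)
        feats, labels, _ = extract_features(comp, rois.subset("train"))
        model = train_classifier(feats, labels, seed=0)
        assert (model.model.predict(feats) == labels).all()

    def test_prediction_recovers_truth_in_separable_limit(self, separable_setup):
        _, truth, comp = separable_setup
        rois = sample_rois(truth, seed=0)
        feats, labels, _ = extract_features(comp, rois)
        model = train_classifier(feats, labels, seed=0)
        pred = predict_map(model, comp)
        assert np.array_equal(pred.values, truth.values)

    def test_same_seed_identical_predictions(self, separable_setup):
        _, truth, comp = separable_setup
        rois = sample_rois(truth, seed=0)
        feats, labels, _ = extract_features(comp, rois)
        a = predict_map(train_classifier(feats, labels, seed=5), comp)
        b = predict_map(train_classifier(feats, labels, seed=5), comp)
        assert np.array_equal(a.values, b.values)

    def test_invalid_pixels_become_nodata(self, separable_setup):
        _, truth, comp = separable_setup
        comp2 = type(comp)(comp.grid, comp.bands, comp.valid.copy(), "x")
        comp2.valid[:5] = False
        rois = sample_rois(truth, seed=0)
        feats, labels, kept = extract_features(comp2, rois)
        pred = predict_map(train_classifier(feats, labels, seed=0), comp2)
        assert np.all(pred.values[:5] == NODATA)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(np.zeros((10, 6)), np.ones(10, dtype=int))

    def test_noisy_default_regime_test_accuracy_above_09(self, bundle):
        comp = composite(filter_scenes(bundle.scenes_1), epoch_label="1985")
        rois = split_rois(sample_rois(bundle.truth_map_1, seed=0), seed=1)
        f_tr, l_tr, _ = extract_features(comp, rois.subset("train"))
        model = train_classifier(f_tr, l_tr, seed=0)
        f_te, l_te, _ = extract_features(comp, rois.subset("test"))
        acc = (model.model.predict(f_te) == l_te).mean()
        assert acc > 0.9

    def test_cloud_free_default_noise_test_accuracy_above_095(self):
        spec = WorldSpec(grid=Grid(96, 96), seed=13, cloud_fraction=0.0)
        truth = generate_truth_map(spec)
        comp = composite(render_scenes(truth, spec, 0, seed=1), epoch_label="1985")
        rois = split_rois(sample_rois(truth, seed=0), seed=1)
        f_tr, l_tr, _ = extract_features(comp, rois.subset("train"))
        model = train_classifier(f_tr, l_tr, seed=0)
        f_te, l_te, _ = extract_features(comp, rois.subset("test"))
        acc = (model.model.predict(f_te) == l_te).mean()
        assert acc > 0.95
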