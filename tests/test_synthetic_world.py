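"""Synthetic-world generator: determinism, clumping, the Markov change
process, scene rendering with QA-flagged clouds, and nested masks."""

import numpy as np
import pytest

from coverchange import Grid, WorldSpec, generate_world
from coverchange.compositing import QA_BITS, qa_valid_mask
from coverchange.raster_core import NODATA
from coverchange.synthetic_world import (
    evolve_truth_map,
    generate_masks,
    generate_truth_map,
    render_scenes,
)


def _join_count(values):
    """Number of horizontally/vertically adjacent same-class pixel pairs."""
    same_h = values[:, :-1] == values[:, 1:]
    same_v = values[:-1, :] == values[1:, :]
    return int(same_h.sum() + same_v.sum())


class TestTruthMap:
    def test_same_seed_identical(self):
        spec = WorldSpec(grid=Grid(64, 64), seed=11)
        a = generate_truth_map(spec)
        b = generate_truth_map(spec)
        assert np.array_equal(a.values, b.values)

    def test_equal_proportions_within_three_points(self):
        spec = WorldSpec(grid=Grid(256, 256), seed=5)
        cmap = generate_truth_map(spec)
        props = np.bincount(cmap.values.ravel(), minlength=8)[1:] / cmap.grid.n_pixels
        assert np.all(np.abs(props - 1 / 7) < 0.03)

    def test_larger_patch_scale_is_more_clumped(self):
        fine = generate_truth_map(WorldSpec(grid=Grid(128, 128), patch_scale=1, seed=3))
        coarse = generate_truth_map(WorldSpec(grid=Grid(128, 128), patch_scale=32, seed=3))
        assert _join_count(coarse.values) > _join_count(fine.values)

    def test_rejects_nonpositive_patch_scale(self):
        spec = WorldSpec(grid=Grid(16, 16), seed=0)
        spec.patch_scale = 0.0
        with pytest.raises(ValueError, match="patch_scale"):
            generate_truth_map(spec)


class TestEvolve:
    def test_identity_kernel_preserves_map(self, bundle):
        out = evolve_truth_map(bundle.truth_map_1, np.eye(7), seed=1)
        assert np.array_equal(out.values, bundle.truth_map_1.values)

    def test_transition_fraction_matches_kernel_mass(self):
        spec = WorldSpec(grid=Grid(128, 128), seed=9)
        map1 = generate_truth_map(spec)
        map2 = evolve_truth_map(map1, spec.transition_kernel, seed=2)
        ag = map1.values == 6
        n = int(ag.sum())
        frac = float((map2.values[ag] == 1).mean())
        sigma = np.sqrt(0.35 * 0.65 / n)
        assert abs(frac - 0.35) < 3 * sigma

    def test_absorbing_column_maps_everything_to_it(self, bundle):
        kernel = np.zeros((7, 7))
        kernel[:, 6] = 1.0
        out = evolve_truth_map(bundle.truth_map_1, kernel, seed=3)
        assert np.all(out.values[bundle.truth_map_1.valid] == 7)

    def test_nodata_preserved(self, checker_map):
        out = evolve_truth_map(checker_map, np.eye(7), seed=0)
        assert np.array_equal(out.values == NODATA, checker_map.values == NODATA)

    def test_rejects_non_stochastic_kernel(self, checker_map):
        with pytest.raises(ValueError, match="row-stochastic"):
            evolve_truth_map(checker_map, np.full((7, 7), 0.5), seed=0)


class TestRenderScenes:
    def test_noise_free_cloud_free_hits_class_means_exactly(self):
        spec = WorldSpec(grid=Grid(32, 32), seed=4, noise_sd=0.0,
                         cloud_fraction=0.0, scenes_per_epoch=1)
        cmap = generate_truth_map(spec)
        (scene,) = render_scenes(cmap, spec, epoch=0, seed=1)
        expected = spec.class_spectra[cmap.values - 1].transpose(2, 0, 1)
        np.testing.assert_array_equal(scene.bands, expected)
        assert scene.cloud_cover_percent == 0.0

    def test_realized_cloud_fraction_near_request(self):
        spec = WorldSpec(grid=Grid(128, 128), seed=6, cloud_fraction=0.3)
        scenes = render_scenes(generate_truth_map(spec), spec, epoch=0, seed=2)
        for scene in scenes:
            assert 20.0 <= scene.cloud_cover_percent <= 40.0

    def test_qa_bits_exactly_where_reflectance_overwritten(self):
        spec = WorldSpec(grid=Grid(64, 64), seed=8, noise_sd=0.0,
                         cloud_fraction=0.2, scenes_per_epoch=1)
        cmap = generate_truth_map(spec)
        (scene,) = render_scenes(cmap, spec, epoch=0, seed=3)
        expected = spec.class_spectra[cmap.values - 1].transpose(2, 0, 1)
        overwritten = np.any(scene.bands != expected, axis=0)
        flagged = ~qa_valid_mask(scene.qa)
        assert np.array_equal(overwritten, flagged)
        cloud_bit = (scene.qa >> QA_BITS["cloud"] & 1).astype(bool)
        shadow_bit = (scene.qa >> QA_BITS["cloud_shadow"] & 1).astype(bool)
        assert np.array_equal(flagged, cloud_bit | shadow_bit)

    def test_header_matches_cloud_bit_fraction(self, bundle):
        for scene in bundle.scenes_1:
            cloud = (scene.qa >> QA_BITS["cloud"] & 1).mean()
            assert scene.cloud_cover_percent == pytest.approx(100 * cloud)


class TestMasks:
    def test_intersection_invariant(self, bundle):
        m = bundle.masks
        assert np.array_equal(m.od_in_protected, m.od & m.protected)

    def test_protected_fraction_near_default(self, bundle):
        frac = bundle.masks.protected.mean()
        assert abs(frac - 0.17) < 0.05

    def test_od_overlap_fraction_is_positive_and_reported(self, bundle):
        m = bundle.masks
        overlap = m.od_in_protected.sum() / m.od.sum()
        # emulates the study's ~24% OD-inside-protected overlap regime
        assert 0.0 < overlap < 1.0

    def test_od_biased_toward_forest(self, bundle):
        forest = bundle.truth_map_1.values == 1
        p_in = bundle.masks.od[forest].mean()
        p_out = bundle.masks.od[~forest].mean()
        assert p_in > p_out


class TestBundle:
    def test_full_determinism_under_seed(self, world_spec, bundle):
        again = generate_world(world_spec)
        assert np.array_equal(again.truth_map_1.values, bundle.truth_map_1.values)
        assert np.array_equal(again.truth_map_2.values, bundle.truth_map_2.values)
        for a, b in zip(again.scenes_1, bundle.scenes_1):
            assert np.array_equal(a.bands, b.bands)
            assert np.array_equal(a.qa, b.qa)
        assert np.array_equal(again.masks.od, bundle.masks.od)
        assert np.array_equal(again.elevation.values, bundle.elevation.values)

    def test_truth_maps_fully_classified(self, bundle):
        assert bundle.truth_map_1.valid.all()
        assert bundle.truth_map_2.valid.all()
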