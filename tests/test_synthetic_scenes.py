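import warnings

import numpy as np
import pytest

from tomatodet.synthetic_scenes import (
    SamplePatch,
    SceneSpec,
    augment_rotations,
    annotation_from_dict,
    annotation_to_dict,
    crop_training_samples,
    default_test_specs,
    default_training_specs,
    generate_scene,
    rotate_patch,
)


class TestGenerateScene:
    def test_deterministic_from_spec(self):
        spec = SceneSpec(n_tomatoes=3, occlusion_fraction=0.2, rng_seed=11)
        img_a, ann_a = generate_scene(spec)
        img_b, ann_b = generate_scene(spec)
        assert np.array_equal(img_a, img_b)
        assert ann_a.boxes == ann_b.boxes
        assert ann_a.occluded_area == ann_b.occluded_area
        assert np.array_equal(ann_a.fruit_mask, ann_b.fruit_mask)

    def test_empty_scene_has_no_red(self):
        img, ann = generate_scene(SceneSpec(n_tomatoes=0, rng_seed=1))
        assert ann.boxes == []
        diff = img[..., 0].astype(int) - img[..., 1].astype(int)
        assert diff.max() <= 50

    def test_three_separated_fruit(self):
        img, ann = generate_scene(
            SceneSpec(n_tomatoes=3, overlap_fraction=0.0, occlusion_fraction=0.0,
                      unripe_fraction=0.0, rng_seed=7)
        )
        assert len(ann.boxes) == 3
        assert ann.condition_labels == ["separated"] * 3
        h, w = img.shape[:2]
        for box in ann.boxes:
            assert 0 <= box.x and box.x2 <= w and 0 <= box.y and box.y2 <= h

    def test_pairwise_overlap_close_to_requested(self):
        spec = SceneSpec(n_tomatoes=2, overlap_fraction=0.3, rng_seed=7)
        img, ann = generate_scene(spec)
        assert ann.condition_labels == ["overlapped"] * 2
        # rebuild the two geometric discs from the boxes and count overlap
        h, w = img.shape[:2]
        yy, xx = np.ogrid[:h, :w]
        discs = []
        for box in ann.boxes:
            cx, cy = box.center
            r = (box.w - 1) / 2
            discs.append((xx - cx + 0.5) ** 2 + (yy - cy + 0.5) ** 2 <= r**2)
        inter = np.count_nonzero(discs[0] & discs[1])
        smaller = min(np.count_nonzero(d) for d in discs)
        assert inter / smaller == pytest.approx(0.3, abs=0.05)

    def test_occlusion_measured_near_requested(self):
        spec = SceneSpec(n_tomatoes=2, occlusion_fraction=0.25, rng_seed=5)
        _, ann = generate_scene(spec)
        assert ann.condition_labels == ["occluded"] * 2
        for frac in ann.occluded_area:
            assert frac == pytest.approx(0.25, abs=0.05)

    def test_every_fruit_gets_a_condition_label(self):
        for spec in default_test_specs(3, n_scenes=6):
            _, ann = generate_scene(spec)
            assert len(ann.condition_labels) == len(ann.boxes)
            assert all(c in ("separated", "overlapped", "occluded")
                       for c in ann.condition_labels)

    def test_infeasible_placement_raises(self):
        with pytest.raises(RuntimeError):
            generate_scene(SceneSpec(n_tomatoes=40, radius_range=(40, 40), rng_seed=0))

    def test_annotation_json_round_trip(self):
        spec = SceneSpec(n_tomatoes=2, occlusion_fraction=0.2, rng_seed=3)
        _, ann = generate_scene(spec)
        back = annotation_from_dict(annotation_to_dict(ann, spec))
        assert back.boxes == ann.boxes
        assert back.condition_labels == ann.condition_labels
        assert back.occluded_area == pytest.approx(ann.occluded_area)


class TestCropTrainingSamples:
    def test_counts_and_sizes(self):
        img, ann = generate_scene(SceneSpec(n_tomatoes=3, rng_seed=2))
        patches = crop_training_samples(img, ann, n_background=9, rng_seed=0)
        labels = [p.label for p in patches]
        assert labels.count(1) == 3 and labels.count(-1) == 9  # the 1:3 ratio
        assert all(p.pixels.shape == (64, 64, 3) for p in patches)

    def test_no_fruit_means_no_positives(self):
        img, ann = generate_scene(SceneSpec(n_tomatoes=0, rng_seed=2))
        patches = crop_training_samples(img, ann, n_background=4, rng_seed=0)
        assert all(p.label == -1 for p in patches)

    def test_background_patches_avoid_fruit(self):
        img, ann = generate_scene(SceneSpec(n_tomatoes=3, rng_seed=4))
        patches = crop_training_samples(img, ann, n_background=12, rng_seed=1)
        for p in patches:
            if p.label == -1:
                diff = p.pixels[..., 0].astype(int) - p.pixels[..., 1].astype(int)
                assert (diff > 50).mean() < 0.5  # mostly non-red content

    def test_warns_when_backgrounds_unavailable(self):
        img, ann = generate_scene(SceneSpec(n_tomatoes=2, rng_seed=2))
        ann.fruit_mask = np.ones_like(ann.fruit_mask)  # everything "fruit"
        with pytest.warns(UserWarning):
            patches = crop_training_samples(img, ann, n_background=5, rng_seed=0)
        assert sum(p.label == -1 for p in patches) == 0


class TestAugmentRotations:
    def _patches(self, rng, n):
        return [
            SamplePatch(rng.integers(0, 256, (64, 64, 3)).astype(np.uint8),
                        1 if i % 2 == 0 else -1)
            for i in range(n)
        ]

    def test_exactly_doubles_and_preserves_labels(self, rng):
        patches = self._patches(rng, 6)
        out = augment_rotations(patches, rng_seed=0)
        assert len(out) == 12
        assert [p.label for p in out] == [p.label for p in patches] * 2

    def test_originals_kept_bit_identical(self, rng):
        patches = self._patches(rng, 1)
        out = augment_rotations(patches, rng_seed=0)
        assert len(out) == 2
        assert np.array_equal(out[0].pixels, patches[0].pixels)

    def test_zero_angle_rotation_is_identity(self, rng):
        pixels = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        assert np.array_equal(rotate_patch(pixels, 0.0), pixels)
        assert np.array_equal(rotate_patch(pixels, 720.0), pixels)
        assert not np.array_equal(rotate_patch(pixels, 45.0), pixels)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_rotations([])


class TestDefaultSpecs:
    def test_training_set_mirrors_canonical_sizes(self):
        specs = default_training_specs(0)
        assert len(specs) == 69
        assert sum(s.n_tomatoes for s in specs) == 207

    def test_test_set_covers_conditions_and_light(self):
        specs = default_test_specs(0)
        assert len(specs) == 75
        assert sum(s.n_tomatoes for s in specs) == 150
        kinds = {
            (s.overlap_fraction > 0, s.occlusion_fraction > 0) for s in specs
        }
        assert kinds == {(False, False), (True, False), (False, True)}
        assert {s.illumination for s in specs} == {"sunny", "shaded"}

    def test_specs_deterministic(self):
        assert default_test_specs(9) == default_test_specs(9)


def test_scene_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(width=32)
    with pytest.raises(ValueError):
        SceneSpec(overlap_fraction=1.0)
    with pytest.raises(ValueError):
        SceneSpec(illumination="noon")
    with pytest.raises(ValueError):
        SceneSpec(radius_range=(0, 10))
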