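import numpy as np
import pytest

from tomatodet.nms import BoundingBox
from tomatodet.pipeline import _enhanced_uint8, PipelineConfig
from tomatodet.roi_extraction import (
    classify_pixels,
    extract_roi,
    nb_log_posterior,
    pixel_color_features,
    train_nb,
)

from _oracles import nb_posterior_mask


class TestPixelColorFeatures:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), (255.0, 255.0, 1.0)),
            ((100, 100, 100), (0.0, 0.0, 1 / 3)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_examples(self, rgb, expected):
        feats = pixel_color_features(np.array([[rgb]], dtype=np.float64))
        assert feats[0, 0] == pytest.approx(expected)


def _cluster_features(rng, center, n=50, spread=3.0):
    pixels = rng.normal(center, spread, (n, 3)).clip(0, 255)
    return pixel_color_features(pixels)


class TestTrainNb:
    def test_single_point_classes_boundary_at_midpoint(self):
        feats = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        model = train_nb(feats, np.array([-1, 1]))
        mid = np.array([4.0, 0.0, 0.0])
        scores = nb_log_posterior(model, mid)
        assert scores[0] == pytest.approx(scores[1], abs=1e-9)
        assert nb_log_posterior(model, mid + [0.1, 0, 0])[1] > scores[0]
        assert nb_log_posterior(model, mid - [0.1, 0, 0])[1] < scores[0]

    def test_priors_from_frequencies(self, rng):
        feats = np.vstack([_cluster_features(rng, [150, 150, 0.7], n=25),
                           _cluster_features(rng, [-60, -20, 0.2], n=75)])
        labels = np.array([1] * 25 + [-1] * 75)
        model = train_nb(feats, labels)
        assert model.priors == pytest.approx([0.75, 0.25])

    def test_order_invariance_bit_identical(self, rng):
        feats = rng.normal(0, 50, (40, 3))
        labels = np.array([1, -1] * 20)
        perm = rng.permutation(40)
        a = train_nb(feats, labels)
        b = train_nb(feats[perm], labels[perm])
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.variances, b.variances)
        assert np.array_equal(a.priors, b.priors)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_nb(np.zeros((3, 3)), np.array([1, 1, 1]))


@pytest.fixture(scope="module")
def red_green_nb():
    rng = np.random.default_rng(0)
    red = rng.normal([200, 45, 40], 10, (200, 3)).clip(0, 255)
    green = rng.normal([50, 120, 45], 15, (200, 3)).clip(0, 255)
    feats = pixel_color_features(np.vstack([red, green]))
    return train_nb(feats, np.array([1] * 200 + [-1] * 200))


class TestClassifyPixels:
    def test_pure_red_all_white(self, red_green_nb):
        img = np.tile(np.array([210, 40, 35], dtype=np.uint8), (8, 8, 1))
        assert classify_pixels(red_green_nb, img).all()

    def test_pure_green_all_black(self, red_green_nb):
        img = np.tile(np.array([45, 130, 50], dtype=np.uint8), (8, 8, 1))
        assert not classify_pixels(red_green_nb, img).any()

    def test_covers_fruit_pixels_on_scene(self, small_models, easy_scene):
        image, annotation = easy_scene
        enhanced = _enhanced_uint8(image, PipelineConfig().preprocess)
        mask = classify_pixels(small_models.nb, enhanced)
        ripe = (annotation.fruit_mask >= 1) & (
            annotation.fruit_mask <= len(annotation.boxes)
        )
        assert mask[ripe].mean() >= 0.9

    def test_matches_brute_force_posteriors(self, red_green_nb, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        mine = classify_pixels(red_green_nb, img)
        ref = nb_posterior_mask(
            red_green_nb.means, red_green_nb.variances, red_green_nb.priors, img
        )
        assert np.array_equal(mine, ref)


class TestExtractRoi:
    def test_small_component_expanded_to_window(self):
        mask = np.zeros((202, 360), dtype=bool)
        mask[50:80, 100:130] = True
        rois = extract_roi(mask, window=64)
        assert len(rois) == 1
        roi = rois[0]
        assert roi.w >= 64 and roi.h >= 64
        assert roi.x <= 100 and roi.x2 >= 130 and roi.y <= 50 and roi.y2 >= 80

    def test_empty_mask(self):
        assert extract_roi(np.zeros((100, 100), dtype=bool)) == []

    def test_speckle_removed(self, rng):
        mask = np.zeros((100, 100), dtype=bool)
        idx = rng.integers(0, 100, (30, 2))
        mask[idx[:, 0], idx[:, 1]] = True  # isolated pixels die under opening
        assert extract_roi(mask) == []

    def test_covers_surviving_components(self, rng):
        mask = np.zeros((202, 360), dtype=bool)
        mask[20:60, 30:70] = True
        mask[120:180, 250:330] = True
        rois = extract_roi(mask)
        for y0, x0 in [(20, 30), (120, 250)]:
            assert any(r.x <= x0 and r.y <= y0 for r in rois)

    def test_scene_roi_prunes_over_half_but_keeps_fruit(self, small_models, easy_scene):
        image, annotation = easy_scene
        enhanced = _enhanced_uint8(image, PipelineConfig().preprocess)
        mask = classify_pixels(small_models.nb, enhanced)
        rois = extract_roi(mask)
        h, w = mask.shape
        covered = np.zeros((h, w), dtype=bool)
        for r in rois:
            covered[r.y:r.y2, r.x:r.x2] = True
        assert covered.mean() < 0.5  # the coarse stage prunes over half the area
        for box in annotation.boxes:
            assert covered[box.y:box.y2, box.x:box.x2].mean() >= 0.9
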