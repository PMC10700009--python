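"""Grad-CAM, integrated gradients and XRAI on hand-built toy backbones."""

import numpy as np
import pytest

from gemmascope.attribution import grad_cam, integrated_gradients, xrai
from gemmascope.backbone import LinearToyBackbone as ToyBackbone
from gemmascope.classifier import TrainedClassifier
from gemmascope.types import NormalizedImage


def _image(side=8, value=0.5):
    pix = np.full((side, side, 3), value, dtype=np.float32)
    return NormalizedImage(pix, mean=np.zeros(3), sd=np.ones(3))


def _toy_classifier(head_w, masks):
    return TrainedClassifier(
        backbone=ToyBackbone(masks), head_w=np.asarray(head_w, float),
        head_b=np.zeros(2))


class TestGradCam:
    def test_matches_hand_derived_chain_rule(self):
        """2-channel, 4x4 toy: alpha_k = w_k / (H'W'), map = ReLU(sum alpha A)."""
        masks = np.zeros((2, 4, 4))
        masks[0, 1, 2] = 1.0   # channel 0 active on one cell
        masks[1, :, :] = 0.25  # channel 1 uniform
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        img = _image(8, 0.5)
        amap = grad_cam(clf, img, target_class=0)
        s = 0.5  # mean input
        alpha = np.array([1.0, 0.0]) / 16.0
        raw = np.maximum((alpha[:, None, None] * masks * s).sum(axis=0), 0)
        expected = raw / raw.max()
        # compare on the conv grid by sampling the upsampled map at cell centers
        assert amap.values.shape == (8, 8)
        assert amap.values.max() == pytest.approx(1.0)
        # channel-0 cell (1,2) upsampled: maximum of the map sits there
        peak = np.unravel_index(amap.values.argmax(), amap.values.shape)
        assert (1 <= peak[0] <= 4) and (3 <= peak[1] <= 6)
        assert amap.logit == pytest.approx(s * masks[0].mean())

    def test_negated_head_zeroes_positive_regions(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 1, 2] = 1.0
        clf_pos = _toy_classifier([[1.0, 0.0], [0.0, 0.0]], masks)
        clf_neg = _toy_classifier([[-1.0, 0.0], [0.0, 0.0]], masks)
        img = _image()
        with pytest.warns(UserWarning, match="identically zero"):
            amap_neg = grad_cam(clf_neg, img, 0)
        amap_pos = grad_cam(clf_pos, img, 0)
        assert amap_neg.values.sum() == 0.0
        assert amap_pos.values.max() == 1.0

    def test_peak_at_active_cell(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 3, 0] = 1.0
        masks[1] = 0.0
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        amap = grad_cam(clf, _image(), 0)
        peak = np.unravel_index(amap.values.argmax(), amap.values.shape)
        assert peak[0] >= 5 and peak[1] <= 2


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        """For a linear logit, attributions are exactly w_i (x_i - b_i)."""
        masks = np.full((2, 4, 4), 0.5)
        clf = _toy_classifier([[1.0, 1.0], [0.0, 0.0]], masks)
        img = _image(8, 0.8)
        baseline = np.full(img.pixels.shape, 0.2)
        for steps in (2, 25):
            attr = integrated_gradients(clf, img, baseline, 0, steps=steps)
            coef = float(np.array([1.0, 1.0]) @ masks.mean(axis=(1, 2))) / img.pixels.size
            assert np.allclose(attr, (img.pixels - baseline) * coef, rtol=1e-6)

    def test_completeness_on_toy(self):
        masks = np.full((2, 4, 4), 0.5)
        clf = _toy_classifier([[2.0, -1.0], [0.0, 0.0]], masks)
        img = _image(8, 0.9)
        baseline = np.zeros(img.pixels.shape)
        attr = integrated_gradients(clf, img, baseline, 0, steps=256)
        _, pooled_x = clf.backbone.forward(
            np.transpose(img.pixels, (2, 0, 1))[None])
        _, pooled_b = clf.backbone.forward(
            np.transpose(baseline, (2, 0, 1))[None])
        diff = float((pooled_x - pooled_b)[0] @ clf.head_w[0])
        assert attr.sum() == pytest.approx(diff, rel=0.05)

    def test_completeness_on_conv_backbone(self, backbone):
        """Midpoint-rule completeness within 5% at 256 steps on the real CNN."""
        rng = np.random.default_rng(0)
        img = NormalizedImage(rng.normal(0, 1, (16, 16, 3)).astype(np.float32),
                              mean=np.zeros(3), sd=np.ones(3))
        clf = TrainedClassifier(
            backbone=backbone,
            head_w=rng.normal(0, 1, (2, backbone.pooled_dim)),
            head_b=np.zeros(2))
        baseline = np.zeros(img.pixels.shape)
        attr = integrated_gradients(clf, img, baseline, 1, steps=256)
        from gemmascope.backbone import to_nchw

        _, px = backbone.forward(to_nchw([img]))
        _, pb = backbone.forward(np.zeros((1, 3, 16, 16)))
        diff = float((px - pb)[0] @ clf.head_w[1])
        assert attr.sum() == pytest.approx(diff, rel=0.05)

    def test_zero_image_zero_baseline(self):
        masks = np.full((2, 4, 4), 0.5)
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        img = _image(8, 0.0)
        attr = integrated_gradients(clf, img, np.zeros(img.pixels.shape), 0)
        assert np.all(attr == 0)

    def test_too_few_steps_rejected(self):
        masks = np.full((2, 4, 4), 0.5)
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        img = _image()
        with pytest.raises(ValueError):
            integrated_gradients(clf, img, np.zeros(img.pixels.shape), 0, steps=1)

    def test_baseline_shape_checked(self):
        masks = np.full((2, 4, 4), 0.5)
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        with pytest.raises(ValueError):
            integrated_gradients(clf, _image(), np.zeros((4, 4, 3)), 0)


class TestXrai:
    def _structured_image(self):
        rng = np.random.default_rng(1)
        pix = rng.normal(0.2, 0.02, (16, 16, 3))
        pix[4:12, 4:12] = rng.normal(0.8, 0.02, (8, 8, 3))
        return NormalizedImage(pix.astype(np.float32),
                               mean=np.zeros(3), sd=np.ones(3))

    def test_concentrated_attribution_ranks_bright_region_first(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 1:3, 1:3] = 1.0
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        img = self._structured_image()
        amap = xrai(clf, img, 0, segment_scales=(20.0, 60.0), steps=8)
        assert amap.method == "xrai"
        # the bright central region receives the top saliency
        assert amap.values[6:10, 6:10].mean() > amap.values[:3, :3].mean()

    def test_deterministic(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 1:3, 1:3] = 1.0
        clf = _toy_classifier([[1.0, 0.0], [0.0, 1.0]], masks)
        img = self._structured_image()
        a = xrai(clf, img, 0, segment_scales=(20.0,), steps=4)
        b = xrai(clf, img, 0, segment_scales=(20.0,), steps=4)
        assert np.array_equal(a.values, b.values)

    def test_values_in_unit_interval(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 0, 0] = 1.0
        clf = _toy_classifier([[1.0, -0.5], [0.0, 1.0]], masks)
        amap = xrai(clf, self._structured_image(), 0,
                    segment_scales=(20.0, 60.0), steps=4)
        assert amap.values.min() >= 0.0 and amap.values.max() <= 1.0
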