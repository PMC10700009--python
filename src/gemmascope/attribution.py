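"""Class-discriminative attribution maps: Grad-CAM, integrated gradients, XRAI.

Grad-CAM weights the last-convolutional-layer activation maps A^k by the
spatially averaged gradient of the target-class logit, alpha_k = mean_ij
d y_c / d A^k_ij, rectifies the weighted sum (ReLU after channel summation),
bilinearly upsamples to input resolution, and min-max normalizes per image.
Because the head is affine on globally average-pooled features, the gradient
with respect to A^k is exactly the head weight for channel k divided by the
spatial cell count.

Integrated gradients attribute the logit to input pixels along the straight
path from a baseline, satisfying completeness (attributions sum to the logit
difference) as the step count grows. The XRAI-style map averages integrated
gradients over black and white baselines, oversegments the image at several
scales, and greedily ranks regions by mean attribution gain over the already
selected area; each pixel receives the gain density of the step at which it
was first covered.
"""

from __future__ import annotations

from typing import Sequence, Tuple
import warnings

import numpy as np
from skimage.segmentation import felzenszwalb
from skimage.transform import resize

from .classifier import TrainedClassifier
from .types import AttributionMap, NormalizedImage


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _single_logit(classifier: TrainedClassifier, image: NormalizedImage,
                  target_class: int) -> float:
    from .backbone import to_nchw

    _, pooled = classifier.backbone.forward(to_nchw([image]))
    return float(classifier.logits_from_features(pooled)[0, target_class])


def grad_cam(
    classifier: TrainedClassifier, image: NormalizedImage, target_class: int
) -> AttributionMap:
    """Grad-CAM heatmap for one image and target class.

    Warns and returns an all-zero map when the rectified weighted sum is
    identically zero (gradient pointing entirely away from active channels).
    """
    from .backbone import to_nchw

    acts, pooled = classifier.backbone.forward(to_nchw([image]))
    a = acts[0]  # (C, H', W')
    hw = a.shape[1] * a.shape[2]
    # d y_c / d A^k_ij = head_w[c, k] / (H' W'); alpha_k is its spatial mean
    alpha = classifier.head_w[target_class] / hw
    raw = np.maximum(np.tensordot(alpha, a, axes=1), 0.0)
    if raw.max() <= 0:
        warnings.warn("Grad-CAM map is identically zero for this image", stacklevel=2)
    up = resize(raw, image.pixels.shape[:2], order=1, preserve_range=True,
                anti_aliasing=False)
    logit = float(classifier.logits_from_features(pooled)[0, target_class])
    return AttributionMap(
        values=_minmax(up), method="gradcam", target_class=target_class,
        image_id="", logit=logit,
    )


def integrated_gradients(
    classifier: TrainedClassifier,
    image: NormalizedImage,
    baseline: np.ndarray,
    target_class: int,
    steps: int = 25,
) -> np.ndarray:
    """Signed per-pixel attribution grid (H, W, 3) for the target logit.

    (image - baseline) times the mean input gradient along the straight-line
    path, sampled at ``steps`` midpoints. Completeness (sum of attributions
    equals the logit difference) holds to a few percent for steps >= 128.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    x = np.asarray(image.pixels, dtype=np.float64)
    b = np.asarray(baseline, dtype=np.float64)
    if b.shape != x.shape:
        raise ValueError("baseline must have the same shape as the image")
    # midpoint rule on the path integral
    alphas = (np.arange(steps) + 0.5) / steps
    path = b[None] + alphas[:, None, None, None] * (x - b)[None]
    batch = np.transpose(path, (0, 3, 1, 2))
    grads = classifier.backbone.input_gradient(batch, classifier.head_w[target_class])
    mean_grad = np.transpose(grads.mean(axis=0), (1, 2, 0))
    return (x - b) * mean_grad


def xrai(
    classifier: TrainedClassifier,
    image: NormalizedImage,
    target_class: int,
    segment_scales: Sequence[float] = (30.0, 80.0, 200.0),
    steps: int = 25,
) -> AttributionMap:
    """Region-ranked attribution map (XRAI-style).

    Pixel attributions are the channel sum of integrated gradients averaged
    over black and white baselines; regions from Felzenszwalb
    oversegmentations at several scales are greedily selected by mean
    attribution gain over the not-yet-covered area.
    """
    rgb = image.denormalize()
    black = (np.zeros(3) - image.mean) / image.sd
    white = (np.ones(3) - image.mean) / image.sd
    attr = np.zeros(image.pixels.shape[:2])
    for base_color in (black, white):
        baseline = np.broadcast_to(base_color, image.pixels.shape).astype(np.float64)
        attr += integrated_gradients(
            classifier, image, baseline, target_class, steps
        ).sum(axis=2)
    attr /= 2.0

    regions = []
    for scale in segment_scales:
        seg = felzenszwalb(rgb, scale=scale, sigma=0.6,
                           min_size=max(4, attr.size // 400))
        for lab in np.unique(seg):
            regions.append(seg == lab)
    if len({r.tobytes() for r in regions}) < 2:
        raise ValueError("degenerate segmentation: only one region produced")

    covered = np.zeros(attr.shape, dtype=bool)
    saliency = np.zeros(attr.shape)
    remaining = regions
    while remaining and not covered.all():
        best_gain, best_idx, best_new = -np.inf, -1, None
        for idx, reg in enumerate(remaining):
            new = reg & ~covered
            cnt = int(new.sum())
            if cnt == 0:
                continue
            gain = attr[new].sum() / cnt
            if gain > best_gain:
                best_gain, best_idx, best_new = gain, idx, new
        if best_new is None:
            break
        saliency[best_new] = best_gain
        covered |= best_new
        remaining = [r for i, r in enumerate(remaining) if i != best_idx]

    logit = _single_logit(classifier, image, target_class)
    return AttributionMap(
        values=_minmax(saliency), method="xrai", target_class=target_class,
        image_id="", logit=logit,
    )
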