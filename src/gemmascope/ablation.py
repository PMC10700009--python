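"""Human-interpretable feature ablations for attribution of classifier information.

Three ablations, applied to raw images before preprocessing, remove
successively more information:

* ``BACKGROUND_MASK`` (I)  -- background set to black; quantifies how much the
  classifier relied on background cues (medium color, scratches).
* ``BINARIZE`` (II)        -- white silhouette on black; additionally removes
  foreground color and texture.
* ``BINARIZE_BLUR`` (III)  -- silhouette followed by severe Gaussian blur
  (bandwidth 60 px at the 1,200-px reference scale); additionally removes the
  fine contour shape, leaving essentially the projected area.

Comparing test accuracies across NONE -> I -> II -> III attributes the
classifier's information to background, color/texture, contour and area.
The same ablation must be applied to training, validation and test data.
"""

from __future__ import annotations

from enum import Enum
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .types import ImageRecord, SilhouetteMask

#: severe-blur bandwidth (Gaussian sigma, px) at the 1,200-px reference scale
SEVERE_BLUR_BANDWIDTH = 60.0
REFERENCE_SIZE = 1200


class AblationType(str, Enum):
    NONE = "none"
    BACKGROUND_MASK = "background"
    BINARIZE = "binarize"
    BINARIZE_BLUR = "binarize-blur"


def scaled_blur_bandwidth(image_shape: tuple) -> float:
    """Severe-blur sigma scaled as 60/1,200 of this image's long side."""
    return SEVERE_BLUR_BANDWIDTH * max(image_shape[0], image_shape[1]) / REFERENCE_SIZE


def apply_ablation(
    image: np.ndarray,
    mask: SilhouetteMask,
    kind: AblationType,
    blur_bandwidth: float | None = None,
) -> np.ndarray:
    """Apply one ablation to a raw uint8 RGB image using its silhouette mask.

    ``BINARIZE_BLUR`` output is left grayscale-valued (not re-binarized): the
    blurred silhouette is returned as float in [0, 255] replicated over RGB.
    Other kinds return uint8.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("apply_ablation expects an RGB image")
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape[:2]}"
        )
    kind = AblationType(kind)
    fg = mask.pixels
    if kind is AblationType.NONE:
        return image.copy()
    if kind is AblationType.BACKGROUND_MASK:
        out = image.copy()
        out[~fg] = 0
        return out
    silhouette = np.zeros(image.shape[:2], dtype=np.float64)
    silhouette[fg] = 255.0
    if kind is AblationType.BINARIZE:
        return np.repeat(silhouette[:, :, None], 3, axis=2).astype(np.uint8)
    # BINARIZE_BLUR
    sigma = scaled_blur_bandwidth(image.shape) if blur_bandwidth is None else blur_bandwidth
    blurred = ndi.gaussian_filter(silhouette, sigma=sigma)
    return np.repeat(blurred[:, :, None], 3, axis=2)


def ablate_dataset(
    dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]],
    kind: AblationType,
    blur_bandwidth: float | None = None,
) -> List[ImageRecord]:
    """Apply one ablation kind uniformly to a whole dataset.

    Raises if any record lacks a mask, listing the offending ids. The
    identical procedure must cover training, validation and test partitions,
    which is guaranteed by ablating before splitting.
    """
    missing = [rec.id for rec, mask in dataset if mask is None]
    if missing:
        raise ValueError(f"records without masks: {missing}")
    out = []
    for rec, mask in dataset:
        pix = apply_ablation(rec.pixels, mask, kind, blur_bandwidth)
        if pix.dtype != np.uint8:
            pix = np.clip(pix, 0, 255).round().astype(np.uint8)
        out.append(
            ImageRecord(id=rec.id, pixels=pix, label=rec.label, line=rec.line,
                        day=rec.day, mask=mask)
        )
    return out
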