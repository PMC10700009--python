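"""Core data containers shared across the pipeline.

The pipeline's unit of data is a labeled RGB photograph of a single young
gemmaling on an agar plate, optionally paired with a binary silhouette mask of
the plant's aerial part. Masks come either from the synthetic generator
(ground truth) or from Otsu segmentation, and the provenance is tracked
because ablations and IoU validation depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: canonical class labels, in index order (male = 0, female = 1)
LABELS = ("male", "female")


def label_index(label: str) -> int:
    """Map a class label to its integer index; raises on unknown labels."""
    try:
        return LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}") from None


@dataclass
class SilhouetteMask:
    """Binary foreground mask of the plant's aerial part.

    ``pixels`` is a boolean H x W grid matching the source image; ``provenance``
    records whether the mask is the generator's ground truth or a segmentation
    result.
    """

    pixels: np.ndarray
    provenance: str = "segmented"  # {"ground_truth", "segmented"}

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D binary grid")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class ImageRecord:
    """One labeled RGB image.

    ``pixels`` is an H x W x 3 uint8 array. ``label`` is the class (sex),
    ``line`` the accession/line identifier, ``day`` the developmental day after
    gemma planting.
    """

    id: str
    pixels: np.ndarray
    label: str
    line: str
    day: int
    mask: Optional[SilhouetteMask] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ImageRecord.pixels must be H x W x 3 RGB")

    @property
    def label_idx(self) -> int:
        return label_index(self.label)


@dataclass
class NormalizedImage:
    """Model-ready image: float32 H x W x 3, channel-standardized.

    Produced from [0, 1]-scaled intensities via ``(x - mean) / sd`` with the
    stored per-channel constants, so the raw intensities can be recovered for
    display and for region segmentation in XRAI.
    """

    pixels: np.ndarray
    mean: np.ndarray = field(default_factory=lambda: np.array([0.485, 0.456, 0.406]))
    sd: np.ndarray = field(default_factory=lambda: np.array([0.229, 0.224, 0.225]))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("NormalizedImage.pixels must be H x W x 3")

    def denormalize(self) -> np.ndarray:
        """Recover the [0, 1] intensity image (clipped)."""
        raw = self.pixels * self.sd[None, None, :] + self.mean[None, None, :]
        return np.clip(raw, 0.0, 1.0)


@dataclass
class AttributionMap:
    """Per-pixel relevance in [0, 1] for one target class of one image.

    ``values`` is min-max normalized per image; an identically-zero raw map
    stays all zeros rather than becoming NaN. ``logit`` is the unnormalized
    target-class logit of the explained image, kept for representative-image
    selection.
    """

    values: np.ndarray
    method: str  # {"gradcam", "xrai"}
    target_class: int
    image_id: str
    logit: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("attribution values must be a 2-D grid")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("attribution values must lie in [0, 1]")
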