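"""Deterministic image preprocessing and training-set augmentation.

Raw photographs are center-cropped to a square (the crop side defaults to
0.75 of the long side, the ratio of a 1,200-px crop on a 1,200 x 1,600
frame), the scale bar is erased with a local background estimate, training
images are expanded to their dihedral-group orbit (right-angle rotations x
horizontal flip), and the result is resized, scaled to [0, 1] and
channel-standardized with the ImageNet constants (mean [0.485, 0.456, 0.406],
sd [0.229, 0.224, 0.225]).

Evaluation mode applies no flip or rotation and is bit-deterministic.
Masks are transformed with the identical geometry using nearest-neighbor
resampling so mask/image correspondence is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .types import NormalizedImage, SilhouetteMask

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_SD = np.array([0.229, 0.224, 0.225])
DEFAULT_CROP_FRACTION = 0.75  # 1,200 / 1,600
DEFAULT_TARGET_SIZE = 300


@dataclass(frozen=True)
class PreprocessConfig:
    """Geometry and normalization settings, recorded in run manifests."""

    crop_fraction: float = DEFAULT_CROP_FRACTION
    target_size: int = DEFAULT_TARGET_SIZE
    normalization_mean: Tuple[float, float, float] = tuple(IMAGENET_MEAN)
    normalization_sd: Tuple[float, float, float] = tuple(IMAGENET_SD)
    scale_bar_box: Optional[Tuple[int, int, int, int]] = None  # (r0, c0, r1, c1)
    augment: bool = True


def _center_crop_window(shape: Tuple[int, int], crop_fraction: float) -> Tuple[int, int, int]:
    h, w = shape
    side = int(round(crop_fraction * max(h, w)))
    if side > min(h, w):
        raise ValueError(
            f"crop side {side} exceeds the short image dimension {min(h, w)}"
        )
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return r0, c0, side


def erase_scale_bar(
    image: np.ndarray, box: Tuple[int, int, int, int], ring: int = 10
) -> np.ndarray:
    """Fill the scale-bar rectangle with the median color of a border ring."""
    r0, c0, r1, c1 = box
    h, w = image.shape[:2]
    ring = max(2, min(ring, h, w))
    rr0, cc0 = max(0, r0 - ring), max(0, c0 - ring)
    rr1, cc1 = min(h, r1 + ring), min(w, c1 + ring)
    region = image[rr0:rr1, cc0:cc1].reshape(-1, image.shape[2]).astype(np.float64)
    inner = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
    inner[r0 - rr0:r1 - rr0, c0 - cc0:c1 - cc0] = True
    fill = np.median(region[~inner.ravel()], axis=0)
    out = image.copy()
    out[max(0, r0):min(h, r1), max(0, c0):min(w, c1)] = fill.astype(image.dtype)
    return out


def dihedral_orbit(image: np.ndarray, dedup: bool = True) -> List[np.ndarray]:
    """The 8-element dihedral orbit of a square image (rot90 x horizontal flip).

    Non-square inputs are rejected because rotation would change the frame.
    Exactly symmetric inputs collapse to fewer variants when ``dedup`` is on.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError("augmentation requires a square image")
    variants = []
    for k in range(4):
        rot = np.rot90(image, k)
        variants.append(rot)
        variants.append(rot[:, ::-1])
    if not dedup:
        return [np.ascontiguousarray(v) for v in variants]
    seen, out = set(), []
    for v in variants:
        key = v.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(np.ascontiguousarray(v))
    return out


def augment(image: np.ndarray) -> List[np.ndarray]:
    """Dihedral-group training augmentation (deduplicated orbit)."""
    return dihedral_orbit(image, dedup=True)


def _finalize(
    img: np.ndarray, cfg: PreprocessConfig
) -> NormalizedImage:
    x = resize(
        img.astype(np.float64),
        (cfg.target_size, cfg.target_size, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    x = x / 255.0
    mean = np.asarray(cfg.normalization_mean)
    sd = np.asarray(cfg.normalization_sd)
    x = (x - mean[None, None, :]) / sd[None, None, :]
    return NormalizedImage(x.astype(np.float32), mean=mean, sd=sd)


def preprocess(
    image: np.ndarray,
    mode: str = "eval",
    config: PreprocessConfig = PreprocessConfig(),
) -> "NormalizedImage | List[NormalizedImage]":
    """Full preprocessing of one raw RGB image.

    ``mode='eval'`` returns a single deterministic NormalizedImage;
    ``mode='train'`` returns the augmented list (dihedral orbit). The scale
    bar, if configured, is erased after cropping; its box is given in original
    image coordinates.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("preprocess expects an RGB image")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    if image.dtype != np.uint8:
        image = np.clip(image, 0, 255).astype(np.uint8)
    r0, c0, side = _center_crop_window(image.shape[:2], config.crop_fraction)
    crop = image[r0:r0 + side, c0:c0 + side]
    if config.scale_bar_box is not None:
        br0, bc0, br1, bc1 = config.scale_bar_box
        box = (br0 - r0, bc0 - c0, br1 - r0, bc1 - c0)
        if box[2] > 0 and box[3] > 0 and box[0] < side and box[1] < side:
            clipped = (max(0, box[0]), max(0, box[1]), min(side, box[2]), min(side, box[3]))
            crop = erase_scale_bar(crop, clipped)
    if mode == "eval":
        return _finalize(crop, config)
    return [_finalize(v, config) for v in augment(crop)]


def preprocess_mask(
    mask: SilhouetteMask, config: PreprocessConfig = PreprocessConfig()
) -> SilhouetteMask:
    """Apply the eval-mode geometric transforms to a mask (nearest neighbor)."""
    pix = mask.pixels
    r0, c0, side = _center_crop_window(pix.shape, config.crop_fraction)
    crop = pix[r0:r0 + side, c0:c0 + side]
    out = resize(
        crop.astype(np.float64), (config.target_size, config.target_size),
        order=0, anti_aliasing=False, preserve_range=True,
    ) > 0.5
    return SilhouetteMask(out, provenance=mask.provenance)
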