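"""Quantitative validation of attribution maps against plant silhouettes.

Normalized heatmaps are binarized at 0.5 and compared to the (geometrically
matched) silhouette mask with IoU, the Jaccard coefficient. Summaries are
computed over correctly predicted test images only, grouped by day, line,
sex and method, reporting the median and interquartile range. The heatmap
area fraction (heatmap foreground / whole image) distinguishes a model that
"looked elsewhere" (IoU ~ 0, fraction > 0) from one whose map is empty.

For figures, one representative heatmap per group is the correctly predicted
image with the highest unnormalized target-class logit, a standard
confidence proxy.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AttributionMap, SilhouetteMask

DEFAULT_HEATMAP_THRESHOLD = 0.5


def binarize_heatmap(
    amap: AttributionMap, threshold: float = DEFAULT_HEATMAP_THRESHOLD
) -> SilhouetteMask:
    """Threshold a normalized attribution map into a binary heatmap mask."""
    return SilhouetteMask(amap.values >= threshold, provenance="segmented")


def iou(mask_a: SilhouetteMask, mask_b: SilhouetteMask) -> float:
    """Intersection over union of two masks; both-empty is defined as 0."""
    a, b = mask_a.pixels, mask_b.pixels
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks; defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def heatmap_area_fraction(mask: SilhouetteMask) -> float:
    """Foreground pixels over total pixels."""
    return float(mask.pixels.mean())


def select_representative(
    rows: pd.DataFrame, group_keys: Sequence[str] = ("day", "line", "sex", "method")
) -> pd.DataFrame:
    """Pick, per group, the correctly predicted image with the highest logit.

    ``rows`` needs columns id, correct, logit plus the group keys. Groups with
    no correct prediction are skipped with a warning. Logit ties break toward
    the lexicographically smallest id.
    """
    required = {"id", "correct", "logit", *group_keys}
    if not required.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    out = []
    for key, grp in rows.groupby(list(group_keys), sort=True):
        correct = grp[grp["correct"]]
        if correct.empty:
            warnings.warn(f"no correctly predicted image in group {key}; skipped",
                          stacklevel=2)
            continue
        best = correct.sort_values(["logit", "id"], ascending=[False, True]).iloc[0]
        out.append(best)
    return pd.DataFrame(out).reset_index(drop=True)


def score_images(
    maps: Sequence[AttributionMap],
    plant_masks: Sequence[SilhouetteMask],
    meta: pd.DataFrame,
    threshold: float = DEFAULT_HEATMAP_THRESHOLD,
) -> pd.DataFrame:
    """Long-format per-image table: id, day, line, sex, method, iou,
    area_fraction, logit, correct.

    ``meta`` rows align with ``maps``/``plant_masks`` and carry columns
    id, day, line, sex, correct.
    """
    if not (len(maps) == len(plant_masks) == len(meta)):
        raise ValueError("maps, masks and meta must align")
    rows = []
    for amap, pmask, (_, m) in zip(maps, plant_masks, meta.iterrows()):
        hmask = binarize_heatmap(amap, threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = iou(hmask, pmask)
        rows.append(dict(
            id=m["id"], day=m["day"], line=m["line"], sex=m["sex"],
            method=amap.method, iou=score,
            area_fraction=heatmap_area_fraction(hmask),
            logit=amap.logit, correct=bool(m["correct"]),
        ))
    return pd.DataFrame(rows)


def summarize_iou(
    scores: pd.DataFrame, group_keys: Sequence[str] = ("day", "sex", "method")
) -> pd.DataFrame:
    """Median and IQR of IoU per group over correctly predicted images."""
    correct = scores[scores["correct"]]
    out = []
    for key, grp in correct.groupby(list(group_keys), sort=True):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            continue
        key = key if isinstance(key, tuple) else (key,)
        q1, med, q3 = np.percentile(grp["iou"], [25, 50, 75])
        out.append(dict(zip(group_keys, key)) | dict(
            n=len(grp), iou_median=med, iou_q1=q1, iou_q3=q3,
            area_fraction_median=float(grp["area_fraction"].median()),
        ))
    dropped = set(map(tuple, scores[list(group_keys)].drop_duplicates().to_numpy().tolist()))
    kept = {tuple(d[k] for k in group_keys) for d in out}
    for missing in sorted(dropped - kept, key=str):
        warnings.warn(f"group {missing} has no correct predictions; omitted",
                      stacklevel=2)
    return pd.DataFrame(out)


def random_same_area_mask(
    like: SilhouetteMask, rng: np.random.Generator
) -> SilhouetteMask:
    """A random disk mask with (approximately) the same area as ``like``.

    Serves as the permutation baseline for localization: a heatmap that truly
    tracks the plant must beat same-area masks placed at random.
    """
    h, w = like.shape
    area = like.area_px
    if area == 0:
        return SilhouetteMask(np.zeros((h, w), dtype=bool), provenance="segmented")
    r = np.sqrt(area / np.pi)
    cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
    cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
    yy, xx = np.mgrid[0:h, 0:w]
    return SilhouetteMask((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r,
                          provenance="segmented")
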