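"""Pooled-feature extraction and 2-D t-SNE visualization of the image set.

Feature vectors come from the frozen backbone's global-average-pooling
output (2,048-d for a ResNet50-class backbone, ``pooled_dim`` in general) and
are embedded jointly across days and lines with t-SNE (perplexity 30, 1,000
iterations, seed 1,000,000 by default), the standard view for checking
whether images group by developmental day, sex, or neither.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .backbone import BackboneAdapter, to_nchw
from .types import ImageRecord, NormalizedImage

DEFAULT_PERPLEXITY = 30.0
DEFAULT_ITERATIONS = 1000
DEFAULT_TSNE_SEED = 1_000_000


def extract_features(
    backbone: BackboneAdapter,
    images: Sequence[NormalizedImage],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One pooled-feature row per eval-preprocessed image, indexed by image id."""
    feats = backbone.features(to_nchw(images))
    if feats.shape[1] != backbone.pooled_dim:
        raise ValueError("backbone returned unexpected feature dimension")
    index = list(ids) if ids is not None else list(range(len(images)))
    return pd.DataFrame(feats, index=pd.Index(index, name="id"))


def embed_2d(
    features: pd.DataFrame,
    perplexity: float = DEFAULT_PERPLEXITY,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_TSNE_SEED,
) -> pd.DataFrame:
    """t-SNE of the feature matrix into 2-D coordinates (columns x, y)."""
    n = len(features)
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity}; "
            f"use perplexity <= {n / 3:.0f}"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        random_state=seed,
        init="pca",
    )
    coords = ts.fit_transform(features.to_numpy())
    return pd.DataFrame(coords, index=features.index, columns=["x", "y"])


def embedding_table(
    coords: pd.DataFrame, records: Sequence[ImageRecord]
) -> pd.DataFrame:
    """Join embedding coordinates with per-image metadata for plotting."""
    meta = pd.DataFrame(
        [dict(id=r.id, day=r.day, line=r.line, label=r.label) for r in records]
    ).set_index("id")
    return coords.join(meta)
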