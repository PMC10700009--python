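"""Shared fixtures: a frozen backbone and small synthetic datasets.

Everything is generated programmatically at test time; image sizes are kept
at the generator's desk scale (64-128 px) so the whole suite runs on one CPU
in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from gemmascope.backbone import TinyConvBackbone
from gemmascope.experiment import desk_preprocess_config
from gemmascope.synthetic import (ChannelEffects, GrowthModel,
                                  SyntheticDatasetConfig, generate_dataset)


@pytest.fixture(scope="session")
def backbone():
    return TinyConvBackbone()


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced two-class dataset with a strong area difference."""
    cfg = SyntheticDatasetConfig(
        n_per_class=12, image_size=64,
        effects=ChannelEffects(area_effect=3.0),
        growth=GrowthModel(day=3), seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Dataset with all class effects zero (one shared distribution)."""
    cfg = SyntheticDatasetConfig(
        n_per_class=12, image_size=64, effects=ChannelEffects(),
        growth=GrowthModel(day=3), seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def desk_config():
    return desk_preprocess_config(64, 64)
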