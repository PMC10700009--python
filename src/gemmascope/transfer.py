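"""Cross-population transfer prediction.

A classifier trained on one male/female pair is applied, unchanged, to the
images of another pair whose class semantics are aligned by an explicit
label map (male <-> male, female <-> female). The asymmetry of the two
transfer directions tells whether one population's discriminative features
are a subset of the other's: a classifier trained on the channel both pairs
share transfers; one trained mostly on a private, easy-to-learn channel
(such as a large area difference) does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .ablation import AblationType, ablate_dataset
from .backbone import BackboneAdapter, to_nchw
from .classifier import (EvalReport, TrainedClassifier, evaluate, split_dataset)
from .preprocessing import PreprocessConfig, preprocess
from .types import ImageRecord, SilhouetteMask, LABELS


@dataclass
class TransferReport:
    """Performance of a pair-A classifier on pair-B images."""

    source_pair: str
    target_pair: str
    day: int
    ablation_kind: AblationType
    report: EvalReport

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def mcc(self) -> float:
        return self.report.mcc


def transfer_predict(
    classifier: TrainedClassifier,
    target_dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]],
    label_map: Optional[Dict[str, str]] = None,
    source_pair: str = "A",
    target_split: str = "all",
    split_seed: int = 0,
    ablation_kind: AblationType = AblationType.NONE,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> TransferReport:
    """Apply a trained classifier to another population's images.

    ``label_map`` maps target-population labels to the classifier's label
    vocabulary (defaults to identity on male/female). ``target_split='all'``
    evaluates every target image (no target training occurs); ``'test'``
    restricts to the target's own 20% test partition for symmetry with the
    within-population protocol.
    """
    label_map = label_map or {lab: lab for lab in LABELS}
    for rec, _ in target_dataset:
        if rec.label not in label_map:
            raise ValueError(f"unmapped label {rec.label!r} in target dataset")
    if target_split not in ("all", "test"):
        raise ValueError("target_split must be 'all' or 'test'")
    records = [rec for rec, _ in target_dataset]
    if target_split == "test":
        spec = split_dataset(records, seed=split_seed)
        keep = set(spec.test_ids)
        target_dataset = [(r, m) for r, m in target_dataset if r.id in keep]
        records = [rec for rec, _ in target_dataset]
    cfg = preprocess_config or classifier.preprocess_config or PreprocessConfig()
    ablated = ablate_dataset(target_dataset, ablation_kind)
    images = [preprocess(rec.pixels, "eval", cfg) for rec in ablated]
    feats = classifier.backbone.features(to_nchw(images))
    logits = classifier.logits_from_features(feats)
    preds = [LABELS[i] for i in logits.argmax(axis=1)]
    truths = [label_map[rec.label] for rec in records]
    report = evaluate(preds, truths)
    days = {rec.day for rec in records}
    pairs = {rec.line for rec in records}
    return TransferReport(
        source_pair=source_pair,
        target_pair="/".join(sorted(pairs)),
        day=days.pop() if len(days) == 1 else -1,
        ablation_kind=AblationType(ablation_kind),
        report=report,
    )
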