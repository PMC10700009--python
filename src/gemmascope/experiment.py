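"""End-to-end experiment orchestration.

Ties the stages into a reproducible run: generate (or load) a dataset,
segment or use ground-truth masks, apply an ablation, run the multi-trial
split/train/evaluate protocol, attribute correct test predictions with
Grad-CAM (and optionally XRAI), summarize heatmap/plant IoU, and optionally
transfer-predict onto a second population. Everything is reproducible from
the config plus one seed; the run directory holds config.json, trials.csv,
iou_scores.csv and summary.json.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from . import attribution as attr_mod
from .ablation import AblationType
from .backbone import TinyConvBackbone
from .classifier import (FeatureBank, TrainHyperparams, TrainedClassifier,
                         _trial_from_bank, build_feature_bank, run_trials,
                         split_dataset, LABELS)
from .preprocessing import PreprocessConfig, preprocess, preprocess_mask
from .synthetic import (ChannelEffects, GrowthModel, SyntheticDatasetConfig,
                        generate_dataset, scale_bar_box)
from .types import ImageRecord, SilhouetteMask
from .xai_validation import score_images, summarize_iou

log = logging.getLogger("gemmascope")

#: desk-scale defaults used throughout examples and validation runs
DESK_IMAGE_SIZE = 64
DESK_TARGET_SIZE = 64


def desk_preprocess_config(image_size: int = DESK_IMAGE_SIZE,
                           target_size: int = DESK_TARGET_SIZE) -> PreprocessConfig:
    """Preprocess config for generator-scale images (scale bar box included)."""
    return PreprocessConfig(target_size=target_size,
                            scale_bar_box=scale_bar_box(image_size))


@dataclass
class ExperimentConfig:
    """Serializable recipe for one experiment run."""

    n_per_class: int = 60
    image_size: int = DESK_IMAGE_SIZE
    target_size: int = DESK_TARGET_SIZE
    day: int = 3
    effects: ChannelEffects = field(default_factory=ChannelEffects)
    line: str = "syn"
    ablation_kind: AblationType = AblationType.NONE
    trials: int = 5
    seed: int = 0
    epochs: int = 500
    attribution_methods: Tuple[str, ...] = ("gradcam",)
    permutation_control: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        d["ablation_kind"] = AblationType(self.ablation_kind).value
        return json.dumps(d, indent=2)


def make_dataset(config: ExperimentConfig):
    return generate_dataset(SyntheticDatasetConfig(
        n_per_class=config.n_per_class,
        image_size=config.image_size,
        effects=config.effects,
        growth=GrowthModel(day=config.day),
        line=config.line,
        seed=config.seed,
    ))


def train_classifier(
    dataset,
    backbone,
    seed: int = 0,
    ablation_kind: AblationType = AblationType.NONE,
    preprocess_config: Optional[PreprocessConfig] = None,
    hyperparams: Optional[TrainHyperparams] = None,
) -> Tuple[TrainedClassifier, "EvalReport", "SplitSpec", FeatureBank]:
    """One split/train/evaluate pass returning a usable TrainedClassifier."""
    records = [rec for rec, _ in dataset]
    cfg = preprocess_config or desk_preprocess_config(records[0].pixels.shape[0])
    hp = hyperparams or TrainHyperparams()
    bank = build_feature_bank(dataset, backbone, ablation_kind, cfg)
    seeds = SeedSequence(seed).generate_state(2) % (2**31)
    report, clf, spec = _trial_from_bank(bank, records, int(seeds[0]), int(seeds[1]), hp)
    clf.backbone = backbone
    clf.preprocess_config = cfg
    return report, clf, spec, bank


def attribute_test_images(
    clf: TrainedClassifier,
    dataset,
    spec,
    methods: Sequence[str] = ("gradcam",),
    max_images: Optional[int] = None,
) -> Tuple[List, List[SilhouetteMask], pd.DataFrame]:
    """Grad-CAM/XRAI maps of the predicted class for test images.

    Returns (maps, geometry-matched plant masks, metadata) aligned row-wise;
    metadata marks whether each image was correctly predicted.
    """
    cfg = clf.preprocess_config
    by_id = {rec.id: (rec, mask) for rec, mask in dataset}
    test_ids = list(spec.test_ids)[:max_images] if max_images else spec.test_ids
    maps, pmasks, rows = [], [], []
    for tid in test_ids:
        rec, mask = by_id[tid]
        img = preprocess(rec.pixels, "eval", cfg)
        _, pooled = clf.backbone.forward(
            np.transpose(img.pixels.astype(np.float64), (2, 0, 1))[None])
        logits = clf.logits_from_features(pooled)[0]
        pred = int(logits.argmax())
        for method in methods:
            if method == "gradcam":
                amap = attr_mod.grad_cam(clf, img, pred)
            elif method == "xrai":
                amap = attr_mod.xrai(clf, img, pred)
            else:
                raise ValueError(f"unknown attribution method {method!r}")
            amap.image_id = rec.id
            maps.append(amap)
            pmasks.append(preprocess_mask(mask, cfg))
            rows.append(dict(id=rec.id, day=rec.day, line=rec.line, sex=rec.label,
                             correct=(pred == rec.label_idx)))
    return maps, pmasks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canned validation experiments (the desk-scale study conditions)
# ---------------------------------------------------------------------------

#: single-channel effect bundles used throughout validation: each dataset
#: differs between classes through exactly one channel. The area effect is a
#: moderate d ~ 3; the color, contour and background effects are set so each
#: channel is individually well-detectable at desk resolution (fine-contour
#: information in particular is near the resolution limit, so its planted
#: spectral-centroid difference is made maximal).
CHANNEL_EFFECTS: Dict[str, ChannelEffects] = {
    "area": ChannelEffects(area_effect=3.0),
    "color": ChannelEffects(color_effect=4.0),
    "contour": ChannelEffects(contour_effect=6.0),
    "background": ChannelEffects(background_effect=3.0),
}

#: shared desk-scale study conditions for the validation experiments
STUDY = dict(n_per_class=80, image_size=128, target_size=96, day=2)


def binomial_chance_band(n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Central (1-alpha) binomial interval around accuracy 0.5 at size n."""
    from scipy.stats import binom

    lo, hi = binom.interval(1.0 - alpha, n, 0.5)
    return lo / n, hi / n


def _sub_seeds(base_seed: int, n: int) -> List[int]:
    return [int(s) for s in SeedSequence(base_seed).generate_state(n) % (2**31)]


def _study_dataset(effects: ChannelEffects, seed: int, line: str = "syn",
                   n_per_class: Optional[int] = None):
    return generate_dataset(SyntheticDatasetConfig(
        n_per_class=n_per_class or STUDY["n_per_class"],
        image_size=STUDY["image_size"], effects=effects,
        growth=GrowthModel(day=STUDY["day"]), line=line, seed=seed,
    ))


def channel_ablation_grid(base_seed: int, trials: int = 5,
                          epochs: int = 500) -> pd.DataFrame:
    """The feature-ablation information-dissection experiment.

    Four synthetic datasets, each discriminative through exactly one channel,
    are classified under no ablation, background masking, binarization and
    severe blur. Returns a long-format table of mean test accuracy per
    (channel, ablation).
    """
    from .ablation import AblationType

    backbone = TinyConvBackbone()
    cfg = desk_preprocess_config(STUDY["image_size"], STUDY["target_size"])
    hp = TrainHyperparams(epochs=epochs)
    data_seed, trial_seed = _sub_seeds(base_seed, 2)
    rows = []
    for channel, effects in CHANNEL_EFFECTS.items():
        dataset = _study_dataset(effects, data_seed)
        for kind in AblationType:
            rep = run_trials(dataset, backbone, n_trials=trials,
                             base_seed=trial_seed, hyperparams=hp,
                             ablation_kind=kind, preprocess_config=cfg)
            rows.append(dict(channel=channel, ablation=kind.value,
                             accuracy_mean=rep.accuracy,
                             accuracy_sd=rep.accuracy_sd,
                             n_test_per_trial=rep.per_trial[0].n))
    return pd.DataFrame(rows)


def permutation_control_experiment(base_seed: int, trials: int = 5,
                                   epochs: int = 500) -> pd.DataFrame:
    """Negative control: the full protocol on randomly permuted labels."""
    backbone = TinyConvBackbone()
    cfg = desk_preprocess_config(STUDY["image_size"], STUDY["target_size"])
    data_seed, trial_seed = _sub_seeds(base_seed, 2)
    dataset = _study_dataset(CHANNEL_EFFECTS["area"], data_seed)
    rep = run_trials(dataset, backbone, n_trials=trials,
                     base_seed=trial_seed, hyperparams=TrainHyperparams(epochs=epochs),
                     preprocess_config=cfg, permute_labels=True)
    return pd.DataFrame([dict(trial=i, accuracy=r.accuracy, n_test=r.n)
                         for i, r in enumerate(rep.per_trial)])


def localization_experiment(effects, base_seed: int, epochs: int = 500,
                            n_null_draws: int = 20,
                            n_null_medians: int = 199) -> Dict:
    """Grad-CAM localization versus the plant silhouette.

    Trains one classifier, attributes all correctly predicted test images,
    and compares the median heatmap/plant IoU to a permutation baseline of
    random same-area disk masks. The p-value is the fraction of null medians
    at least as large as the observed median.
    """
    from .xai_validation import (binarize_heatmap, iou, random_same_area_mask,
                                 score_images)

    backbone = TinyConvBackbone()
    cfg = desk_preprocess_config(STUDY["image_size"], STUDY["target_size"])
    data_seed, fit_seed, null_seed = _sub_seeds(base_seed, 3)
    dataset = _study_dataset(effects, data_seed)
    report, clf, spec, _ = train_classifier(
        dataset, backbone, seed=fit_seed, preprocess_config=cfg,
        hyperparams=TrainHyperparams(epochs=epochs))
    maps, pmasks, meta = attribute_test_images(clf, dataset, spec, ["gradcam"])
    scores = score_images(maps, pmasks, meta)
    ok = scores[scores.correct]
    rng = np.random.default_rng(null_seed)
    correct_pairs = [(m, p) for m, p, c in zip(maps, pmasks, meta["correct"]) if c]
    null_per_image = np.array([
        [iou(random_same_area_mask(binarize_heatmap(amap), rng), pmask)
         for _ in range(n_null_draws)]
        for amap, pmask in correct_pairs
    ])
    null_medians = [
        float(np.median(null_per_image[np.arange(len(correct_pairs)),
                                       rng.integers(0, n_null_draws,
                                                    len(correct_pairs))]))
        for _ in range(n_null_medians)
    ]
    observed = float(ok["iou"].median())
    p_value = (1 + sum(m >= observed for m in null_medians)) / (1 + n_null_medians)
    return dict(
        accuracy=report.accuracy,
        median_iou=observed,
        null_median_iou=float(np.median(null_medians)),
        p_value=float(p_value),
        median_area_fraction=float(ok["area_fraction"].median()),
        n_correct=int(len(ok)),
    )


def transfer_asymmetry_experiment(base_seed: int, n_seeds: int = 5,
                                  epochs: int = 500) -> pd.DataFrame:
    """Cross-population transfer with planted shared/private channels.

    Pair A differs through a large area effect plus a color effect; pair B
    inherits only the color difference at half strength. A classifier
    trained on the shared (subset) channel transfers to A; a classifier
    trained on A latches onto the easy private area difference and transfers
    to B near chance. Evaluation uses the target's own 20% test split.
    """
    from .transfer import transfer_predict

    backbone = TinyConvBackbone()
    cfg = desk_preprocess_config(STUDY["image_size"], STUDY["target_size"])
    hp = TrainHyperparams(epochs=epochs)
    eff_a = ChannelEffects(area_effect=5.0, color_effect=4.0)
    eff_b = ChannelEffects(color_effect=2.0)
    rows = []
    seeds = _sub_seeds(base_seed, 3 * n_seeds)
    for k in range(n_seeds):
        sa, sb, sf = seeds[3 * k:3 * k + 3]
        ds_a = _study_dataset(eff_a, sa, line="pairA")
        ds_b = _study_dataset(eff_b, sb, line="pairB")
        _, clf_a, _, _ = train_classifier(ds_a, backbone, seed=sf,
                                          preprocess_config=cfg, hyperparams=hp)
        _, clf_b, _, _ = train_classifier(ds_b, backbone, seed=sf,
                                          preprocess_config=cfg, hyperparams=hp)
        a2b = transfer_predict(clf_a, ds_b, source_pair="A",
                               target_split="test", split_seed=sf)
        b2a = transfer_predict(clf_b, ds_a, source_pair="B",
                               target_split="test", split_seed=sf)
        rows.append(dict(seed=k, a_to_b=a2b.accuracy, b_to_a=b2a.accuracy,
                         a_to_b_mcc=a2b.mcc, b_to_a_mcc=b2a.mcc,
                         n_target=a2b.report.n))
    return pd.DataFrame(rows)


def effect_size_recovery(base_seed: int, n_seeds: int = 20,
                         n_per_class: int = 200,
                         area_effect: float = 1.0) -> pd.DataFrame:
    """Generate datasets with a planted standardized log-area difference and
    recompute Hedges' g from the rendered silhouette areas."""
    from .segmentation import hedges_g

    rows = []
    for k, seed in enumerate(_sub_seeds(base_seed, n_seeds)):
        cfg = SyntheticDatasetConfig(
            n_per_class=n_per_class, image_size=64,
            effects=ChannelEffects(area_effect=area_effect),
            growth=GrowthModel(day=3), seed=seed, scale_bar=False)
        logs = {"male": [], "female": []}
        for rec, mask in generate_dataset(cfg):
            logs[rec.label].append(np.log(mask.area_px))
        rows.append(dict(seed=k, g=hedges_g(logs["female"], logs["male"]).g))
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> Dict:
    """Execute the full protocol and write tables plus a summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    summary: Dict = {"schema_version": 1, "stages": {}}
    stage = "generate"
    try:
        t0 = time.time()
        dataset = make_dataset(config)
        log.info("generated %d images in %.1fs", len(dataset), time.time() - t0)

        stage = "train"
        backbone = TinyConvBackbone()
        cfg = desk_preprocess_config(config.image_size, config.target_size)
        hp = TrainHyperparams(epochs=config.epochs)
        report = run_trials(
            dataset, backbone, n_trials=config.trials, base_seed=config.seed,
            hyperparams=hp, ablation_kind=config.ablation_kind,
            preprocess_config=cfg, permute_labels=config.permutation_control,
        )
        trials = pd.DataFrame(
            [dict(trial=i, accuracy=r.accuracy, mcc=r.mcc)
             for i, r in enumerate(report.per_trial)]
        )
        trials.to_csv(outdir / "trials.csv", index=False)
        summary["test_accuracy_mean"] = report.accuracy
        summary["test_accuracy_sd"] = report.accuracy_sd
        summary["mcc_pooled"] = report.mcc
        summary["confusion_pooled"] = report.confusion.tolist()

        stage = "attribution"
        if config.attribution_methods and not config.permutation_control:
            _, clf, spec, _ = train_classifier(
                dataset, backbone, seed=config.seed,
                ablation_kind=config.ablation_kind, preprocess_config=cfg,
                hyperparams=hp,
            )
            maps, pmasks, meta = attribute_test_images(
                clf, dataset, spec, config.attribution_methods
            )
            scores = score_images(maps, pmasks, meta)
            scores.to_csv(outdir / "iou_scores.csv", index=False)
            summ = summarize_iou(scores)
            summ.to_csv(outdir / "iou_summary.csv", index=False)
            summary["iou_median_by_group"] = summ.to_dict(orient="records")
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        raise
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
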