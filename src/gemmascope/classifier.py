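"""Last-layer transfer classifier: split, train, evaluate, multi-trial protocol.

The backbone stays frozen; only a 2-logit affine head on the pooled features
is trained, by minibatch cross-entropy with Adam (learning rate 0.001, batch
size 32, 500 epochs), keeping the checkpoint with maximum validation accuracy
(earliest epoch on ties). Data are split 64:16:20 into train/validation/test,
stratified by class; the dihedral augmentation applies only to the training
partition and all variants of a source image stay in its partition.

The multi-trial protocol repeats split + head initialization with independent
seeds and reports mean +/- SD of test accuracy; the permutation negative
control re-runs the whole protocol with randomly permuted class labels, which
must land at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.random import SeedSequence, default_rng

from .ablation import AblationType, ablate_dataset
from .backbone import BackboneAdapter, to_nchw
from .preprocessing import PreprocessConfig, preprocess
from .types import ImageRecord, SilhouetteMask, LABELS, label_index

# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive, class-stratified id partition."""

    train_ids: Tuple[str, ...]
    val_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    fractions: Tuple[float, float, float]
    seed: int


def split_dataset(
    records: Sequence[ImageRecord],
    fractions: Tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitSpec:
    """Stratified random 64:16:20 split on source-image ids."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_class: Dict[str, List[str]] = {lab: [] for lab in LABELS}
    for rec in records:
        by_class[rec.label].append(rec.id)
    for lab, ids in by_class.items():
        if not ids:
            raise ValueError(f"class {lab!r} absent from dataset")
        if len(ids) < 5:
            raise ValueError(f"need >= 5 records per class, class {lab!r} has {len(ids)}")
    rng = default_rng(seed)
    train, val, test = [], [], []
    for lab in LABELS:
        ids = sorted(by_class[lab])
        rng.shuffle(ids)
        n = len(ids)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n - 2)
        n_va = max(1, min(n_va, n - n_tr - 1))
        train += ids[:n_tr]
        val += ids[n_tr:n_tr + n_va]
        test += ids[n_tr + n_va:]
    return SplitSpec(tuple(train), tuple(val), tuple(test), tuple(fractions), seed)


def permutation_control(records: Sequence[ImageRecord], seed: int = 0) -> List[ImageRecord]:
    """Randomly permute class labels across records (before splitting).

    The label multiset is preserved; only the assignment changes. Used as the
    negative control: downstream test accuracy must be indistinguishable from
    chance.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    rng = default_rng(seed)
    labels = [rec.label for rec in records]
    perm = rng.permutation(len(labels))
    return [replace(rec, label=labels[j]) for rec, j in zip(records, perm)]


# ---------------------------------------------------------------------------
# head training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainHyperparams:
    """The minimal training recipe: Adam, lr 0.001, batch 32, 500 epochs,
    checkpoint at maximum validation accuracy."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 500

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive; epochs >= 1")


@dataclass
class TrainedClassifier:
    """Frozen backbone plus trained 2-logit affine head and its training log."""

    backbone: BackboneAdapter
    head_w: np.ndarray  # (2, pooled_dim)
    head_b: np.ndarray  # (2,)
    train_log: Optional[List[Tuple[float, float]]] = None  # per-epoch (train, val) accuracy
    selected_epoch: int = -1
    preprocess_config: Optional[PreprocessConfig] = None

    def logits_from_features(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.head_w.T + self.head_b[None, :]


def _accuracy(logits: np.ndarray, y: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == y).mean())


def fit_head(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hyperparams: TrainHyperparams = TrainHyperparams(),
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[float, float]], int]:
    """Train the affine head on fixed features; returns (W, b, log, best_epoch).

    Minibatch softmax cross-entropy with Adam; head initialized with
    zero-mean small-variance draws from ``seed``. The returned parameters are
    the checkpoint with maximal validation accuracy (earliest tie).

    Features are standardized with training-set statistics before the affine
    map (the usual conditioning for a linear probe over pooled deep
    features); the standardization is folded back into the returned (W, b),
    which therefore act on raw features.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    # variance floor: near-constant (rarely firing) features would otherwise
    # be inflated into spuriously dominant inputs
    floor = 0.1 * np.median(sd[sd > 0]) if (sd > 0).any() else 1.0
    sd = np.sqrt(sd**2 + floor**2)
    x_train = (x_train - mu) / sd
    x_val = (x_val - mu) / sd
    rng = default_rng(seed)
    n, d = x_train.shape
    w = rng.normal(0, 0.01, size=(2, d))
    b = np.zeros(2)
    m_w = np.zeros_like(w); v_w = np.zeros_like(w)
    m_b = np.zeros_like(b); v_b = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best = (-1.0, None, None, -1)
    log: List[Tuple[float, float]] = []
    for epoch in range(hyperparams.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hyperparams.batch_size):
            idx = order[start:start + hyperparams.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = xb @ w.T + b
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(p)):
                raise FloatingPointError("NaN/inf encountered in head training")
            g = p.copy()
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            gw = g.T @ xb
            gb = g.sum(axis=0)
            t += 1
            m_w = beta1 * m_w + (1 - beta1) * gw
            v_w = beta2 * v_w + (1 - beta2) * gw**2
            m_b = beta1 * m_b + (1 - beta1) * gb
            v_b = beta2 * v_b + (1 - beta2) * gb**2
            mhat_w = m_w / (1 - beta1**t); vhat_w = v_w / (1 - beta2**t)
            mhat_b = m_b / (1 - beta1**t); vhat_b = v_b / (1 - beta2**t)
            w -= hyperparams.learning_rate * mhat_w / (np.sqrt(vhat_w) + eps)
            b -= hyperparams.learning_rate * mhat_b / (np.sqrt(vhat_b) + eps)
        tr_acc = _accuracy(x_train @ w.T + b, y_train)
        va_acc = _accuracy(x_val @ w.T + b, y_val)
        log.append((tr_acc, va_acc))
        if va_acc > best[0]:
            best = (va_acc, w.copy(), b.copy(), epoch)
    w_best, b_best = best[1], best[2]
    # fold standardization into the affine head: W' = W/sd, b' = b - W mu/sd
    w_raw = w_best / sd[None, :]
    b_raw = b_best - w_raw @ mu
    return w_raw, b_raw, log, best[3]


def train_head(
    backbone: BackboneAdapter,
    train_set: Sequence[Tuple],
    val_set: Sequence[Tuple],
    hyperparams: TrainHyperparams = TrainHyperparams(),
    seed: int = 0,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> TrainedClassifier:
    """Train the head from (NormalizedImage, label) pairs.

    ``label`` may be a class string or an integer index. Features are
    extracted once (the backbone is frozen) and the head fitted on them.
    """
    def to_xy(items):
        imgs = [im for im, _ in items]
        ys = np.array([lab if isinstance(lab, (int, np.integer)) else label_index(lab)
                       for _, lab in items])
        return backbone.features(to_nchw(imgs)), ys

    x_tr, y_tr = to_xy(train_set)
    x_va, y_va = to_xy(val_set)
    w, b, log, best_epoch = fit_head(x_tr, y_tr, x_va, y_va, hyperparams, seed)
    return TrainedClassifier(
        backbone=backbone, head_w=w, head_b=b, train_log=log,
        selected_epoch=best_epoch, preprocess_config=preprocess_config,
    )


def predict(
    classifier: TrainedClassifier, images: Sequence
) -> Tuple[List[str], np.ndarray]:
    """Predicted labels and raw 2-logit outputs for eval-preprocessed images."""
    feats = classifier.backbone.features(to_nchw(images))
    logits = classifier.logits_from_features(feats)
    labels = [LABELS[i] for i in logits.argmax(axis=1)]
    return labels, logits


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def confusion_matrix_2x2(true_idx: np.ndarray, pred_idx: np.ndarray) -> np.ndarray:
    """2x2 counts, rows = true class, columns = predicted class."""
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(true_idx, pred_idx):
        cm[t, p] += 1
    return cm


def mcc_from_confusion(cm: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fn = float(cm[1, 1]), float(cm[1, 0])
    tn, fp = float(cm[0, 0]), float(cm[0, 1])
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


@dataclass
class EvalReport:
    """Confusion matrix plus accuracy and MCC; optionally per-trial values."""

    confusion: np.ndarray
    accuracy: float
    mcc: float
    per_trial: Optional[List["EvalReport"]] = None

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def trial_accuracies(self) -> np.ndarray:
        if not self.per_trial:
            return np.array([self.accuracy])
        return np.array([r.accuracy for r in self.per_trial])

    @property
    def accuracy_sd(self) -> float:
        accs = self.trial_accuracies
        return float(accs.std(ddof=1)) if len(accs) > 1 else 0.0


def evaluate(predictions: Sequence[str], truths: Sequence[str]) -> EvalReport:
    """Confusion matrix, accuracy and MCC for aligned prediction/truth lists."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    t = np.array([label_index(x) for x in truths])
    p = np.array([label_index(x) for x in predictions])
    cm = confusion_matrix_2x2(t, p)
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return EvalReport(confusion=cm, accuracy=acc, mcc=mcc_from_confusion(cm))


# ---------------------------------------------------------------------------
# feature bank + multi-trial protocol
# ---------------------------------------------------------------------------


@dataclass
class FeatureBank:
    """Precomputed frozen-backbone features for one dataset x ablation.

    ``eval_feats[id]`` is the eval-mode feature row; ``train_feats[id]`` the
    stacked features of the dihedral training variants. Because the backbone
    is frozen, trials re-split and re-train heads on these cached features
    without touching images again.
    """

    ids: List[str]
    labels: Dict[str, int]
    eval_feats: Dict[str, np.ndarray]
    train_feats: Dict[str, np.ndarray]


def build_feature_bank(
    dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]],
    backbone: BackboneAdapter,
    ablation_kind: AblationType = AblationType.NONE,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
) -> FeatureBank:
    """Ablate, preprocess and featurize a dataset once."""
    ablated = ablate_dataset(dataset, ablation_kind)
    ids, labels = [], {}
    eval_imgs, train_imgs, train_counts = [], [], []
    for rec in ablated:
        ids.append(rec.id)
        labels[rec.id] = rec.label_idx
        eval_imgs.append(preprocess(rec.pixels, "eval", preprocess_config))
        variants = preprocess(rec.pixels, "train", preprocess_config)
        train_imgs.extend(variants)
        train_counts.append(len(variants))
    ev = backbone.features(to_nchw(eval_imgs))
    tr = backbone.features(to_nchw(train_imgs))
    eval_feats = {i: ev[k] for k, i in enumerate(ids)}
    train_feats = {}
    pos = 0
    for i, cnt in zip(ids, train_counts):
        train_feats[i] = tr[pos:pos + cnt]
        pos += cnt
    return FeatureBank(ids=ids, labels=labels, eval_feats=eval_feats, train_feats=train_feats)


def _trial_from_bank(
    bank: FeatureBank,
    records: Sequence[ImageRecord],
    split_seed: int,
    init_seed: int,
    hyperparams: TrainHyperparams,
) -> Tuple[EvalReport, TrainedClassifier, SplitSpec]:
    spec = split_dataset(records, seed=split_seed)
    x_tr = np.concatenate([bank.train_feats[i] for i in spec.train_ids])
    y_tr = np.concatenate(
        [np.full(len(bank.train_feats[i]), bank.labels[i]) for i in spec.train_ids]
    )
    x_va = np.stack([bank.eval_feats[i] for i in spec.val_ids])
    y_va = np.array([bank.labels[i] for i in spec.val_ids])
    x_te = np.stack([bank.eval_feats[i] for i in spec.test_ids])
    y_te = np.array([bank.labels[i] for i in spec.test_ids])
    w, b, log, best = fit_head(x_tr, y_tr, x_va, y_va, hyperparams, init_seed)
    logits = x_te @ w.T + b
    preds = [LABELS[i] for i in logits.argmax(axis=1)]
    report = evaluate(preds, [LABELS[i] for i in y_te])
    clf = TrainedClassifier(backbone=None, head_w=w, head_b=b, train_log=log,
                            selected_epoch=best)
    return report, clf, spec


def run_trials(
    dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]],
    backbone: BackboneAdapter,
    n_trials: int = 5,
    base_seed: int = 0,
    hyperparams: TrainHyperparams = TrainHyperparams(),
    ablation_kind: AblationType = AblationType.NONE,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    permute_labels: bool = False,
) -> EvalReport:
    """Five-trial protocol: independent split + head-init seeds per trial.

    Returns an aggregate report (summed confusion matrix, mean accuracy) with
    per-trial reports attached. ``permute_labels`` runs the negative control.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    records = [rec for rec, _ in dataset]
    if permute_labels:
        perm_seed = int(SeedSequence(base_seed).generate_state(1)[0] % (2**31))
        permuted = permutation_control(records, seed=perm_seed)
        dataset = [(rec, mask) for rec, (_, mask) in zip(permuted, dataset)]
        records = permuted
    bank = build_feature_bank(dataset, backbone, ablation_kind, preprocess_config)
    seeds = SeedSequence(base_seed).generate_state(2 * n_trials) % (2**31)
    trials = []
    for k in range(n_trials):
        report, _, _ = _trial_from_bank(
            bank, records, int(seeds[2 * k]), int(seeds[2 * k + 1]), hyperparams
        )
        trials.append(report)
    cm = np.sum([r.confusion for r in trials], axis=0)
    acc = float(np.mean([r.accuracy for r in trials]))
    mcc = mcc_from_confusion(cm)
    return EvalReport(confusion=cm, accuracy=acc, mcc=mcc, per_trial=trials)
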