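"""Split protocol, head training, evaluation metrics, multi-trial runs."""

import numpy as np
import pytest

from gemmascope.classifier import (TrainHyperparams, confusion_matrix_2x2,
                                   evaluate, fit_head, mcc_from_confusion,
                                   permutation_control, run_trials,
                                   split_dataset, predict, TrainedClassifier)
from gemmascope.types import ImageRecord, LABELS


def _records(n_per_class=50):
    out = []
    for i in range(n_per_class):
        for lab in LABELS:
            out.append(ImageRecord(
                id=f"{lab}-{i:03d}", pixels=np.zeros((8, 8, 3), np.uint8),
                label=lab, line="syn", day=0))
    return out


class TestSplit:
    def test_ratio_and_stratification(self):
        spec = split_dataset(_records(50), seed=1)
        assert len(spec.train_ids) == 64
        assert len(spec.val_ids) == 16
        assert len(spec.test_ids) == 20
        for part in (spec.train_ids, spec.val_ids, spec.test_ids):
            labs = [i.split("-")[0] for i in part]
            assert abs(labs.count("male") - labs.count("female")) <= 1

    def test_partition_laws(self):
        recs = _records(25)
        spec = split_dataset(recs, seed=3)
        parts = [set(spec.train_ids), set(spec.val_ids), set(spec.test_ids)]
        assert parts[0] | parts[1] | parts[2] == {r.id for r in recs}
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_deterministic_per_seed(self):
        recs = _records(20)
        assert split_dataset(recs, seed=9) == split_dataset(recs, seed=9)
        assert split_dataset(recs, seed=9) != split_dataset(recs, seed=10)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_records(4), seed=0)


class TestPermutationControl:
    def test_label_histogram_preserved(self):
        recs = _records(10)
        perm = permutation_control(recs, seed=5)
        assert sorted(r.label for r in perm) == sorted(r.label for r in recs)

    def test_same_seed_same_permutation(self):
        recs = _records(10)
        a = [r.label for r in permutation_control(recs, seed=5)]
        b = [r.label for r in permutation_control(recs, seed=5)]
        assert a == b

    def test_actually_permutes(self):
        recs = _records(30)
        perm = permutation_control(recs, seed=1)
        assert any(a.label != b.label for a, b in zip(recs, perm))


class TestEvaluate:
    @pytest.mark.parametrize("confusion, acc, mcc", [
        (np.array([[10, 0], [0, 10]]), 1.0, 1.0),
        (np.array([[5, 5], [5, 5]]), 0.5, 0.0),
        (np.array([[8, 2], [4, 6]]), 0.7, 0.40824829),
    ])
    def test_worked_confusions(self, confusion, acc, mcc):
        truths, preds = [], []
        for t in range(2):
            for p in range(2):
                truths += [LABELS[t]] * confusion[t, p]
                preds += [LABELS[p]] * confusion[t, p]
        rep = evaluate(preds, truths)
        assert np.array_equal(rep.confusion, confusion)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.mcc == pytest.approx(mcc, abs=1e-6)

    def test_mcc_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            ours = mcc_from_confusion(confusion_matrix_2x2(t, p))
            theirs = matthews_corrcoef(t, p)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["male"], ["hermaphrodite"])


class TestFitHead:
    def test_separable_features_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        x0 = rng.normal(-2, 0.3, (40, 8))
        x1 = rng.normal(2, 0.3, (40, 8))
        x = np.vstack([x0, x1])
        y = np.array([0] * 40 + [1] * 40)
        w, b, log, best = fit_head(x, y, x[:10], y[:10],
                                   TrainHyperparams(epochs=30), seed=0)
        assert max(tr for tr, _ in log) == 1.0

    def test_checkpoint_earliest_max_validation(self):
        # two interleaved feature clusters: validation accuracy saturates
        # early; the selected epoch must be the first argmax
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (60, 4))
        y = (x[:, 0] > 0).astype(int)
        w, b, log, best = fit_head(x, y, x, y, TrainHyperparams(epochs=20), seed=0)
        vals = [va for _, va in log]
        assert best == int(np.argmax(vals))

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            fit_head(np.zeros((0, 3)), np.zeros(0, int),
                     np.zeros((2, 3)), np.zeros(2, int))

    def test_zero_weight_head_predicts_constant(self, backbone):
        clf = TrainedClassifier(
            backbone=backbone, head_w=np.zeros((2, backbone.pooled_dim)),
            head_b=np.array([0.0, 1.0]))
        imgs = [np.random.default_rng(3).normal(size=(16, 16, 3)).astype(np.float32)
                for _ in range(3)]
        labels, logits = predict(clf, imgs)
        assert labels == ["female"] * 3
        assert np.allclose(logits, [0.0, 1.0])


class TestRunTrials:
    def test_five_trials_aggregate(self, small_dataset, backbone, desk_config):
        rep = run_trials(small_dataset, backbone, n_trials=3, base_seed=0,
                         hyperparams=TrainHyperparams(epochs=25),
                         preprocess_config=desk_config)
        assert len(rep.per_trial) == 3
        assert rep.confusion.sum() == sum(r.n for r in rep.per_trial)
        accs = rep.trial_accuracies
        assert rep.accuracy == pytest.approx(accs.mean())

    def test_identical_accuracies_zero_sd(self):
        from gemmascope.classifier import EvalReport

        sub = EvalReport(confusion=np.array([[5, 0], [0, 5]]), accuracy=1.0, mcc=1.0)
        rep = EvalReport(confusion=sub.confusion * 2, accuracy=1.0, mcc=1.0,
                         per_trial=[sub, sub])
        assert rep.accuracy_sd == 0.0

    def test_n_trials_lower_bound(self, small_dataset, backbone):
        with pytest.raises(ValueError):
            run_trials(small_dataset, backbone, n_trials=1)
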