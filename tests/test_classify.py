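"""Classifier training contracts and the evaluation-metric oracle."""

import numpy as np
import pytest

from xferlang._cnn import CNNParams
from xferlang.classify import (LabeledVectorSet, encode_sequences, evaluate,
                               predict, train_cnn, train_rf)


def _separable_set(n=80, d=10, seed=0, tag="train"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    labels = ["malignant" if i < n // 2 else "benign" for i in range(n)]
    X[: n // 2, 0] += 10.0
    return LabeledVectorSet(report_ids=[f"r{i}" for i in range(n)],
                            vectors=X, labels=labels, split_tag=tag)


class TestRandomForest:
    def test_memorizes_separable_vectors(self):
        train = _separable_set()
        model = train_rf(train, seed=0)
        labels, scores = predict(model, train.vectors)
        assert labels == train.labels
        assert np.all((scores >= 0) & (scores <= 1))

    def test_same_seed_same_predictions(self):
        train = _separable_set(seed=1)
        test = _separable_set(seed=2, tag="test_templated")
        a = predict(train_rf(train, seed=3), test.vectors)
        b = predict(train_rf(train, seed=3), test.vectors)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_consistent_column_permutation_preserves_accuracy(self):
        train, test = _separable_set(seed=1), _separable_set(seed=2)
        perm = np.random.default_rng(0).permutation(train.vectors.shape[1])
        base = predict(train_rf(train, seed=3), test.vectors)[0]
        train_p = LabeledVectorSet(train.report_ids, train.vectors[:, perm],
                                   train.labels)
        shuf = predict(train_rf(train_p, seed=3), test.vectors[:, perm])[0]
        acc = lambda pred: np.mean([p == t for p, t in zip(pred, test.labels)])
        assert acc(base) == acc(shuf)

    def test_single_class_training_is_error(self):
        s = _separable_set()
        bad = LabeledVectorSet(s.report_ids, s.vectors,
                               ["benign"] * len(s.labels))
        with pytest.raises(ValueError):
            train_rf(bad)

    def test_empty_input_empty_output(self):
        model = train_rf(_separable_set(), seed=0)
        labels, scores = predict(model, np.zeros((0, 10)))
        assert labels == [] and scores.size == 0


def _toy_sequences(n=120, V=40, seed=0):
    rng = np.random.default_rng(seed)
    vocab = {f"t{i}": i for i in range(V)}
    seqs, labels = [], []
    for k in range(n):
        s = [f"t{i}" for i in rng.integers(5, V, size=15)]
        if k % 2 == 0:
            s[int(rng.integers(15))] = "t1"
            labels.append("malignant")
        else:
            labels.append("benign")
        seqs.append(s)
    return seqs, labels, vocab


class TestCNN:
    def test_embedding_initialisation_is_exact(self):
        seqs, labels, vocab = _toy_sequences()
        rng = np.random.default_rng(9)
        table = rng.normal(size=(len(vocab), 16))
        hp = CNNParams(dim=16, epochs=0, max_len=20)
        model = train_cnn(seqs, labels, vocab, embedding_init=table,
                          hyperparams=hp, seed=0)
        assert model.kind == "cnn_pretrained"
        assert np.array_equal(model.fitted.E[1:], table)
        assert np.all(model.fitted.E[0] == 0)      # frozen pad row

    def test_table_shape_mismatch_is_error(self):
        seqs, labels, vocab = _toy_sequences()
        with pytest.raises(ValueError):
            train_cnn(seqs, labels, vocab,
                      embedding_init=np.zeros((3, 16)),
                      hyperparams=CNNParams(dim=16), seed=0)

    def test_no_dropout_fixed_seed_identical_weights(self):
        seqs, labels, vocab = _toy_sequences()
        hp = CNNParams(dim=16, epochs=2, dropout=0.0, max_len=20)
        a = train_cnn(seqs, labels, vocab, hyperparams=hp, seed=4)
        b = train_cnn(seqs, labels, vocab, hyperparams=hp, seed=4)
        assert np.array_equal(a.fitted.W, b.fitted.W)
        assert np.array_equal(a.fitted.E, b.fitted.E)

    def test_training_loss_decreases(self):
        seqs, labels, vocab = _toy_sequences()
        hp = CNNParams(dim=16, epochs=8, dropout=0.0, max_len=20, lr=5e-3)
        model = train_cnn(seqs, labels, vocab, hyperparams=hp, seed=0)
        assert model.training_losses[-1] < model.training_losses[0]

    def test_scores_bounded_and_threshold_applied(self):
        seqs, labels, vocab = _toy_sequences()
        hp = CNNParams(dim=16, epochs=2, max_len=20)
        model = train_cnn(seqs, labels, vocab, hyperparams=hp, seed=0)
        pred, scores = predict(model, seqs)
        assert np.all((scores >= 0) & (scores <= 1))
        for p, s in zip(pred, scores):
            assert p == ("malignant" if s >= 0.5 else "benign")

    def test_representation_mismatch_is_error(self):
        seqs, labels, vocab = _toy_sequences()
        model = train_cnn(seqs, labels, vocab,
                          hyperparams=CNNParams(dim=16, epochs=0, max_len=20),
                          seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((4, 16)))


class TestEncodeSequences:
    def test_padding_and_oov_dropping(self):
        vocab = {"a": 0, "b": 1}
        out = encode_sequences([["a", "zzz", "b"], []], vocab, max_len=4)
        assert out.tolist() == [[1, 2, 0, 0], [0, 0, 0, 0]]


class TestEvaluate:
    def test_perfect_predictions_all_ones(self):
        truth = [(f"r{i}", "malignant" if i % 3 == 0 else "benign")
                 for i in range(30)]
        ev = evaluate(truth, truth)
        assert ev.weighted_f1 == 1.0
        for cls in ("malignant", "benign"):
            assert ev.per_class[cls] == {"precision": 1.0, "recall": 1.0,
                                         "f1": 1.0}

    def test_all_benign_under_class_imbalance(self):
        """90 benign / 10 malignant, everything predicted benign: benign
        f1 = 2*0.9/1.9 ~ 0.947, weighted f1 = 0.9 * 0.947 ~ 0.853."""
        truth = [(f"r{i}", "malignant" if i < 10 else "benign")
                 for i in range(100)]
        preds = [(f"r{i}", "benign") for i in range(100)]
        ev = evaluate(preds, truth)
        assert ev.per_class["benign"]["precision"] == pytest.approx(0.9)
        assert ev.per_class["benign"]["recall"] == 1.0
        assert ev.per_class["benign"]["f1"] == pytest.approx(0.947, abs=5e-4)
        assert ev.per_class["malignant"]["f1"] == 0.0
        assert ev.weighted_f1 == pytest.approx(0.853, abs=5e-4)

    def test_matches_sklearn_on_random_sets(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            y = rng.choice(["malignant", "benign"], size=n)
            if len(set(y)) < 2:
                continue
            p = rng.choice(["malignant", "benign"], size=n)
            ids = [f"r{i}" for i in range(n)]
            ev = evaluate(list(zip(ids, p)), list(zip(ids, y)))
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, labels=["malignant", "benign"], zero_division=0)
            assert abs(ev.per_class["malignant"]["precision"] - prec[0]) <= 1e-9
            assert abs(ev.per_class["benign"]["recall"] - rec[1]) <= 1e-9
            assert abs(ev.per_class["malignant"]["f1"] - f1[0]) <= 1e-9
            from sklearn.metrics import f1_score
            wf1 = f1_score(y, p, average="weighted", zero_division=0)
            assert abs(ev.weighted_f1 - wf1) <= 1e-9

    def test_id_mismatch_is_error(self):
        with pytest.raises(ValueError):
            evaluate([("a", "benign")], [("b", "benign")])
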