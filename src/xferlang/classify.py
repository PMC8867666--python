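"""Predictive models: report-vector Random Forest and 1D-CNN classifiers.

Three classifier kinds mirror the study design: ``rf`` (Random Forest on
mean-of-token-vector report embeddings), ``cnn_random`` (1D-CNN whose
embedding layer starts random) and ``cnn_pretrained`` (the same CNN with its
embedding layer initialised from a word-embedding model, so the classifier
inherits what the language model learned from unlabelled text).  Evaluation
reports per-class precision/recall/f1 and the support-weighted f1 summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._cnn import CNNParams, TextCNN
from .preprocess import TokenizedReport
from .w2v import ReportVector, WordEmbeddingModel

__all__ = [
    "LabeledVectorSet",
    "ClassifierModel",
    "EvalResult",
    "RFParams",
    "CNNParams",
    "train_rf",
    "train_cnn",
    "predict",
    "evaluate",
    "encode_sequences",
]

MALIGNANT, BENIGN = "malignant", "benign"


@dataclass
class LabeledVectorSet:
    """Report vectors with labels for one split."""
    report_ids: list[str]
    vectors: np.ndarray          # N x d
    labels: list[str]            # MALIGNANT | BENIGN
    split_tag: str = "train"     # train | test_templated | test_untemplated

    def __post_init__(self):
        if not (len(self.report_ids) == self.vectors.shape[0] == len(self.labels)):
            raise ValueError("ids, vectors and labels must align")
        bad = set(self.labels) - {MALIGNANT, BENIGN}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")

    @classmethod
    def from_report_vectors(cls, vectors: Sequence[ReportVector],
                            split_tag: str = "train") -> "LabeledVectorSet":
        return cls(report_ids=[v.report_id for v in vectors],
                   vectors=np.stack([v.values for v in vectors]),
                   labels=[v.label for v in vectors], split_tag=split_tag)


@dataclass(frozen=True)
class RFParams:
    n_estimators: int = 200
    max_depth: int | None = None
    max_features: str = "sqrt"


@dataclass
class ClassifierModel:
    kind: str                    # rf | cnn_random | cnn_pretrained
    hyperparams: object
    seed: int
    fitted: object = None        # RandomForestClassifier | TextCNN
    vocab: dict[str, int] | None = None     # token -> 0-based row (cnn only)
    embedding_model_id: str | None = None   # cnn_pretrained provenance
    threshold: float = 0.5
    training_losses: list = field(default_factory=list)


def train_rf(train: LabeledVectorSet, hyperparams: RFParams | None = None,
             seed: int = 0) -> ClassifierModel:
    """Fit the Random Forest on report vectors; deterministic given seed."""
    if len(set(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    hp = hyperparams or RFParams()
    clf = RandomForestClassifier(
        n_estimators=hp.n_estimators, max_depth=hp.max_depth,
        max_features=hp.max_features, random_state=seed, n_jobs=1)
    y = np.array([1 if l == MALIGNANT else 0 for l in train.labels])
    clf.fit(train.vectors, y)
    return ClassifierModel(kind="rf", hyperparams=hp, seed=seed, fitted=clf)


def encode_sequences(token_seqs: Sequence[Sequence[str]],
                     vocab: Mapping[str, int], max_len: int) -> np.ndarray:
    """Map token sequences to padded index matrices.

    Indices are vocabulary rows shifted by one; 0 is the pad index.  Tokens
    outside the vocabulary are dropped (they have no embedding row).
    """
    out = np.zeros((len(token_seqs), max_len), dtype=np.int64)
    for i, toks in enumerate(token_seqs):
        idx = [vocab[t] + 1 for t in toks if t in vocab][:max_len]
        out[i, :len(idx)] = idx
    return out


def train_cnn(train_sequences: Sequence[Sequence[str]], labels: Sequence[str],
              vocab: Mapping[str, int],
              embedding_init: np.ndarray | None = None,
              hyperparams: CNNParams | None = None,
              seed: int = 0) -> ClassifierModel:
    """Train the 1D-CNN; ``embedding_init`` (a V x d word-vector table aligned
    with ``vocab``) seeds the embedding layer exactly when given.  All layers
    remain trainable."""
    hp = hyperparams or CNNParams()
    if embedding_init is not None:
        if embedding_init.shape != (len(vocab), hp.dim):
            raise ValueError(
                f"embedding_init shape {embedding_init.shape} does not match "
                f"vocab size {len(vocab)} x dim {hp.dim}")
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    net = TextCNN(n_vocab=len(vocab), params=hp, seed=seed,
                  embedding_init=(np.asarray(embedding_init, dtype=float)
                                  if embedding_init is not None else None))
    X = encode_sequences(train_sequences, vocab, hp.max_len)
    y = np.array([1.0 if l == MALIGNANT else 0.0 for l in labels])
    losses = net.fit(X, y)
    kind = "cnn_pretrained" if embedding_init is not None else "cnn_random"
    return ClassifierModel(kind=kind, hyperparams=hp, seed=seed, fitted=net,
                           vocab=dict(vocab), training_losses=losses)


def predict(model: ClassifierModel, inputs) -> tuple[list[str], np.ndarray]:
    """Labels and malignancy scores for a batch of inputs.

    ``rf`` expects an N x d vector matrix (or a LabeledVectorSet); CNNs expect
    token sequences.  Deterministic given a fitted model.
    """
    if model.kind == "rf":
        if isinstance(inputs, LabeledVectorSet):
            inputs = inputs.vectors
        X = np.asarray(inputs, dtype=float)
        if X.size == 0:
            return [], np.zeros(0)
        if X.ndim != 2 or X.shape[1] != model.fitted.n_features_in_:
            raise ValueError("input vectors do not match the fitted forest")
        scores = model.fitted.predict_proba(X)[:, 1]
    elif model.kind in ("cnn_random", "cnn_pretrained"):
        if len(inputs) == 0:
            return [], np.zeros(0)
        if isinstance(inputs, np.ndarray) and inputs.ndim == 2:
            raise ValueError("CNN models take token sequences, not vectors")
        seqs = [s.tokens if isinstance(s, TokenizedReport) else s
                for s in inputs]
        X = encode_sequences(seqs, model.vocab, model.hyperparams.max_len)
        scores = model.fitted.predict_proba(X)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    labels = [MALIGNANT if s >= model.threshold else BENIGN for s in scores]
    return labels, scores


@dataclass(frozen=True)
class EvalResult:
    """Per-class precision/recall/f1 and support-weighted f1 for one cell."""
    per_class: dict            # {class: {"precision","recall","f1"}}
    weighted_f1: float
    support: dict              # {class: count}
    confusion: dict            # {"tp","fp","fn","tn"} w.r.t. malignant

    def as_row(self) -> dict:
        row = {}
        for cls in (MALIGNANT, BENIGN):
            for metric in ("precision", "recall", "f1"):
                row[f"{cls}_{metric}"] = self.per_class[cls][metric]
        row["weighted_f1"] = self.weighted_f1
        return row


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def evaluate(predictions: Sequence[tuple[str, str]],
             truth: Sequence[tuple[str, str]]) -> EvalResult:
    """Confusion-matrix metrics from aligned (id, label) pairs.

    Raises on any id mismatch: a prediction must exist for exactly the
    reports in the truth set, in any order.
    """
    pred = dict(predictions)
    true = dict(truth)
    if set(pred) != set(true):
        missing = set(true) ^ set(pred)
        raise ValueError(f"prediction/truth id mismatch: {sorted(missing)[:5]}")
    tp = sum(1 for i in true if true[i] == MALIGNANT and pred[i] == MALIGNANT)
    fn = sum(1 for i in true if true[i] == MALIGNANT and pred[i] == BENIGN)
    fp = sum(1 for i in true if true[i] == BENIGN and pred[i] == MALIGNANT)
    tn = sum(1 for i in true if true[i] == BENIGN and pred[i] == BENIGN)
    p_m, r_m, f_m = _prf(tp, fp, fn)
    p_b, r_b, f_b = _prf(tn, fn, fp)     # benign: swap roles
    n_m, n_b = tp + fn, tn + fp
    total = n_m + n_b
    if total == 0:
        raise ValueError("empty evaluation set")
    weighted = (n_m * f_m + n_b * f_b) / total
    return EvalResult(
        per_class={MALIGNANT: {"precision": p_m, "recall": r_m, "f1": f_m},
                   BENIGN: {"precision": p_b, "recall": r_b, "f1": f_b}},
        weighted_f1=weighted,
        support={MALIGNANT: n_m, BENIGN: n_b},
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )
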