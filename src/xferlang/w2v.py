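"""Context-independent word embeddings with cross-domain transfer.

Implements skipgram training with hierarchical softmax (a Huffman tree over
the vocabulary replaces the flat softmax), plus the transfer step that makes
similar-domain adaptation work: a target-domain model is initialised by
copying the source-domain vector of every shared-vocabulary token exactly,
with only genuinely new tokens starting from random, and is then fine-tuned
on the target corpus.  Training is sequential and fully deterministic for a
given seed.

The trainer is written here (numba-jitted inner loop) rather than delegated:
the exact initialise-then-continue-training contract on the raw vector table
is the package's central mechanism and needs bitwise control over it.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .preprocess import TokenizedReport

__all__ = [
    "WordEmbeddingModel",
    "ReportVector",
    "train_skipgram",
    "transfer_initialize",
    "finetune",
    "embed_report",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class WordEmbeddingModel:
    """Vocabulary + dense vector table + provenance."""

    model_id: str
    vocab: dict[str, int]            # token -> row index
    vectors: np.ndarray              # V x d, float32
    dim: int
    provenance: dict = field(default_factory=dict)   # domain, finetuned_from
    training_meta: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.vectors.shape != (len(self.vocab), self.dim):
            raise ValueError("vector table shape does not match vocab/dim")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector table contains non-finite entries")

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def __contains__(self, token: str) -> bool:
        return token in self.vocab


@dataclass(frozen=True)
class ReportVector:
    """Mean-of-token-vectors representation of one report."""
    report_id: str
    values: np.ndarray
    n_tokens_used: int
    label: str | None = None


# ---------------------------------------------------------------------------
# Huffman coding for hierarchical softmax
# ---------------------------------------------------------------------------

def _build_huffman(counts_desc: np.ndarray):
    """Classic two-pointer Huffman construction over frequency-sorted counts.

    Returns per-word binary codes and internal-node paths (root first);
    deterministic for a fixed count vector.
    """
    V = len(counts_desc)
    if V == 1:
        return [np.zeros(0, np.int64)], [np.zeros(0, np.int64)]
    count = np.empty(2 * V - 1, dtype=np.int64)
    count[:V] = counts_desc
    count[V:] = np.iinfo(np.int64).max
    parent = np.zeros(2 * V - 1, dtype=np.int64)
    binary = np.zeros(2 * V - 1, dtype=np.int64)
    pos1, pos2 = V - 1, V
    for a in range(V - 1):
        if pos1 >= 0 and count[pos1] < count[pos2]:
            min1, pos1 = pos1, pos1 - 1
        else:
            min1, pos2 = pos2, pos2 + 1
        if pos1 >= 0 and count[pos1] < count[pos2]:
            min2, pos1 = pos1, pos1 - 1
        else:
            min2, pos2 = pos2, pos2 + 1
        count[V + a] = count[min1] + count[min2]
        parent[min1] = V + a
        parent[min2] = V + a
        binary[min2] = 1
    codes, points = [], []
    root = 2 * V - 2
    for a in range(V):
        code_tmp, point_tmp = [], []
        b = a
        while b != root:
            code_tmp.append(binary[b])
            point_tmp.append(b)
            b = parent[b]
        n = len(code_tmp)
        code = np.array(code_tmp[::-1], dtype=np.int64)
        point = np.empty(n, dtype=np.int64)
        point[0] = root - V
        for i in range(1, n):
            point[i] = point_tmp[::-1][i - 1] - V
        codes.append(code)
        points.append(point)
    return codes, points


def _flatten_paths(codes, points):
    lens = np.array([len(c) for c in codes], dtype=np.int64)
    offs = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum(lens, out=offs[1:])
    flat_c = np.concatenate(codes) if offs[-1] else np.zeros(0, np.int64)
    flat_p = np.concatenate(points) if offs[-1] else np.zeros(0, np.int64)
    return flat_c, flat_p, offs


@njit(cache=False)
def _sg_hs_train(data, sent_offs, syn0, syn1, code_flat, point_flat,
                 path_offs, window, epochs, alpha0, min_alpha, seed,
                 trainable):
    """Sequential skipgram / hierarchical-softmax training loop.

    For each (center, context) pair the context vector predicts the Huffman
    path of the center word, as in the reference formulation.  A 64-bit LCG
    drives the per-position window shrink so runs are bit-reproducible.
    """
    total = data.shape[0] * epochs
    processed = 0
    state = np.uint64(seed * 25214903917 + 11)
    d = syn0.shape[1]
    neu1e = np.zeros(d, dtype=np.float32)
    for _ in range(epochs):
        for s in range(sent_offs.shape[0] - 1):
            start = sent_offs[s]
            end = sent_offs[s + 1]
            for pos in range(start, end):
                alpha = alpha0 - (alpha0 - min_alpha) * processed / total
                processed += 1
                w = data[pos]
                state = state * np.uint64(25214903917) + np.uint64(11)
                b = np.int64(state >> np.uint64(33)) % window
                for j in range(pos - window + b, pos + window + 1 - b):
                    if j == pos or j < start or j >= end:
                        continue
                    c = data[j]
                    for k in range(d):
                        neu1e[k] = 0.0
                    for t in range(path_offs[w], path_offs[w + 1]):
                        node = point_flat[t]
                        f = np.float32(0.0)
                        for k in range(d):
                            f += syn0[c, k] * syn1[node, k]
                        if f > 6.0:
                            f = np.float32(1.0)
                        elif f < -6.0:
                            f = np.float32(0.0)
                        else:
                            f = np.float32(1.0 / (1.0 + np.exp(-f)))
                        g = np.float32((1 - code_flat[t] - f) * alpha)
                        for k in range(d):
                            neu1e[k] += g * syn1[node, k]
                        for k in range(d):
                            syn1[node, k] += g * syn0[c, k]
                    if trainable[c]:
                        for k in range(d):
                            syn0[c, k] += neu1e[k]


def _encode_corpus(corpus: Sequence[Sequence[str]], vocab: dict[str, int]):
    sents, offs = [], [0]
    for toks in corpus:
        idx = [vocab[t] for t in toks if t in vocab]
        sents.extend(idx)
        offs.append(len(sents))
    return (np.asarray(sents, dtype=np.int64),
            np.asarray(offs, dtype=np.int64))


def _as_token_lists(corpus) -> list[list[str]]:
    out = []
    for item in corpus:
        if isinstance(item, TokenizedReport):
            out.append(list(item.tokens))
        else:
            out.append(list(item))
    return out


def _run_training(corpus, model: WordEmbeddingModel, window: int, epochs: int,
                  seed: int, alpha0: float = 0.025,
                  min_alpha: float = 1e-4,
                  frozen_tokens: Iterable[str] = ()) -> None:
    """Train ``model.vectors`` in place with a fresh hierarchical-softmax tree
    built from the corpus frequencies (restricted to the model vocabulary)."""
    if epochs <= 0:
        return
    counts = Counter()
    for toks in corpus:
        counts.update(t for t in toks if t in model.vocab)
    V = len(model.vocab)
    inv = [""] * V
    for t, i in model.vocab.items():
        inv[i] = t
    # Huffman tree over rows in corpus-frequency order
    rows = sorted(range(V), key=lambda r: (-counts.get(inv[r], 0), r))
    rank_of_row = {r: i for i, r in enumerate(rows)}
    counts_desc = np.array([max(1, counts.get(inv[r], 0)) for r in rows],
                           dtype=np.int64)
    codes, points = _build_huffman(counts_desc)
    codes_by_row = [codes[rank_of_row[r]] for r in range(V)]
    points_by_row = [points[rank_of_row[r]] for r in range(V)]
    code_flat, point_flat, path_offs = _flatten_paths(codes_by_row, points_by_row)
    data, sent_offs = _encode_corpus(corpus, model.vocab)
    if data.size == 0:
        return
    syn1 = np.zeros((max(1, len(model.vocab) - 1), model.dim), dtype=np.float32)
    trainable = np.ones(V, dtype=np.bool_)
    for t in frozen_tokens:
        if t in model.vocab:
            trainable[model.vocab[t]] = False
    _sg_hs_train(data, sent_offs, model.vectors, syn1, code_flat, point_flat,
                 path_offs, np.int64(window), np.int64(epochs),
                 np.float32(alpha0), np.float32(min_alpha), np.int64(seed),
                 trainable)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def train_skipgram(corpus, dim: int = 100, window: int = 5, epochs: int = 10,
                   min_count: int = 2, seed: int = 0,
                   domain: str = "", model_id: str | None = None,
                   ) -> WordEmbeddingModel:
    """Train a base skipgram / hierarchical-softmax model on one corpus.

    ``corpus`` is a sequence of token lists or :class:`TokenizedReport`.
    Deterministic for fixed seed (single-worker sequential updates).
    """
    toks = _as_token_lists(corpus)
    counts = Counter(t for sent in toks for t in sent)
    kept = {t: c for t, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError("empty effective vocabulary after min_count filter")
    ordered = sorted(kept, key=lambda t: (-kept[t], t))
    vocab = {t: i for i, t in enumerate(ordered)}
    rng = np.random.default_rng(seed)
    vectors = ((rng.random((len(vocab), dim), dtype=np.float32) - 0.5) / dim)
    model = WordEmbeddingModel(
        model_id=model_id or f"w2v:{domain or 'corpus'}:base",
        vocab=vocab, vectors=vectors, dim=dim,
        provenance={"domain": domain, "finetuned_from": None},
        training_meta={"window": window, "epochs": epochs, "seed": seed,
                       "min_count": min_count,
                       "algorithm": "skipgram+hierarchical-softmax"},
        counts=dict(kept),
    )
    _run_training(toks, model, window, epochs, seed)
    return model


def transfer_initialize(source: WordEmbeddingModel,
                        target_vocab: Mapping[str, int] | Iterable[str],
                        dim: int, seed: int = 0, domain: str = "",
                        model_id: str | None = None) -> WordEmbeddingModel:
    """Initialise a target-domain model from a source-domain model.

    Every token shared with the source keeps the source vector bitwise;
    target-only tokens get seeded uniform(-0.5/d, 0.5/d) rows.  ``target_vocab``
    may carry counts (used to order rows by frequency) or be a plain set.
    """
    if source.dim != dim:
        raise ValueError(f"dimension mismatch: source {source.dim} != {dim}")
    if isinstance(target_vocab, Mapping):
        counts = dict(target_vocab)
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
    else:
        ordered = sorted(set(target_vocab))
        counts = {t: 1 for t in ordered}
    vocab = {t: i for i, t in enumerate(ordered)}
    shared = [t for t in ordered if t in source.vocab]
    if not shared:
        warnings.warn("no vocabulary overlap with source model; "
                      "all rows randomly initialised")
    rng = np.random.default_rng(seed)
    vectors = ((rng.random((len(vocab), dim), dtype=np.float32) - 0.5) / dim)
    for t in shared:
        vectors[vocab[t]] = source.vectors[source.vocab[t]]
    return WordEmbeddingModel(
        model_id=model_id or f"w2v:{domain or 'target'}:xfer",
        vocab=vocab, vectors=vectors, dim=dim,
        provenance={"domain": domain, "finetuned_from": source.model_id},
        training_meta={"seed": seed,
                       "algorithm": "skipgram+hierarchical-softmax",
                       "copied_tokens": shared},
        counts=counts,
    )


def finetune(model: WordEmbeddingModel, target_corpus, epochs: int = 5,
             window: int = 5, seed: int = 0,
             freeze_copied: bool = False) -> WordEmbeddingModel:
    """Continue skipgram training from an initialised vector table.

    By default all rows remain trainable; ``freeze_copied=True`` pins the
    transferred (source-copied) rows for ablation, training only the
    target-only vocabulary.  The model's vocabulary must cover the target
    corpus.  ``epochs=0`` is the identity.
    """
    toks = _as_token_lists(target_corpus)
    for sent in toks:
        for t in sent:
            if t not in model.vocab:
                raise ValueError(
                    f"token {t!r} in target corpus is absent from the "
                    "model vocabulary (build it with transfer_initialize)")
    out = WordEmbeddingModel(
        model_id=model.model_id,
        vocab=dict(model.vocab), vectors=model.vectors.copy(), dim=model.dim,
        provenance=dict(model.provenance),
        training_meta={**model.training_meta, "finetune_epochs": epochs,
                       "finetune_seed": seed, "window": window,
                       "freeze_copied": freeze_copied},
        counts=dict(model.counts),
    )
    frozen = (model.training_meta.get("copied_tokens", ())
              if freeze_copied else ())
    _run_training(toks, out, window, epochs, seed, frozen_tokens=frozen)
    return out


def embed_report(model: WordEmbeddingModel,
                 report: TokenizedReport | Sequence[str]) -> ReportVector:
    """Arithmetic mean of in-vocabulary token vectors of one report.

    Out-of-vocabulary tokens are skipped; a report with no in-vocabulary
    tokens is an error rather than a silent zero vector.
    """
    if isinstance(report, TokenizedReport):
        tokens, rid, label = report.tokens, report.report_id, report.label
    else:
        tokens, rid, label = tuple(report), "", None
    rows = [model.vocab[t] for t in tokens if t in model.vocab]
    if not rows:
        raise ValueError(f"report {rid!r}: no in-vocabulary tokens")
    values = model.vectors[rows].astype(np.float64).mean(axis=0)
    return ReportVector(report_id=rid, values=values,
                        n_tokens_used=len(rows), label=label)


# ---------------------------------------------------------------------------
# Serialisation: word2vec text format + provenance sidecar
# ---------------------------------------------------------------------------

def save_embeddings(model: WordEmbeddingModel, path: str | Path) -> None:
    path = Path(path)
    inv = sorted(model.vocab.items(), key=lambda kv: kv[1])
    with open(path, "w") as fh:
        fh.write(f"{len(model.vocab)} {model.dim}\n")
        for tok, row in inv:
            vals = " ".join(f"{v:.8e}" for v in model.vectors[row])
            fh.write(f"{tok} {vals}\n")
    meta = {"model_id": model.model_id, "dim": model.dim,
            "provenance": model.provenance,
            "training_meta": model.training_meta,
            "counts": model.counts}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_embeddings(path: str | Path) -> WordEmbeddingModel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path.name}: malformed header line")
        V, d = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((V, d), dtype=np.float32)
        for i in range(V):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path.name}: expected {V} rows, got {i}")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path.name}: row {i + 1} has {len(parts) - 1} values, "
                    f"expected {d}")
            vocab[parts[0]] = i
            vectors[i] = np.array(parts[1:], dtype=np.float32)
        if fh.readline().strip():
            raise ValueError(f"{path.name}: more rows than header declares")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return WordEmbeddingModel(
        model_id=meta.get("model_id", path.stem),
        vocab=vocab, vectors=vectors, dim=d,
        provenance=meta.get("provenance", {}),
        training_meta=meta.get("training_meta", {}),
        counts=meta.get("counts", {}),
    )
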