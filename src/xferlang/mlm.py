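"""Context-dependent language modelling: a small masked LM per domain.

A byte-pair-encoded subword vocabulary is learned from each cleaned corpus,
and a compact transformer encoder is trained to predict masked subword units
from bidirectional context.  Cross-domain transfer reuses the source model's
subword vocabulary and *all* of its weights as the initialisation, appending
seeded random embedding rows only for subword units the target corpus needs
that the source never saw; the model is then fine-tuned on the target
corpus.  (Word-level vector copying is ill-defined over subword
vocabularies, so full-weight reuse with vocabulary extension is the
transfer interpretation implemented here.)
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._transformer import (AdamState, TransformerConfig, forward, init_params,
                           loss_and_grads)
from .preprocess import TokenizedReport
from .w2v import ReportVector

__all__ = [
    "SubwordTokenizer",
    "MaskedLMModel",
    "build_tokenizer",
    "train_mlm",
    "finetune_mlm",
    "transfer_initialize_mlm",
    "embed_report_mlm",
]

PAD, MASK, UNK = "[PAD]", "[MASK]", "[UNK]"
_SPECIALS = (PAD, MASK, UNK)
_EOW = "</w>"


# ---------------------------------------------------------------------------
# Byte-pair subword tokenizer
# ---------------------------------------------------------------------------

@dataclass
class SubwordTokenizer:
    vocab: dict[str, int]                 # unit -> id (specials first)
    merges: tuple[tuple[str, str], ...]   # in priority order
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def mask_id(self) -> int:
        return self.vocab[MASK]

    def units_of_word(self, word: str) -> list[str]:
        """Greedy merge application: highest-priority applicable merge first."""
        if word in self._cache:
            return self._cache[word]
        symbols = list(word) + [_EOW]
        rank = {m: i for i, m in enumerate(self.merges)}
        while len(symbols) > 1:
            best, best_rank = None, None
            for i in range(len(symbols) - 1):
                r = rank.get((symbols[i], symbols[i + 1]))
                if r is not None and (best_rank is None or r < best_rank):
                    best, best_rank = i, r
            if best is None:
                break
            merged = symbols[best] + symbols[best + 1]
            # merge every occurrence of this pair, left to right
            pair = (symbols[best], symbols[best + 1])
            out, i = [], 0
            while i < len(symbols):
                if (i < len(symbols) - 1
                        and (symbols[i], symbols[i + 1]) == pair):
                    out.append(merged)
                    i += 2
                else:
                    out.append(symbols[i])
                    i += 1
            symbols = out
        self._cache[word] = symbols
        return symbols

    def encode(self, words: Sequence[str]) -> list[int]:
        ids = []
        unk = self.vocab[UNK]
        for w in words:
            ids.extend(self.vocab.get(u, unk) for u in self.units_of_word(w))
        return ids

    def decode(self, ids: Sequence[int]) -> list[str]:
        inv = {i: u for u, i in self.vocab.items()}
        text = "".join(inv[i] for i in ids if inv[i] not in _SPECIALS)
        return [w for w in text.split(_EOW) if w]


def build_tokenizer(corpus, vocab_size: int = 2000) -> SubwordTokenizer:
    """Learn a deterministic BPE vocabulary from a cleaned corpus.

    ``vocab_size`` caps the unit count (specials + characters + merges); ties
    between equally frequent pairs break lexicographically.  Every token of
    the build corpus is encodable, and ``decode(encode(x)) == x``.
    """
    word_freq = Counter()
    for item in corpus:
        toks = item.tokens if isinstance(item, TokenizedReport) else item
        word_freq.update(toks)
    if not word_freq:
        raise ValueError("cannot build a tokenizer from an empty corpus")
    base = sorted({ch for w in word_freq for ch in w}) + [_EOW]
    n_floor = len(_SPECIALS) + len(base)
    if vocab_size < n_floor:
        raise ValueError(
            f"vocab_size {vocab_size} < {n_floor} base units")

    words = {w: list(w) + [_EOW] for w in word_freq}
    merges: list[tuple[str, str]] = []
    units = list(_SPECIALS) + base
    while len(units) < vocab_size:
        pairs = Counter()
        for w, syms in words.items():
            f = word_freq[w]
            for i in range(len(syms) - 1):
                pairs[(syms[i], syms[i + 1])] += f
        if not pairs:
            break
        best = min(pairs, key=lambda pr: (-pairs[pr], pr))
        merges.append(best)
        merged = best[0] + best[1]
        units.append(merged)
        for w, syms in words.items():
            out, i = [], 0
            while i < len(syms):
                if i < len(syms) - 1 and (syms[i], syms[i + 1]) == best:
                    out.append(merged)
                    i += 2
                else:
                    out.append(syms[i])
                    i += 1
            words[w] = out
    vocab = {u: i for i, u in enumerate(units)}
    return SubwordTokenizer(vocab=vocab, merges=tuple(merges))


# ---------------------------------------------------------------------------
# Masked LM model
# ---------------------------------------------------------------------------

@dataclass
class MaskedLMModel:
    model_id: str
    tokenizer: SubwordTokenizer
    config: TransformerConfig
    params: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def encode_clipped(self, tokens: Sequence[str]) -> list[int]:
        return self.tokenizer.encode(tokens)[: self.config.max_seq_len]


def _encode_corpus(corpus, tokenizer: SubwordTokenizer,
                   max_seq_len: int) -> list[list[int]]:
    out = []
    for item in corpus:
        toks = item.tokens if isinstance(item, TokenizedReport) else item
        ids = tokenizer.encode(toks)[:max_seq_len]
        if ids:
            out.append(ids)
    return out


def _make_batch(seqs: list[list[int]], pad_id: int):
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = True
    return ids, mask


def _mask_batch(ids: np.ndarray, pad_mask: np.ndarray, mask_prob: float,
                mask_id: int, n_vocab: int, rng: np.random.Generator):
    """80/10/10 mask/random/keep policy; at least one target per sequence."""
    masked = ids.copy()
    pos, tgt = [], []
    for b in range(ids.shape[0]):
        real = np.flatnonzero(pad_mask[b])
        k = max(1, int(round(mask_prob * len(real))))
        chosen = rng.choice(real, size=min(k, len(real)), replace=False)
        for j in np.sort(chosen):
            pos.append((b, j))
            tgt.append(ids[b, j])
            u = rng.random()
            if u < 0.8:
                masked[b, j] = mask_id
            elif u < 0.9:
                masked[b, j] = int(rng.integers(len(_SPECIALS), n_vocab))
            # else: keep
    return masked, np.array(pos, dtype=np.int64), np.array(tgt, dtype=np.int64)


def _heldout_loss(model: MaskedLMModel, heldout: list[list[int]],
                  mask_prob: float, mask_seed: int) -> float:
    """Masked-prediction loss on held-out sequences with masks drawn from a
    fixed seed, so two evaluations of the same data are comparable."""
    rng = np.random.default_rng(mask_seed)
    tok = model.tokenizer
    total, n = 0.0, 0
    for i in range(0, len(heldout), 16):
        chunk = heldout[i:i + 16]
        ids, pad = _make_batch(chunk, tok.pad_id)
        masked, pos, tgt = _mask_batch(ids, pad, mask_prob, tok.mask_id,
                                       model.config.vocab_size, rng)
        loss, _ = loss_and_grads(model.params, model.config, masked, pad,
                                 pos, tgt)
        total += loss * len(tgt)
        n += len(tgt)
    return total / max(1, n)


def _train_loop(model: MaskedLMModel, train_seqs: list[list[int]],
                epochs: int, mask_prob: float, batch_size: int,
                lr: float, seed: int) -> list[float]:
    if epochs <= 0:
        return []
    rng = np.random.default_rng(seed)
    adam = AdamState(model.params, lr=lr)
    tok = model.tokenizer
    epoch_losses = []
    for _ in range(epochs):
        order = rng.permutation(len(train_seqs))
        total, n = 0.0, 0
        for i in range(0, len(order), batch_size):
            chunk = [train_seqs[j] for j in order[i:i + batch_size]]
            ids, pad = _make_batch(chunk, tok.pad_id)
            masked, pos, tgt = _mask_batch(ids, pad, mask_prob, tok.mask_id,
                                           model.config.vocab_size, rng)
            loss, grads = loss_and_grads(model.params, model.config, masked,
                                         pad, pos, tgt)
            adam.step(model.params, grads)
            total += loss * len(tgt)
            n += len(tgt)
        epoch_losses.append(total / max(1, n))
    return epoch_losses


def train_mlm(tokenized_corpus, config: TransformerConfig | None = None,
              mask_prob: float = 0.15, epochs: int = 15, seed: int = 0,
              vocab_size: int = 2000, batch_size: int = 16, lr: float = 1e-3,
              holdout_fraction: float = 0.1, domain: str = "",
              model_id: str | None = None) -> MaskedLMModel:
    """Train a masked LM from scratch on one domain's cleaned corpus.

    A deterministic held-out slice tracks masked-prediction loss before and
    after training (``meta["holdout_loss_initial"/"holdout_loss_final"]``).
    Sequences longer than ``max_seq_len`` are clipped.
    """
    corpus = list(tokenized_corpus)
    if not corpus:
        raise ValueError("empty corpus")
    tokenizer = build_tokenizer(corpus, vocab_size)
    cfg = config or TransformerConfig(vocab_size=len(tokenizer.vocab))
    if cfg.vocab_size != len(tokenizer.vocab):
        cfg = TransformerConfig(
            vocab_size=len(tokenizer.vocab), layers=cfg.layers,
            hidden=cfg.hidden, heads=cfg.heads, d_ff=cfg.d_ff,
            max_seq_len=cfg.max_seq_len)
    seqs = _encode_corpus(corpus, tokenizer, cfg.max_seq_len)
    if not seqs:
        raise ValueError("corpus empty after encoding")
    step = max(2, int(round(1.0 / max(holdout_fraction, 1e-9))))
    heldout = seqs[::step] if len(seqs) >= step else seqs[:1]
    train_seqs = [s for i, s in enumerate(seqs) if i % step != 0] or seqs

    model = MaskedLMModel(
        model_id=model_id or f"mlm:{domain or 'corpus'}:base",
        tokenizer=tokenizer, config=cfg,
        params=init_params(cfg, seed),
        provenance={"domain": domain, "finetuned_from": None},
        meta={"mask_prob": mask_prob, "epochs": epochs, "seed": seed},
    )
    model.meta["holdout_loss_initial"] = _heldout_loss(
        model, heldout, mask_prob, mask_seed=seed + 1)
    model.meta["train_losses"] = _train_loop(
        model, train_seqs, epochs, mask_prob, batch_size, lr, seed)
    model.meta["holdout_loss_final"] = _heldout_loss(
        model, heldout, mask_prob, mask_seed=seed + 1)
    return model


def transfer_initialize_mlm(source: MaskedLMModel, target_corpus,
                            seed: int = 0, domain: str = "",
                            model_id: str | None = None) -> MaskedLMModel:
    """Initialise a target-domain masked LM from a source-domain one.

    The source subword vocabulary and all transformer weights are reused
    verbatim; subword units required by the target corpus but unknown to the
    source (novel characters) are appended with seeded random embedding rows
    and output-head columns.
    """
    tok = source.tokenizer
    required: set[str] = set()
    for item in target_corpus:
        toks = item.tokens if isinstance(item, TokenizedReport) else item
        for w in toks:
            required.update(tok.units_of_word(w))
            required.update(ch for ch in w if ch not in tok.vocab)
    new_units = sorted(u for u in required if u not in tok.vocab)

    vocab = dict(tok.vocab)
    for u in new_units:
        vocab[u] = len(vocab)
    new_tok = SubwordTokenizer(vocab=vocab, merges=tok.merges)

    params = {k: v.copy() for k, v in source.params.items()}
    n_new = len(new_units)
    if n_new:
        rng = np.random.default_rng(seed)
        H = source.config.hidden
        params["E_tok"] = np.vstack(
            [params["E_tok"], rng.normal(0, 0.02, (n_new, H))])
        params["W_out"] = np.hstack(
            [params["W_out"], rng.normal(0, 0.02, (H, n_new))])
        params["b_out"] = np.concatenate([params["b_out"], np.zeros(n_new)])
    cfg = TransformerConfig(
        vocab_size=len(vocab), layers=source.config.layers,
        hidden=source.config.hidden, heads=source.config.heads,
        d_ff=source.config.d_ff, max_seq_len=source.config.max_seq_len)
    return MaskedLMModel(
        model_id=model_id or f"mlm:{domain or 'target'}:xfer",
        tokenizer=new_tok, config=cfg, params=params,
        provenance={"domain": domain, "finetuned_from": source.model_id},
        meta={"appended_units": new_units, "seed": seed},
    )


def finetune_mlm(model: MaskedLMModel, target_corpus, epochs: int = 10,
                 mask_prob: float = 0.15, batch_size: int = 16,
                 lr: float = 1e-3, seed: int = 0) -> MaskedLMModel:
    """Continue masked-LM training on the target corpus (all weights
    trainable); ``epochs=0`` returns an identical copy."""
    out = MaskedLMModel(
        model_id=model.model_id, tokenizer=model.tokenizer,
        config=model.config,
        params={k: v.copy() for k, v in model.params.items()},
        provenance=dict(model.provenance),
        meta={**model.meta, "finetune_epochs": epochs, "finetune_seed": seed},
    )
    seqs = _encode_corpus(target_corpus, model.tokenizer,
                          model.config.max_seq_len)
    out.meta["finetune_losses"] = _train_loop(
        out, seqs, epochs, mask_prob, batch_size, lr, seed)
    return out


def save_mlm(model: MaskedLMModel, path) -> None:
    """Model directory: vocab.txt (one unit per line, id order), merges.txt,
    config.json and weights.npz."""
    import json
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    inv = sorted(model.tokenizer.vocab, key=model.tokenizer.vocab.get)
    (path / "vocab.txt").write_text("\n".join(inv) + "\n")
    (path / "merges.txt").write_text(
        "\n".join(f"{a}\t{b}" for a, b in model.tokenizer.merges) + "\n")
    cfg = model.config
    (path / "config.json").write_text(json.dumps({
        "model_id": model.model_id,
        "config": {"vocab_size": cfg.vocab_size, "layers": cfg.layers,
                   "hidden": cfg.hidden, "heads": cfg.heads,
                   "d_ff": cfg.d_ff, "max_seq_len": cfg.max_seq_len},
        "provenance": model.provenance,
        "meta": {k: v for k, v in model.meta.items()
                 if isinstance(v, (int, float, str, list))},
    }, indent=1, default=float))
    np.savez(path / "weights.npz", **model.params)


def load_mlm(path) -> MaskedLMModel:
    import json
    from pathlib import Path
    path = Path(path)
    obj = json.loads((path / "config.json").read_text())
    units = (path / "vocab.txt").read_text().splitlines()
    merges = tuple(tuple(line.split("\t"))
                   for line in (path / "merges.txt").read_text().splitlines()
                   if line)
    tok = SubwordTokenizer(vocab={u: i for i, u in enumerate(units)},
                           merges=merges)
    cfg = TransformerConfig(**obj["config"])
    with np.load(path / "weights.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    return MaskedLMModel(model_id=obj["model_id"], tokenizer=tok, config=cfg,
                         params=params, provenance=obj.get("provenance", {}),
                         meta=obj.get("meta", {}))


def embed_report_mlm(model: MaskedLMModel,
                     report: TokenizedReport | Sequence[str]) -> ReportVector:
    """Mean of final-layer token representations over the clipped sequence."""
    if isinstance(report, TokenizedReport):
        tokens, rid, label = report.tokens, report.report_id, report.label
    else:
        tokens, rid, label = tuple(report), "", None
    ids = model.encode_clipped(tokens)
    if not ids:
        raise ValueError(f"report {rid!r}: empty subword sequence")
    arr = np.asarray([ids], dtype=np.int64)
    pad = np.ones_like(arr, dtype=bool)
    _, hidden, _ = forward(model.params, model.config, arr, pad)
    return ReportVector(report_id=rid, values=hidden[0].mean(axis=0),
                        n_tokens_used=len(ids), label=label)
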