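"""Skipgram training, transfer initialisation and report embedding contracts."""

import itertools
from collections import Counter

import numpy as np
import pytest

from xferlang.reports import BENIGN_TOKENS, MALIGNANT_TOKENS
from xferlang.w2v import (WordEmbeddingModel, embed_report, finetune,
                          load_embeddings, save_embeddings, train_skipgram,
                          transfer_initialize)


def _cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestTrainSkipgram:
    def test_vocabulary_equals_min_count_filter(self, tokenized_by_domain):
        corpus = tokenized_by_domain["us"]
        counts = Counter(t for r in corpus for t in r.tokens)
        model = train_skipgram(corpus, dim=20, epochs=1, min_count=3, seed=0)
        assert set(model.vocab) == {t for t, c in counts.items() if c >= 3}

    def test_fixed_seed_reproduces_vectors(self, tokenized_by_domain):
        corpus = tokenized_by_domain["us"][:100]
        a = train_skipgram(corpus, dim=30, epochs=3, seed=5)
        b = train_skipgram(corpus, dim=30, epochs=3, seed=5)
        assert np.array_equal(a.vectors, b.vectors)

    def test_empty_vocabulary_is_error(self):
        with pytest.raises(ValueError):
            train_skipgram([["a"], ["b"]], min_count=5)

    def test_synonym_groups_cluster_in_most_seeds(self, tokenized_by_domain):
        """Tokens planted from the same class-signal group should sit closer
        together than random token pairs (semantic clustering)."""
        corpus = tokenized_by_domain["us"]
        wins = 0
        for seed in range(5):
            m = train_skipgram(corpus, dim=50, epochs=5, seed=seed)
            group = [t for t in MALIGNANT_TOKENS if t in m.vocab]
            within = np.mean([_cos(m[a], m[b])
                              for a, b in itertools.combinations(group, 2)])
            toks = list(m.vocab)
            rng = np.random.default_rng(seed)
            ii = rng.integers(0, len(toks), 1000)
            jj = rng.integers(0, len(toks), 1000)
            rand = np.mean([_cos(m[toks[i]], m[toks[j]])
                            for i, j in zip(ii, jj) if i != j])
            wins += within > rand
        assert wins >= 4


class TestTransferInitialize:
    def test_shared_vectors_copied_bitwise(self, us_model, tokenized_by_domain):
        counts = Counter(t for r in tokenized_by_domain["mr"] for t in r.tokens)
        xfer = transfer_initialize(us_model, counts, dim=us_model.dim,
                                   seed=3, domain="mr")
        shared = [t for t in xfer.vocab if t in us_model.vocab]
        assert shared
        for t in shared:
            assert np.array_equal(xfer[t], us_model[t])
        assert xfer.provenance["finetuned_from"] == us_model.model_id

    def test_copied_fraction_matches_set_arithmetic(self, us_model,
                                                    tokenized_by_domain):
        counts = Counter(t for r in tokenized_by_domain["mr"] for t in r.tokens)
        xfer = transfer_initialize(us_model, counts, dim=us_model.dim, seed=3)
        n_copied = sum(np.array_equal(xfer[t], us_model[t])
                       for t in xfer.vocab if t in us_model.vocab)
        expected = len(set(counts) & set(us_model.vocab))
        assert n_copied == expected

    def test_disjoint_vocabulary_warns_and_randomises(self, us_model):
        with pytest.warns(UserWarning):
            xfer = transfer_initialize(us_model, {"zzz1": 5, "zzz2": 3},
                                       dim=us_model.dim, seed=3)
        for t in xfer.vocab:
            assert not any(np.array_equal(xfer[t], us_model.vectors[i])
                           for i in range(len(us_model.vocab)))

    def test_dimension_mismatch_is_error(self, us_model):
        with pytest.raises(ValueError):
            transfer_initialize(us_model, {"a": 1}, dim=us_model.dim + 1)


class TestFinetune:
    def test_zero_epochs_is_identity(self, us_model, tokenized_by_domain):
        counts = Counter(t for r in tokenized_by_domain["mr"] for t in r.tokens)
        xfer = transfer_initialize(us_model, counts, dim=us_model.dim, seed=1)
        out = finetune(xfer, tokenized_by_domain["mr"], epochs=0)
        assert np.array_equal(out.vectors, xfer.vectors)

    def test_training_moves_frequent_vectors_and_stays_finite(
            self, us_model, tokenized_by_domain):
        mr = tokenized_by_domain["mr"]
        counts = Counter(t for r in mr for t in r.tokens)
        xfer = transfer_initialize(us_model, counts, dim=us_model.dim, seed=1)
        out = finetune(xfer, mr, epochs=2, seed=1)
        frequent = [t for t, c in counts.items() if c >= 20]
        assert frequent
        for t in frequent:
            assert np.linalg.norm(out[t] - xfer[t]) > 0
        assert np.all(np.isfinite(out.vectors))
        assert out.provenance == xfer.provenance

    def test_freeze_copied_pins_transferred_rows_only(self, us_model,
                                                      tokenized_by_domain):
        mr = tokenized_by_domain["mr"]
        counts = Counter(t for r in mr for t in r.tokens)
        xfer = transfer_initialize(us_model, counts, dim=us_model.dim, seed=2)
        out = finetune(xfer, mr, epochs=2, seed=2, freeze_copied=True)
        copied = set(xfer.training_meta["copied_tokens"])
        for t in copied:
            assert np.array_equal(out[t], xfer[t])
        new_frequent = [t for t, c in counts.items()
                        if c >= 20 and t not in copied]
        assert new_frequent
        assert any(np.linalg.norm(out[t] - xfer[t]) > 0 for t in new_frequent)

    def test_out_of_vocabulary_corpus_token_is_named(self, us_model):
        with pytest.raises(ValueError, match="zzz"):
            finetune(us_model, [["zzz"]], epochs=1)

    def test_target_only_synonyms_gain_clustering(self):
        """After fine-tuning, the target domain's private surface synonyms
        (absent from the source) cluster like base-model synonyms do."""
        from xferlang.experiments import prepare_corpora
        from xferlang.reports import SyntheticConfig, generate_corpus
        reports, _ = generate_corpus(
            SyntheticConfig(n_reports={"us": 800, "mr": 400}, seed=42))
        corpora = prepare_corpora(reports)
        us, mr = corpora["us"], corpora["mr"]
        wins = 0
        for seed in range(3):
            src = train_skipgram(us, dim=50, epochs=5, seed=seed)
            counts = Counter(t for r in mr for t in r.tokens)
            ft = finetune(transfer_initialize(src, counts, dim=50, seed=seed),
                          mr, epochs=8, seed=seed)
            new = [t for t in ft.vocab if t not in src.vocab]
            group = [f"{t}_mr" for t in MALIGNANT_TOKENS if f"{t}_mr" in new]
            assert len(group) >= 3
            within = np.mean([_cos(ft[a], ft[b])
                              for a, b in itertools.combinations(group, 2)])
            toks = list(ft.vocab)
            rng = np.random.default_rng(seed)
            rand = np.mean([_cos(ft[toks[i]], ft[toks[j]])
                            for i, j in zip(rng.integers(0, len(toks), 500),
                                            rng.integers(0, len(toks), 500))
                            if i != j])
            wins += within > rand
        assert wins >= 2


class TestEmbedReport:
    def test_single_token_report_equals_row(self, us_model):
        rv = embed_report(us_model, ["liver", "liver", "liver"])
        assert np.allclose(rv.values, us_model["liver"], atol=1e-7)
        assert rv.n_tokens_used == 3

    def test_matches_brute_force_mean(self, us_model, tokenized_by_domain):
        rng = np.random.default_rng(0)
        corpus = tokenized_by_domain["us"]
        picks = rng.choice(len(corpus), size=100, replace=False)
        for i in picks:
            r = corpus[int(i)]
            rows = [us_model[t].astype(np.float64) for t in r.tokens
                    if t in us_model]
            if not rows:
                continue
            rv = embed_report(us_model, r)
            assert np.max(np.abs(rv.values - np.mean(rows, axis=0))) <= 1e-9

    def test_all_oov_is_error(self, us_model):
        with pytest.raises(ValueError):
            embed_report(us_model, ["zzz", "qqq"])


class TestSerialization:
    def test_round_trip(self, us_model, tmp_path):
        fp = tmp_path / "m.txt"
        save_embeddings(us_model, fp)
        back = load_embeddings(fp)
        assert back.vocab == us_model.vocab
        assert np.max(np.abs(back.vectors - us_model.vectors)) <= 1e-6
        assert back.provenance == us_model.provenance
        assert back.model_id == us_model.model_id

    def test_wrong_dimension_is_error(self, us_model, tmp_path):
        fp = tmp_path / "m.txt"
        save_embeddings(us_model, fp)
        lines = fp.read_text().splitlines()
        lines[0] = f"{len(us_model.vocab)} {us_model.dim + 1}"
        fp.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            load_embeddings(fp)

    def test_row_count_mismatch_is_error(self, us_model, tmp_path):
        fp = tmp_path / "m.txt"
        save_embeddings(us_model, fp)
        lines = fp.read_text().splitlines()
        fp.write_text("\n".join(lines[:-5]) + "\n")
        with pytest.raises(ValueError):
            load_embeddings(fp)
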