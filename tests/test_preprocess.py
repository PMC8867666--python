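"""Segmentation exactness against ground truth and cleaning-rule oracles."""

import re
from collections import Counter

import pytest

from xferlang.preprocess import (AnatomyLexicon, CleaningConfig,
                                 SegmentedReport, clean_corpus,
                                 common_vocabulary, corpus_statistics,
                                 default_lexicon, segment_corpus,
                                 segment_liver, split_sentences)
from xferlang.reports import ReportDocument, SyntheticConfig, generate_corpus


class TestSplitSentences:
    @pytest.mark.parametrize("text,expected", [
        ("A b. C d.", ["A b.", "C d."]),
        ("", []),
        ("   ", []),
        ("one sentence without period", ["one sentence without period"]),
        ("first.\nsecond line.", ["first.", "second line."]),
    ])
    def test_examples(self, text, expected):
        assert split_sentences(text) == expected

    def test_concatenation_preserves_content(self, small_corpus):
        reports, _ = small_corpus
        for r in reports[:50]:
            sents = split_sentences(r.findings_text())
            assert " ".join(sents).split() == r.findings_text().split()


class TestSegmentation:
    def test_exact_on_generated_reports_per_style(self, small_corpus):
        """Sentence-level precision and recall are 1.0 against the
        generator's ground truth, for both report styles (>=200 each)."""
        reports, truths = small_corpus
        truth_by_id = {t.report_id: t for t in truths}
        lex = default_lexicon()
        n_by_style = Counter()
        for r in reports:
            _, idx = segment_liver(r, lex)
            assert set(idx) == set(truth_by_id[r.id].liver_sentence_indices), r.id
            n_by_style[r.style] += 1
        assert n_by_style["templated"] >= 100
        assert n_by_style["freetext"] >= 200

    def test_dependent_term_resolves_to_most_recent_anchor(self):
        lex = default_lexicon()
        r = ReportDocument(
            id="x", domain="us", style="freetext",
            sections={"FINDINGS": (
                "the liver is coarse. a lesion is again seen. "
                "the kidney is normal. a nodule is noted there.")})
        text, idx = segment_liver(r, lex)
        # lesion follows the liver anchor -> liver; nodule follows kidney -> not
        assert idx == (0, 1)
        assert "lesion" in text and "nodule" not in text

    def test_no_liver_content_is_empty_not_error(self):
        r = ReportDocument(id="x", domain="us", style="freetext",
                           sections={"FINDINGS": "the kidney is normal."})
        assert segment_liver(r, default_lexicon()) == ("", ())

    def test_impression_is_never_consulted(self):
        r = ReportDocument(
            id="x", domain="mr", style="freetext",
            sections={"FINDINGS": "the kidney is normal.",
                      "IMPRESSION": "hepatic malignancy suspected."})
        text, idx = segment_liver(r, default_lexicon())
        assert text == "" and idx == ()

    def test_templated_liver_block_returned_whole(self):
        r = ReportDocument(
            id="x", domain="mr", style="templated",
            sections={"FINDINGS": "Liver: the liver is fine. nothing else. "
                                  "Kidneys: the kidney is normal."})
        text, idx = segment_liver(r, default_lexicon())
        assert idx == (0, 1)   # label-anchored block, including anchor-free sentence

    def test_lexicon_validation(self):
        with pytest.raises(ValueError):
            AnatomyLexicon(liver_terms=frozenset())
        with pytest.raises(ValueError):
            AnatomyLexicon(liver_terms=frozenset({"Liver"}))


def _brute_force_clean(texts_by_id, config):
    """Independent cleaning oracle: plain regex + dict counting."""
    date_re = re.compile(
        r"\b\d{1,2}/\d{1,2}/\d{2,4}\b|\b\d{4}-\d{2}-\d{2}\b"
        r"|\b\d{1,2}:\d{2}(?::\d{2})?(?:\s?[ap]m)?\b")
    word_re = re.compile(r"<[a-z]+>|[a-z0-9_']+")
    staged = {}
    for rid, text in texts_by_id.items():
        t = date_re.sub(f" {config.date_token} ", text.lower())
        for phrase in config.blacklist_phrases:
            t = t.replace(phrase.lower(), " ")
        staged[rid] = [w for w in word_re.findall(t)
                       if w not in config.stopwords]
    freq = Counter(w for toks in staged.values() for w in toks)
    return {rid: [w for w in toks if freq[w] >= config.min_frequency]
            for rid, toks in staged.items()}


class TestCleaning:
    def test_stated_rules_on_one_sentence(self):
        seg = [SegmentedReport("r1", "us", "freetext",
                               "The liver is NORMAL on 01/02/2015",
                               (0,))]
        cfg = CleaningConfig(stopwords=frozenset({"the", "is", "on"}),
                             min_frequency=0)
        out = clean_corpus(seg, cfg)
        assert list(out[0].tokens) == ["liver", "normal", "<datetoken>"]

    def test_low_frequency_tokens_dropped_everywhere(self):
        seg = [SegmentedReport(f"r{i}", "us", "freetext", text, (0,))
               for i, text in enumerate(
                   ["rare liver liver liver liver.",
                    "rare liver liver liver liver.",
                    "rare liver liver liver liver."])]
        out = clean_corpus(seg, CleaningConfig(stopwords=frozenset(),
                                               min_frequency=4))
        for t in out:
            assert "rare" not in t.tokens and "liver" in t.tokens

    def test_matches_brute_force_oracle_on_500_reports(self):
        cfg = SyntheticConfig(n_reports=250, seed=13)
        reports, _ = generate_corpus(cfg)
        seg = segment_corpus(reports)
        clean_cfg = CleaningConfig(min_frequency=3)
        mine = clean_corpus(seg, clean_cfg)
        # oracle applied per domain (the threshold's scope)
        for domain in cfg.domains:
            texts = {s.report_id: s.text for s in seg if s.domain == domain}
            oracle = _brute_force_clean(texts, clean_cfg)
            for t in (x for x in mine if x.domain == domain):
                assert list(t.tokens) == oracle[t.report_id]

    def test_cleaning_is_idempotent(self, tokenized):
        cfg = CleaningConfig(min_frequency=2)
        again = clean_corpus(
            [SegmentedReport(t.report_id, t.domain, t.style,
                             " ".join(t.tokens), (), t.label)
             for t in tokenized], cfg)
        for a, b in zip(tokenized, again):
            assert a.tokens == b.tokens

    def test_output_honours_constraints(self, tokenized):
        cfg = CleaningConfig(min_frequency=2)
        counts = {}
        for t in tokenized:
            counts.setdefault(t.domain, Counter()).update(t.tokens)
        for t in tokenized:
            for tok in t.tokens:
                assert tok == tok.lower()
                assert tok not in cfg.stopwords
                assert counts[t.domain][tok] >= cfg.min_frequency


class TestStatistics:
    def test_common_vocabulary_examples(self):
        assert common_vocabulary({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
        assert common_vocabulary({"a"}, {"b"}) == set()
        assert common_vocabulary({"a", "b"}, {"a", "b"}) == {"a", "b"}

    def test_single_report_common_words(self):
        mk = lambda rid, dom, text: ReportDocument(
            id=rid, domain=dom, style="freetext", sections={"FINDINGS": text})
        df = corpus_statistics([mk("1", "us", "a b c"), mk("2", "mr", "b c d")])
        assert df.loc["Common words in two domains", "us"] == 2

    def test_stats_match_brute_force_recount(self, small_corpus, tokenized):
        import numpy as np
        reports, _ = small_corpus
        df = corpus_statistics(reports, tokenized)
        for dom in ("us", "mr"):
            vocab = set()
            lens = []
            for r in reports:
                if r.domain != dom:
                    continue
                words = re.findall(r"<[a-z]+>|[a-z0-9_']+",
                                   r.findings_text().lower())
                vocab.update(words)
                lens.append(len(words))
            assert df.loc["Number of unique words", dom] == len(vocab)
            reported = df.loc["Average number of words (+/- std)", dom]
            assert reported.startswith(f"{np.mean(lens):.1f}")

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            corpus_statistics([])
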