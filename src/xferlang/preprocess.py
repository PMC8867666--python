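"""Liver-section segmentation and text normalisation.

The pipeline's feature text is not the whole report but the findings that
describe the liver.  Segmentation combines a small anatomical lexicon with a
"most recent anatomical anchor wins" rule for dependent terms (``lesion``,
``nodule``, ...), so that liver lesions described in later sentences are
still attributed to the liver.  The Impression section is never consulted:
in LI-RADS-coded reports it states the assessment outright and would leak
the label.  Cleaning lowercases, replaces date/time stamps with a dedicated
token, removes stop words and blacklisted phrases, and finally drops tokens
below a per-domain corpus frequency threshold.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .reports import ReportDocument
from .stopwords import ENGLISH_STOPWORDS

__all__ = [
    "AnatomyLexicon",
    "CleaningConfig",
    "SegmentedReport",
    "TokenizedReport",
    "split_sentences",
    "segment_liver",
    "segment_corpus",
    "clean_corpus",
    "corpus_statistics",
    "common_vocabulary",
    "default_lexicon",
]


@dataclass(frozen=True)
class AnatomyLexicon:
    """Surface terms that drive dictionary-based sentence retrieval.

    ``other_terms`` (non-liver anatomical anchors) are required by the
    dependency rule: a dependent term is attributed to the liver only when
    the most recent anatomical mention is a liver term, which is undecidable
    without recognising competing anchors.
    """

    liver_terms: frozenset[str]
    dependent_terms: frozenset[str] = frozenset()
    other_terms: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.liver_terms:
            raise ValueError("liver_terms must be non-empty")
        for group in (self.liver_terms, self.dependent_terms, self.other_terms):
            bad = [t for t in group if t != t.lower()]
            if bad:
                raise ValueError(f"lexicon entries must be lowercase: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnatomyLexicon":
        obj = yaml.safe_load(Path(path).read_text())
        return cls(
            liver_terms=frozenset(obj["liver_terms"]),
            dependent_terms=frozenset(obj.get("dependent_terms", [])),
            other_terms=frozenset(obj.get("other_terms", [])),
        )


def default_lexicon() -> AnatomyLexicon:
    """Curated lexicon covering the synthetic generator plus common
    liver-imaging anatomy (a small stand-in for a full anatomical ontology)."""
    return AnatomyLexicon(
        liver_terms=frozenset({
            "liver", "hepatic", "hepatobiliary", "lobe", "segment",
            "parenchyma", "porta",
        }),
        dependent_terms=frozenset({"lesion", "nodule", "focus", "foci"}),
        other_terms=frozenset({
            "kidney", "kidneys", "renal", "spleen", "splenic", "pancreas",
            "pancreatic", "gallbladder", "bowel", "aorta", "bladder",
        }),
    )


@dataclass(frozen=True)
class CleaningConfig:
    stopwords: frozenset[str] = ENGLISH_STOPWORDS
    min_frequency: int = 50
    blacklist_phrases: tuple[str, ...] = (
        "i have personally reviewed the images for this examination",
    )
    date_token: str = "<datetoken>"

    def __post_init__(self):
        if self.min_frequency < 0:
            raise ValueError("min_frequency must be >= 0")
        if not self.date_token:
            raise ValueError("date_token must be non-empty")


@dataclass(frozen=True)
class SegmentedReport:
    """Liver findings text of one report, pre-cleaning."""
    report_id: str
    domain: str
    style: str
    text: str
    sentence_indices: tuple[int, ...]
    label: str | None = None


@dataclass(frozen=True)
class TokenizedReport:
    """Normalised liver-findings token sequence of one report."""
    report_id: str
    domain: str
    style: str
    tokens: tuple[str, ...]
    label: str | None = None

    def to_json(self) -> dict:
        return {"id": self.report_id, "domain": self.domain,
                "style": self.style, "tokens": list(self.tokens),
                "label": self.label}

    @classmethod
    def from_json(cls, obj: dict) -> "TokenizedReport":
        return cls(report_id=obj["id"], domain=obj["domain"],
                   style=obj["style"], tokens=tuple(obj["tokens"]),
                   label=obj.get("label"))


# ---------------------------------------------------------------------------
# Sentence splitting and segmentation
# ---------------------------------------------------------------------------

_SENT_BOUNDARY = re.compile(r"(?<=\.)\s+")


def split_sentences(text: str) -> list[str]:
    """Split on terminal periods; deterministic, whitespace-normalising."""
    if not text or not text.strip():
        return []
    parts = _SENT_BOUNDARY.split(text.strip())
    return [" ".join(p.split()) for p in parts if p.strip()]


_WORD = re.compile(r"<[a-z]+>|[a-z0-9_']+")


def _words(sentence: str) -> list[str]:
    return _WORD.findall(sentence.lower())


_BLOCK_LABEL = re.compile(r"^([A-Z][a-z]+):")


def segment_liver(report: ReportDocument,
                  lexicon: AnatomyLexicon) -> tuple[str, tuple[int, ...]]:
    """Extract the liver-related findings of one report.

    Templated reports: the liver-labelled block is returned whole (from the
    ``Liver:`` label up to the next organ label).  Free-text reports: a
    sentence is liver-related if it contains a liver term, or contains a
    dependent term whose most recent anatomical anchor is a liver term.
    Sentence ordinals index the findings body; the Impression section is
    never consulted.  A report with no liver content yields ``("", ())``.
    """
    sentences = split_sentences(report.findings_text())
    if report.style == "templated":
        keep: list[int] = []
        in_liver = False
        for i, sent in enumerate(sentences):
            m = _BLOCK_LABEL.match(sent)
            if m:
                in_liver = m.group(1).lower() in lexicon.liver_terms
            if in_liver:
                keep.append(i)
    else:
        keep = []
        last_anchor_is_liver = False
        for i, sent in enumerate(sentences):
            words = set(_words(sent))
            if words & lexicon.liver_terms:
                keep.append(i)
                last_anchor_is_liver = True
            elif words & lexicon.other_terms:
                last_anchor_is_liver = False
            elif words & lexicon.dependent_terms and last_anchor_is_liver:
                keep.append(i)
    text = " ".join(sentences[i] for i in keep)
    return text, tuple(keep)


def segment_corpus(reports: Sequence[ReportDocument],
                   lexicon: AnatomyLexicon | None = None) -> list[SegmentedReport]:
    lexicon = lexicon or default_lexicon()
    out = []
    for r in reports:
        text, idx = segment_liver(r, lexicon)
        out.append(SegmentedReport(report_id=r.id, domain=r.domain,
                                   style=r.style, text=text,
                                   sentence_indices=idx, label=r.label))
    return out


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(
    r"\b\d{1,2}/\d{1,2}/\d{2,4}\b"          # 01/02/2015, 1/2/15
    r"|\b\d{4}-\d{2}-\d{2}\b"               # 2015-01-02
    r"|\b\d{1,2}:\d{2}(?::\d{2})?(?:\s?[ap]m)?\b"  # 13:45, 9:05:12, 9:05 am
)


def _normalise(text: str, config: CleaningConfig) -> list[str]:
    text = text.lower()
    text = _DATE_RE.sub(f" {config.date_token} ", text)
    for phrase in config.blacklist_phrases:
        text = text.replace(phrase.lower(), " ")
    return [w for w in _WORD.findall(text) if w not in config.stopwords]


def clean_corpus(segmented: Sequence[SegmentedReport],
                 config: CleaningConfig | None = None) -> list[TokenizedReport]:
    """Normalise liver texts into token sequences.

    Corpus-level: the frequency threshold is computed over the whole input,
    separately per domain, *after* stop-word removal and date tokenisation.
    Token order within each report is preserved.
    """
    config = config or CleaningConfig()
    pre = [(s, _normalise(s.text, config)) for s in segmented]
    counts: dict[str, Counter] = {}
    for s, toks in pre:
        counts.setdefault(s.domain, Counter()).update(toks)
    out = []
    for s, toks in pre:
        c = counts[s.domain]
        kept = tuple(t for t in toks if c[t] >= config.min_frequency)
        out.append(TokenizedReport(report_id=s.report_id, domain=s.domain,
                                   style=s.style, tokens=kept, label=s.label))
    return out


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------

def common_vocabulary(vocab_a: Iterable[str], vocab_b: Iterable[str]) -> set[str]:
    """Exact intersection of two vocabularies."""
    return set(vocab_a) & set(vocab_b)


def corpus_statistics(reports: Sequence[ReportDocument],
                      tokenized: Sequence[TokenizedReport] | None = None,
                      ) -> pd.DataFrame:
    """Cohort synopsis: unique/common word counts, report lengths and
    sentence counts (raw text), split by templated/untemplated, plus
    liver-findings token lengths when ``tokenized`` is given.

    Returns a DataFrame with one column per domain and one row per statistic.
    """
    if not reports:
        raise ValueError("corpus_statistics requires a non-empty corpus")
    domains = sorted({r.domain for r in reports})
    if len(domains) != 2:
        raise ValueError(f"expected exactly two domains, got {domains}")

    vocab: dict[str, set] = {d: set() for d in domains}
    words_per_report: dict[str, list[int]] = {d: [] for d in domains}
    sents_per_report: dict[str, list[int]] = {d: [] for d in domains}
    vocab_by_style: dict[str, dict[str, set]] = {
        d: {"templated": set(), "freetext": set()} for d in domains}
    for r in reports:
        ws = _words(r.findings_text())
        vocab[r.domain].update(ws)
        vocab_by_style[r.domain][r.style].update(ws)
        words_per_report[r.domain].append(len(ws))
        sents_per_report[r.domain].append(len(split_sentences(r.findings_text())))

    def mean_sd(values: list[int]) -> str:
        if not values:
            return "n/a"
        return f"{np.mean(values):.1f} (+/- {np.std(values):.1f})"

    rows: dict[str, dict[str, object]] = {}
    rows["Number of unique words"] = {d: len(vocab[d]) for d in domains}
    n_common = len(common_vocabulary(vocab[domains[0]], vocab[domains[1]]))
    rows["Common words in two domains"] = {d: n_common for d in domains}
    rows["Average number of words (+/- std)"] = {
        d: mean_sd(words_per_report[d]) for d in domains}
    rows["Average number of sentences (+/- std)"] = {
        d: mean_sd(sents_per_report[d]) for d in domains}
    rows["Number of unique words in templated reports"] = {
        d: len(vocab_by_style[d]["templated"]) for d in domains}
    rows["Number of unique words in reports without template"] = {
        d: len(vocab_by_style[d]["freetext"]) for d in domains}

    if tokenized:
        liver_lens: dict[str, dict[str, list[int]]] = {
            d: {"templated": [], "freetext": []} for d in domains}
        for t in tokenized:
            liver_lens[t.domain][t.style].append(len(t.tokens))
        rows["Average liver-finding tokens, templated (+/- std)"] = {
            d: mean_sd(liver_lens[d]["templated"]) for d in domains}
        rows["Average liver-finding tokens, without template (+/- std)"] = {
            d: mean_sd(liver_lens[d]["freetext"]) for d in domains}

    return pd.DataFrame(rows).T[domains]
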