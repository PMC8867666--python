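"""Synthetic two-domain radiology-style report corpora.

Real HCC-screening report corpora are PHI-restricted, so this module
generates paired-domain corpora (an ultrasound-like and an MRI-like domain)
with known liver-section spans and known malignant/benign labels.  The two
domains share a core screening lexicon but each carries modality-specific
terms; reports are rendered either with a structured section template
(``FINDINGS:`` / ``IMPRESSION:`` headers and organ labels) or as free text
without headers and with shuffled organ order.  Class-indicative tokens are
planted only inside the liver block, at a configurable rate, which gives the
downstream classifiers a tunable signal floor and gives every pipeline stage
an exact ground-truth oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReportDocument",
    "GroundTruth",
    "SyntheticConfig",
    "SyntheticConfigError",
    "CorpusParseError",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "MALIGNANT_TOKENS",
    "BENIGN_TOKENS",
    "LIVER_ANCHORS",
    "OTHER_ANCHORS",
    "DEPENDENT_TERMS",
]

# ---------------------------------------------------------------------------
# Fixed lexical inventory
# ---------------------------------------------------------------------------

#: Shared class-indicative tokens planted in liver sentences of malignant reports.
MALIGNANT_TOKENS = (
    "mass", "washout", "hypervascular", "capsule", "thrombus",
    "infiltrative", "necrosis", "satellite", "heterogeneous", "enlarging",
)

#: Shared class-indicative tokens planted in liver sentences of benign reports.
BENIGN_TOKENS = (
    "cyst", "hemangioma", "stable", "unremarkable", "simple",
    "granuloma", "calcification", "homogeneous", "tiny", "subcentimeter",
)

#: Anatomical anchors that mark a sentence as liver-related.
LIVER_ANCHORS = ("liver", "hepatic")

#: Non-liver organ anchors (each non-liver block opens with one of these).
OTHER_ANCHORS = ("kidney", "spleen", "pancreas", "gallbladder", "bowel")

#: Terms that refer back to the most recently mentioned anatomical entity.
DEPENDENT_TERMS = ("lesion", "nodule", "focus")

# Style-marker tokens: non-informative filler that differs between templated
# and free-text rendering, so the two styles occupy visibly different regions
# of the language space (classifiers train on templated text only and are
# tested on both).
_TEMPLATED_MARKERS = tuple(f"protocolphrase{i:02d}" for i in range(8))
_FREETEXT_MARKERS = tuple(f"narrativephrase{i:02d}" for i in range(8))

_FIXED_SHARED = (
    MALIGNANT_TOKENS + BENIGN_TOKENS + LIVER_ANCHORS + OTHER_ANCHORS
    + DEPENDENT_TERMS + _TEMPLATED_MARKERS + _FREETEXT_MARKERS
)

_ORGAN_LABELS = {
    "kidney": "Kidneys:", "spleen": "Spleen:", "pancreas": "Pancreas:",
    "gallbladder": "Gallbladder:", "bowel": "Bowel:",
}


class SyntheticConfigError(ValueError):
    """Raised when a :class:`SyntheticConfig` is internally inconsistent."""


class CorpusParseError(ValueError):
    """Raised when a corpus file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class ReportDocument:
    """One report: the atomic input of the whole pipeline."""

    id: str
    domain: str
    style: str  # "templated" | "freetext"
    sections: Mapping[str, str]
    label: str | None = None  # "malignant" | "benign" | None

    def findings_text(self) -> str:
        return self.sections.get("FINDINGS", "")

    def render(self) -> str:
        """Full report text as a reader would see it.

        Templated reports carry the fixed section headers; free-text reports
        are plain prose with no headers.
        """
        if self.style == "templated":
            parts = []
            for header, body in self.sections.items():
                parts.append(f"{header}:")
                parts.append(body)
            return "\n".join(parts)
        return "\n".join(self.sections.values())

    def word_count(self) -> int:
        """Whitespace word count of the findings body (the segmenter's input)."""
        return len(self.findings_text().split())

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "domain": self.domain,
            "style": self.style,
            "sections": dict(self.sections),
            "label": self.label,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ReportDocument":
        return cls(
            id=obj["id"], domain=obj["domain"], style=obj["style"],
            sections=dict(obj["sections"]), label=obj.get("label"),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side oracle for one report."""

    report_id: str
    liver_sentence_indices: tuple[int, ...]
    label: str
    signal_tokens: tuple[str, ...]

    def to_json(self) -> dict:
        return {
            "report_id": self.report_id,
            "liver_sentence_indices": list(self.liver_sentence_indices),
            "label": self.label,
            "signal_tokens": list(self.signal_tokens),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            report_id=obj["report_id"],
            liver_sentence_indices=tuple(obj["liver_sentence_indices"]),
            label=obj["label"],
            signal_tokens=tuple(obj["signal_tokens"]),
        )


def _per_domain(value, domains: Sequence[str], name: str) -> dict:
    if isinstance(value, Mapping):
        missing = [d for d in domains if d not in value]
        if missing:
            raise SyntheticConfigError(f"{name} missing domains {missing}")
        return {d: value[d] for d in domains}
    return {d: value for d in domains}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one paired-domain corpus.

    ``n_reports`` and ``malignant_prevalence`` accept either a single value
    applied to both domains or a per-domain mapping; the emulated cohorts are
    asymmetric (a large source domain with severe class imbalance and a small
    target domain with mild imbalance).
    """

    n_reports: int | Mapping[str, int] = 300
    domains: tuple[str, str] = ("us", "mr")
    shared_vocab_size: int = 600
    private_vocab_size: int = 400
    malignant_prevalence: float | Mapping[str, float] = field(
        default_factory=lambda: {"us": 0.1, "mr": 0.4})
    templated_fraction: float = 0.3
    signal_strength: float = 0.3
    signal_ambiguity: float = 0.15
    freetext_signal_factor: float = 0.7
    domain_variant_fraction: float = 0.3
    length_range: tuple[int, int] = (60, 200)
    seed: int = 0

    def validate(self) -> None:
        n = _per_domain(self.n_reports, self.domains, "n_reports")
        prev = _per_domain(self.malignant_prevalence, self.domains,
                           "malignant_prevalence")
        if any(v < 0 for v in n.values()):
            raise SyntheticConfigError("n_reports must be >= 0")
        for d, p in prev.items():
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(
                    f"malignant_prevalence[{d}]={p} outside [0, 1]")
        if not 0.0 <= self.templated_fraction <= 1.0:
            raise SyntheticConfigError("templated_fraction outside [0, 1]")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise SyntheticConfigError("signal_strength outside [0, 1]")
        if not 0.0 <= self.signal_ambiguity <= 0.5:
            raise SyntheticConfigError("signal_ambiguity outside [0, 0.5]")
        if not 0.0 <= self.freetext_signal_factor <= 1.0:
            raise SyntheticConfigError("freetext_signal_factor outside [0, 1]")
        if self.shared_vocab_size < len(_FIXED_SHARED):
            raise SyntheticConfigError(
                f"shared_vocab_size must be >= {len(_FIXED_SHARED)} "
                "(the fixed screening lexicon)")
        if self.private_vocab_size < len(MALIGNANT_TOKENS) + len(BENIGN_TOKENS) + 1:
            raise SyntheticConfigError(
                "private_vocab_size too small for the domain-variant lexicon")
        lo, hi = self.length_range
        if lo > hi or lo < 30:
            raise SyntheticConfigError(
                "length_range must satisfy 30 <= min <= max")
        if len(self.domains) != 2 or self.domains[0] == self.domains[1]:
            raise SyntheticConfigError("domains must be a pair of distinct tags")

    # -- derived lexicons ---------------------------------------------------

    def shared_lexicon(self) -> tuple[str, ...]:
        """Core tokens used by both domains (fixed terms + neutral fillers)."""
        n_neutral = self.shared_vocab_size - len(_FIXED_SHARED)
        neutral = tuple(f"finding{i:03d}" for i in range(n_neutral))
        return _FIXED_SHARED + neutral

    def private_lexicon(self, domain: str) -> tuple[str, ...]:
        """Modality-specific tokens of one domain.

        Includes a domain-specific surface synonym for every class-indicative
        shared token (e.g. ``washout_us``), so transfer has both overlap to
        exploit and genuinely new vocabulary to learn.
        """
        variants = tuple(f"{t}_{domain}" for t in MALIGNANT_TOKENS + BENIGN_TOKENS)
        n_neutral = self.private_vocab_size - len(variants)
        neutral = tuple(f"{domain}term{i:03d}" for i in range(n_neutral))
        return variants + neutral

    def neutral_shared(self) -> tuple[str, ...]:
        n_neutral = self.shared_vocab_size - len(_FIXED_SHARED)
        return tuple(f"finding{i:03d}" for i in range(n_neutral))

    def neutral_private(self, domain: str) -> tuple[str, ...]:
        n_var = len(MALIGNANT_TOKENS) + len(BENIGN_TOKENS)
        return tuple(f"{domain}term{i:03d}"
                     for i in range(self.private_vocab_size - n_var))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _draw_content(rng: np.random.Generator, k: int, pools: list[tuple[str, ...]],
                  weights: list[float]) -> list[str]:
    """Draw k content words, choosing a pool per word by weight."""
    out = []
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    for _ in range(k):
        pool = pools[int(rng.choice(len(pools), p=w))]
        out.append(pool[int(rng.integers(len(pool)))])
    return out


class _ReportBuilder:
    """Builds one report sentence-by-sentence under an exact word budget."""

    def __init__(self, cfg: SyntheticConfig, domain: str, label: str,
                 style: str, rng: np.random.Generator):
        self.cfg, self.domain, self.label, self.style, self.rng = (
            cfg, domain, label, style, rng)
        self.signal_pool = (MALIGNANT_TOKENS if label == "malignant"
                            else BENIGN_TOKENS)
        self.counter_pool = (BENIGN_TOKENS if label == "malignant"
                             else MALIGNANT_TOKENS)
        # untemplated narrative states findings less densely
        self.eff_signal = cfg.signal_strength * (
            1.0 if style == "templated" else cfg.freetext_signal_factor)
        self.neutral_pools = [cfg.neutral_shared(), cfg.neutral_private(domain)]
        self.markers = (_TEMPLATED_MARKERS if style == "templated"
                        else _FREETEXT_MARKERS)
        self.signal_tokens_used: list[str] = []

    def _neutral_words(self, k: int) -> list[str]:
        words = _draw_content(self.rng, k, self.neutral_pools, [0.7, 0.3])
        # sprinkle one style marker into ~half of all sentences
        if k >= 2 and self.rng.random() < 0.5:
            words[int(self.rng.integers(k))] = self.markers[
                int(self.rng.integers(len(self.markers)))]
        return words

    def _liver_content(self, k: int) -> list[str]:
        """Content words of a liver sentence: class signal vs neutral mix.

        A fraction ``signal_ambiguity`` of signal draws come from the
        opposite class's group — both classes mention the shared finding
        vocabulary (as real reports do, e.g. to state a finding's absence) —
        which sets the generator's Bayes floor.
        """
        words = []
        for _ in range(k):
            if self.rng.random() < self.eff_signal:
                consistent = self.rng.random() >= self.cfg.signal_ambiguity
                pool = self.signal_pool if consistent else self.counter_pool
                tok = pool[int(self.rng.integers(len(pool)))]
                if self.rng.random() < self.cfg.domain_variant_fraction:
                    tok = f"{tok}_{self.domain}"
                if consistent:
                    self.signal_tokens_used.append(tok)
                words.append(tok)
            else:
                words.append(self._neutral_words(1)[0])
        return words

    def liver_block(self, n_sent: int, budget: int) -> list[str]:
        """Liver sentences: the first carries a liver anchor, later ones
        alternate between 'hepatic' anchors and anchor-free dependent-term
        sentences (which the segmenter must resolve back to the liver)."""
        sents = []
        for i in range(n_sent):
            k = int(self.rng.integers(4, 9))
            k = max(1, min(k, budget - 3))
            content = self._liver_content(k)
            if i == 0:
                words = ["the", "liver", "shows"] + content
            elif self.rng.random() < 0.45:
                dep = DEPENDENT_TERMS[int(self.rng.integers(len(DEPENDENT_TERMS)))]
                words = ["a", dep, "with"] + content
            else:
                words = ["the", "hepatic", "parenchyma", "has"] + content
            sents.append(" ".join(words) + ".")
            budget -= len(words)
            if budget < 8:
                break
        return sents

    def organ_block(self, organ: str, n_sent: int, budget: int) -> list[str]:
        sents = []
        for i in range(n_sent):
            k = int(self.rng.integers(3, 8))
            k = max(1, min(k, budget - 3))
            content = self._neutral_words(k)
            if i == 0:
                words = ["the", organ, "is"] + content
            elif self.rng.random() < 0.3:
                # dependent term anchored to THIS organ, not the liver
                dep = DEPENDENT_TERMS[int(self.rng.integers(len(DEPENDENT_TERMS)))]
                words = ["a", dep, "near", "the", organ, "with"] + content
            else:
                words = ["there", "is"] + content
            sents.append(" ".join(words) + ".")
            budget -= len(words)
            if budget < 8:
                break
        return sents

    def build(self) -> tuple[str, tuple[int, ...]]:
        """Render the findings body; returns (text, liver sentence ordinals)."""
        lo, hi = self.cfg.length_range
        target = int(self.rng.integers(lo, hi + 1))

        n_liver = int(self.rng.integers(2, 6))
        organs = list(OTHER_ANCHORS[:-1])
        self.rng.shuffle(organs)
        organs = organs[: int(self.rng.integers(2, 5))]

        # Reserve roughly proportional budgets; exact length is enforced by
        # the filler loop at the end.
        liver_sents = self.liver_block(n_liver, budget=max(20, target // 3))
        blocks: list[tuple[str, list[str]]] = [("liver", liver_sents)]
        used = sum(len(s.split()) for s in liver_sents)
        for organ in organs:
            remaining = target - used
            if remaining < 10:
                break
            sents = self.organ_block(organ, int(self.rng.integers(1, 4)),
                                     budget=remaining // 2 + 5)
            blocks.append((organ, sents))
            used += sum(len(s.split()) for s in sents)

        if self.style == "freetext":
            order = self.rng.permutation(len(blocks))
            blocks = [blocks[i] for i in order]

        # filler sentences (no anchors, no signal) appended to the last
        # non-liver block -- or their own trailing run in free text
        sentences: list[str] = []
        liver_idx: list[int] = []
        for name, sents in blocks:
            if name == "liver":
                liver_idx.extend(range(len(sentences), len(sentences) + len(sents)))
            sentences.extend(sents)

        count = sum(len(s.split()) for s in sentences)
        while count < lo:
            k = min(int(self.rng.integers(4, 10)), hi - count - 2)
            k = max(1, k)
            words = ["there", "is"] + self._neutral_words(k)
            if count + len(words) > hi:
                words = words[: hi - count]
            sentences.append(" ".join(words) + ".")
            count += len(words)

        if self.style == "templated":
            rendered = []
            for name, sents in blocks:
                label = "Liver:" if name == "liver" else _ORGAN_LABELS[name]
                rendered.append(label + " " + " ".join(sents))
            # trailing fillers belong to the last labelled block
            n_in_blocks = sum(len(s) for _, s in blocks)
            extra = sentences[n_in_blocks:]
            if extra:
                rendered[-1] = rendered[-1] + " " + " ".join(extra)
            text = "\n".join(rendered)
        else:
            text = " ".join(sentences)
        return text, tuple(liver_idx)


def _impression(label: str) -> str:
    if label == "malignant":
        return "hepatic malignancy suspected, malignant features present."
    return "no suspicious hepatic abnormality, benign findings."


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[ReportDocument], list[GroundTruth]]:
    """Generate a paired-domain corpus with ground truth.

    Deterministic: the same config (including seed) yields a byte-identical
    corpus.  Per domain, exactly ``round(prevalence * n)`` reports are
    malignant and exactly ``round(templated_fraction * n)`` are templated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_by_domain = _per_domain(config.n_reports, config.domains, "n_reports")
    prev = _per_domain(config.malignant_prevalence, config.domains,
                       "malignant_prevalence")

    reports: list[ReportDocument] = []
    truths: list[GroundTruth] = []
    for domain in config.domains:
        n = n_by_domain[domain]
        n_mal = _round_half_up(prev[domain] * n)
        labels = np.array(["malignant"] * n_mal + ["benign"] * (n - n_mal))
        rng.shuffle(labels)
        n_temp = _round_half_up(config.templated_fraction * n)
        styles = np.array(["templated"] * n_temp + ["freetext"] * (n - n_temp))
        rng.shuffle(styles)

        for i in range(n):
            label, style = str(labels[i]), str(styles[i])
            builder = _ReportBuilder(config, domain, label, style, rng)
            findings, liver_idx = builder.build()
            rid = f"{domain}-{i:05d}"
            reports.append(ReportDocument(
                id=rid, domain=domain, style=style,
                sections={"FINDINGS": findings, "IMPRESSION": _impression(label)},
                label=label,
            ))
            truths.append(GroundTruth(
                report_id=rid, liver_sentence_indices=liver_idx,
                label=label, signal_tokens=tuple(builder.signal_tokens_used),
            ))
    return reports, truths


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------

def write_corpus(reports: Sequence[ReportDocument],
                 ground_truth: Sequence[GroundTruth],
                 path: str | Path) -> None:
    """Write ``reports.jsonl`` and ``truth.jsonl`` under directory *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "reports.jsonl", "w") as fh:
        for r in reports:
            fh.write(json.dumps(r.to_json(), sort_keys=True) + "\n")
    with open(path / "truth.jsonl", "w") as fh:
        for t in ground_truth:
            fh.write(json.dumps(t.to_json(), sort_keys=True) + "\n")


def _read_jsonl(fp: Path) -> list[dict]:
    out = []
    with open(fp) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorpusParseError(
                    f"{fp.name}: malformed JSON at line {lineno}: {exc}"
                ) from exc
    return out


def read_corpus(path: str | Path) -> tuple[list[ReportDocument], list[GroundTruth]]:
    """Inverse of :func:`write_corpus` (round-trip identity)."""
    path = Path(path)
    reports = [ReportDocument.from_json(o) for o in _read_jsonl(path / "reports.jsonl")]
    truth_fp = path / "truth.jsonl"
    truths = ([GroundTruth.from_json(o) for o in _read_jsonl(truth_fp)]
              if truth_fp.exists() else [])
    return reports, truths
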