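"""Orchestration of the four experimental settings.

Settings 1/3 train the language model from scratch on the evaluation (target)
domain; settings 2/4 first train it on the other (source) domain, transfer-
initialise the shared vocabulary and fine-tune on the target.  In every
setting the downstream malignant/benign classifier is trained only on
templated reports and evaluated on two held-out test sets: templated reports
and the harder untemplated ones.  Language models train on all target-domain
reports (labels are never needed for LM training); classifier train and test
splits are disjoint by report id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classify, mlm, w2v
from ._cnn import CNNParams
from .classify import RFParams
from .preprocess import (CleaningConfig, TokenizedReport, clean_corpus,
                         segment_corpus)
from .reports import ReportDocument

__all__ = [
    "SettingSpec",
    "ExperimentConfig",
    "prepare_corpora",
    "split_target",
    "run_setting",
    "run_full_factorial",
    "transfer_benefit",
    "family_comparison",
    "results_to_tsv",
]

_FAMILY_NAMES = {"w2v": "Word2Vec", "mlm": "MaskedLM"}
_CLF_NAMES = {"rf": "Random Forest Classifier",
              "cnn_random": "1DCNN",
              "cnn_pretrained": "Embedding+1DCNN"}


@dataclass(frozen=True)
class SettingSpec:
    """One experimental cell: which LM, which classifier, which domains."""
    setting_id: int                      # 1..4
    lm_family: str                       # "w2v" | "mlm"
    classifier_kind: str                 # "rf" | "cnn_random" | "cnn_pretrained"
    target_domain: str
    source_domain: str | None = None     # required for settings 2 and 4
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.setting_id not in (1, 2, 3, 4):
            raise ValueError("setting_id must be 1..4")
        transfer = self.setting_id in (2, 4)
        if transfer and not self.source_domain:
            raise ValueError(
                f"setting {self.setting_id} is a transfer setting and "
                "requires source_domain")
        if not transfer and self.source_domain:
            raise ValueError(
                f"setting {self.setting_id} trains from scratch; "
                "source_domain must be None")
        if self.lm_family not in _FAMILY_NAMES:
            raise ValueError(f"unknown lm_family {self.lm_family!r}")
        if self.classifier_kind not in _CLF_NAMES:
            raise ValueError(f"unknown classifier {self.classifier_kind!r}")
        if self.lm_family == "mlm" and self.classifier_kind != "rf":
            raise ValueError("the masked-LM family pairs only with rf")

    @property
    def transfer(self) -> bool:
        return self.setting_id in (2, 4)

    @property
    def title(self) -> str:
        dom = self.target_domain.upper()
        ft = "-finetuned" if self.transfer else ""
        return f"{dom}{ft} {_FAMILY_NAMES[self.lm_family]}+{_CLF_NAMES[self.classifier_kind]}"


@dataclass(frozen=True)
class ExperimentConfig:
    """Hyperparameters shared across settings."""
    dim: int = 100
    window: int = 5
    w2v_epochs: int = 10
    w2v_finetune_epochs: int = 5
    min_count: int = 2
    mlm_vocab_size: int = 600
    mlm_epochs: int = 10
    mlm_finetune_epochs: int = 5
    cnn: CNNParams = field(default_factory=CNNParams)
    rf: RFParams = field(default_factory=RFParams)
    test_fraction: float = 0.2
    split_seed: int = 0


def prepare_corpora(reports: Sequence[ReportDocument],
                    cleaning: CleaningConfig | None = None,
                    ) -> dict[str, list[TokenizedReport]]:
    """Segment + clean a raw corpus; returns tokenized reports per domain."""
    cleaning = cleaning or CleaningConfig(min_frequency=2)
    tokenized = clean_corpus(segment_corpus(reports), cleaning)
    out: dict[str, list[TokenizedReport]] = {}
    for t in tokenized:
        out.setdefault(t.domain, []).append(t)
    return out


def split_target(target_reports: Sequence[TokenizedReport],
                 test_fraction: float, split_seed: int):
    """Stratified templated train/test split plus the untemplated test set.

    Reports without a usable token sequence are dropped (they cannot be
    embedded); the three returned sets are disjoint by id.
    """
    usable = [t for t in target_reports if t.tokens and t.label]
    templated = [t for t in usable if t.style == "templated"]
    untemplated = [t for t in usable if t.style == "freetext"]
    labels = [t.label for t in templated]
    train, test = train_test_split(
        templated, test_size=test_fraction, random_state=split_seed,
        stratify=labels)
    return list(train), list(test), untemplated


def _count_vocab(corpus: Sequence[TokenizedReport], min_count: int):
    c = Counter(t for r in corpus for t in r.tokens)
    return {t: n for t, n in c.items() if n >= min_count}


def _build_lm(spec: SettingSpec, corpora, config: ExperimentConfig, seed: int,
              lm_cache: dict | None):
    """Train (or fetch) the language model this setting calls for."""
    key = (spec.lm_family, spec.target_domain, spec.source_domain, seed)
    if lm_cache is not None and key in lm_cache:
        return lm_cache[key]
    target_corpus = corpora[spec.target_domain]
    if spec.lm_family == "w2v":
        if spec.transfer:
            src = _build_lm(replace(spec, setting_id=1 if spec.setting_id == 2
                                    else 3, source_domain=None,
                                    target_domain=spec.source_domain),
                            corpora, config, seed, lm_cache)
            counts = _count_vocab(target_corpus, config.min_count)
            init = w2v.transfer_initialize(
                src, counts, dim=config.dim, seed=seed,
                domain=spec.target_domain)
            model = w2v.finetune(init, target_corpus,
                                 epochs=config.w2v_finetune_epochs,
                                 window=config.window, seed=seed)
        else:
            model = w2v.train_skipgram(
                target_corpus, dim=config.dim, window=config.window,
                epochs=config.w2v_epochs, min_count=config.min_count,
                seed=seed, domain=spec.target_domain)
    else:
        if spec.transfer:
            src = _build_lm(replace(spec, setting_id=1 if spec.setting_id == 2
                                    else 3, source_domain=None,
                                    target_domain=spec.source_domain),
                            corpora, config, seed, lm_cache)
            init = mlm.transfer_initialize_mlm(src, target_corpus, seed=seed,
                                               domain=spec.target_domain)
            model = mlm.finetune_mlm(init, target_corpus,
                                     epochs=config.mlm_finetune_epochs,
                                     seed=seed)
        else:
            model = mlm.train_mlm(target_corpus, epochs=config.mlm_epochs,
                                  seed=seed, vocab_size=config.mlm_vocab_size,
                                  domain=spec.target_domain)
    if lm_cache is not None:
        lm_cache[key] = model
    return model


def _embed_set(lm, family: str, reports: Sequence[TokenizedReport], tag: str):
    embed = w2v.embed_report if family == "w2v" else mlm.embed_report_mlm
    vecs, kept = [], []
    for r in reports:
        try:
            vecs.append(embed(lm, r))
        except ValueError:
            continue
    return classify.LabeledVectorSet.from_report_vectors(vecs, split_tag=tag)


def run_setting(spec: SettingSpec,
                corpora: Mapping[str, Sequence[TokenizedReport]],
                config: ExperimentConfig | None = None,
                lm_cache: dict | None = None) -> pd.DataFrame:
    """Execute one setting for every seed; returns per-seed result rows.

    Each run emits two test-set cells (templated, untemplated) with
    per-class precision/recall/f1 and weighted f1.
    """
    config = config or ExperimentConfig()
    for dom in (spec.target_domain, spec.source_domain):
        if dom and dom not in corpora:
            raise KeyError(f"missing corpus for domain {dom!r}")
    train, test_t, test_u = split_target(
        corpora[spec.target_domain], config.test_fraction, config.split_seed)
    train_ids = {t.report_id for t in train}
    assert train_ids.isdisjoint(t.report_id for t in test_t + test_u)

    rows = []
    for seed in spec.seeds:
        lm = _build_lm(spec, corpora, config, seed, lm_cache)
        if spec.classifier_kind == "rf":
            train_set = _embed_set(lm, spec.lm_family, train, "train")
            clf = classify.train_rf(train_set, config.rf, seed=seed)
            test_sets = {
                "test_templated": _embed_set(lm, spec.lm_family, test_t,
                                             "test_templated"),
                "test_untemplated": _embed_set(lm, spec.lm_family, test_u,
                                               "test_untemplated"),
            }
            def _predict(ts):
                labels, _ = classify.predict(clf, ts.vectors)
                return list(zip(ts.report_ids, labels)), \
                    list(zip(ts.report_ids, ts.labels))
            evals = {name: classify.evaluate(*_predict(ts))
                     for name, ts in test_sets.items()}
        else:
            vocab = lm.vocab
            init = lm.vectors if spec.classifier_kind == "cnn_pretrained" else None
            hp = config.cnn
            if hp.dim != config.dim:
                hp = replace(hp, dim=config.dim)
            clf = classify.train_cnn(
                [t.tokens for t in train], [t.label for t in train],
                vocab, embedding_init=init, hyperparams=hp, seed=seed)
            clf.embedding_model_id = (lm.model_id if init is not None else None)
            evals = {}
            for name, subset in (("test_templated", test_t),
                                 ("test_untemplated", test_u)):
                labels, _ = classify.predict(clf, [t.tokens for t in subset])
                preds = list(zip((t.report_id for t in subset), labels))
                truth = [(t.report_id, t.label) for t in subset]
                evals[name] = classify.evaluate(preds, truth)
        for name, ev in evals.items():
            row = {
                "title": spec.title, "setting_id": spec.setting_id,
                "lm_family": spec.lm_family,
                "classifier": spec.classifier_kind,
                "target_domain": spec.target_domain,
                "source_domain": spec.source_domain or "",
                "transfer": spec.transfer, "test_set": name, "seed": seed,
                "lm_model_id": lm.model_id,
                "finetuned_from": (lm.provenance or {}).get("finetuned_from")
                                   or "",
            }
            row.update(ev.as_row())
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_factorial(corpora, target_domain: str, source_domain: str,
                       seeds: Sequence[int],
                       config: ExperimentConfig | None = None,
                       lm_families: Sequence[str] = ("w2v", "mlm"),
                       ) -> pd.DataFrame:
    """All six experiment titles for one evaluation domain:
    {scratch, finetuned} x {w2v+rf, w2v-embedding+cnn, mlm+rf}."""
    config = config or ExperimentConfig()
    scratch_id = 3 if target_domain == "us" else 1
    transfer_id = 4 if target_domain == "us" else 2
    cells = []
    for family in lm_families:
        kinds = ("rf", "cnn_pretrained") if family == "w2v" else ("rf",)
        for kind in kinds:
            cells.append(SettingSpec(scratch_id, family, kind, target_domain,
                                     None, tuple(seeds)))
            cells.append(SettingSpec(transfer_id, family, kind, target_domain,
                                     source_domain, tuple(seeds)))
    cache: dict = {}
    tables = [run_setting(c, corpora, config, lm_cache=cache) for c in cells]
    return pd.concat(tables, ignore_index=True)


def run_benchmark(seed: int = 0, n_source: int = 3000, n_target: int = 300,
                  n_seeds: int = 5, config: ExperimentConfig | None = None,
                  source_domain: str = "us", target_domain: str = "mr",
                  include_mlm: bool = True) -> pd.DataFrame:
    """The default synthetic benchmark: a large source corpus, a small target
    corpus (vocabulary overlap ~0.6), replicated over ``n_seeds`` seeds.

    Runs the cells the headline comparisons need: w2v+rf and
    w2v-embedding+cnn in both the scratch and finetuned arms, plus mlm+rf
    from scratch for the family comparison.
    """
    from .reports import SyntheticConfig, generate_corpus

    config = config or ExperimentConfig()
    corpus_cfg = SyntheticConfig(
        n_reports={source_domain: n_source, target_domain: n_target},
        domains=(source_domain, target_domain), seed=seed)
    reports, _ = generate_corpus(corpus_cfg)
    corpora = prepare_corpora(reports)
    seeds = tuple(seed * 1000 + i for i in range(n_seeds))
    scratch_id = 3 if target_domain == "us" else 1
    transfer_id = 4 if target_domain == "us" else 2
    cells = [
        SettingSpec(scratch_id, "w2v", "rf", target_domain, None, seeds),
        SettingSpec(transfer_id, "w2v", "rf", target_domain, source_domain, seeds),
        SettingSpec(scratch_id, "w2v", "cnn_pretrained", target_domain, None, seeds),
        SettingSpec(transfer_id, "w2v", "cnn_pretrained", target_domain,
                    source_domain, seeds),
    ]
    if include_mlm:
        cells.append(SettingSpec(scratch_id, "mlm", "rf", target_domain,
                                 None, seeds))
    cache: dict = {}
    tables = [run_setting(c, corpora, config, lm_cache=cache) for c in cells]
    return pd.concat(tables, ignore_index=True)


def _cell(table: pd.DataFrame, lm_family: str, classifier_kind: str,
          transfer: bool, test_set: str) -> pd.DataFrame:
    sel = table[(table.lm_family == lm_family)
                & (table.classifier == classifier_kind)
                & (table.transfer == transfer)
                & (table.test_set == test_set)]
    if sel.empty:
        raise ValueError(
            f"missing results for {lm_family}+{classifier_kind} "
            f"transfer={transfer} on {test_set}")
    return sel.set_index("seed")


def transfer_benefit(table: pd.DataFrame, lm_family: str,
                     classifier_kind: str,
                     test_set: str = "test_untemplated") -> pd.Series:
    """Per-seed weighted-f1 deltas (finetuned - scratch) for one pairing."""
    ft = _cell(table, lm_family, classifier_kind, True, test_set)
    sc = _cell(table, lm_family, classifier_kind, False, test_set)
    return (ft.weighted_f1 - sc.weighted_f1).dropna()


def family_comparison(table: pd.DataFrame, classifier_kind: str = "rf",
                      test_set: str = "test_untemplated") -> pd.DataFrame:
    """Per-seed weighted-f1 differences (w2v - mlm) per transfer arm."""
    out = {}
    for transfer in (False, True):
        try:
            a = _cell(table, "w2v", classifier_kind, transfer, test_set)
            b = _cell(table, "mlm", "rf", transfer, test_set)
        except ValueError:
            continue
        out["finetuned" if transfer else "scratch"] = (
            a.weighted_f1 - b.weighted_f1)
    if not out:
        raise ValueError("need both families in the table")
    return pd.DataFrame(out)


def results_to_tsv(table: pd.DataFrame, path) -> pd.DataFrame:
    """Write the seed-averaged results grid (per title/class/test set)."""
    recs = []
    for (title, test_set), grp in table.groupby(["title", "test_set"]):
        for cls in ("malignant", "benign"):
            recs.append({
                "title": title, "test_set": test_set, "class": cls,
                "precision": grp[f"{cls}_precision"].mean(),
                "recall": grp[f"{cls}_recall"].mean(),
                "f1": grp[f"{cls}_f1"].mean(),
                "weighted_f1": grp.weighted_f1.mean(),
            })
    df = pd.DataFrame(recs)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return df
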