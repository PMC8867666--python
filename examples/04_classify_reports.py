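"""Train the three classifiers and evaluate them per test set.

Report vectors (mean of token embeddings) feed a Random Forest; token index
sequences feed the 1D-CNN, whose embedding layer is either random or
initialised from the word-embedding model.  Classifiers train on templated
reports only and are evaluated on templated and (harder) untemplated test
sets — the metric layout printed is per-class precision/recall/f1 plus the
support-weighted f1.
"""

from xferlang import (CNNParams, LabeledVectorSet, SyntheticConfig,
                      embed_report, evaluate, generate_corpus, predict,
                      prepare_corpora, train_cnn, train_rf, train_skipgram)
from xferlang.experiments import split_target

reports, _ = generate_corpus(SyntheticConfig(n_reports={"us": 200, "mr": 400},
                                             seed=3))
corpora = prepare_corpora(reports)
mr = corpora["mr"]
lm = train_skipgram(mr, dim=100, epochs=10, seed=0, domain="mr")
train, test_t, test_u = split_target(mr, test_fraction=0.2, split_seed=0)
print(f"train {len(train)} templated; test {len(test_t)} templated "
      f"+ {len(test_u)} untemplated\n")

vec = lambda subset, tag: LabeledVectorSet.from_report_vectors(
    [embed_report(lm, t) for t in subset], split_tag=tag)
rf = train_rf(vec(train, "train"), seed=0)

cnn = train_cnn([t.tokens for t in train], [t.label for t in train],
                lm.vocab, embedding_init=lm.vectors,
                hyperparams=CNNParams(dim=lm.dim), seed=0)

for name, subset in (("templated", test_t), ("untemplated", test_u)):
    ts = vec(subset, name)
    labels, _ = predict(rf, ts.vectors)
    ev = evaluate(list(zip(ts.report_ids, labels)),
                  list(zip(ts.report_ids, ts.labels)))
    print(f"RF  {name:<12} weighted f1 {ev.weighted_f1:.3f}  "
          f"malignant f1 {ev.per_class['malignant']['f1']:.3f}")
    labels, _ = predict(cnn, [t.tokens for t in subset])
    ev = evaluate(list(zip((t.report_id for t in subset), labels)),
                  [(t.report_id, t.label) for t in subset])
    print(f"CNN {name:<12} weighted f1 {ev.weighted_f1:.3f}  "
          f"malignant f1 {ev.per_class['malignant']['f1']:.3f}")
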