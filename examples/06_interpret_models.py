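"""Inspect what the models learned: token heatmaps and 2-D projections.

The sensitivity heatmap weights each token of a report by the gradient norm
of the CNN's loss at its predicted label — the tokens the decision leaned
on.  The projections reduce vocabulary vectors (tagged common vs new after
transfer) and mean report vectors (tagged by class) to two dimensions with
t-SNE; the silhouette quantifies how separable the classes are per domain.
"""

from collections import Counter

from xferlang import (CNNParams, SyntheticConfig, embed_report, finetune,
                      generate_corpus, label_separation, prepare_corpora,
                      project_reports, project_vocab, sensitivity_heatmap,
                      train_cnn, train_skipgram, transfer_initialize)
from xferlang.experiments import split_target

reports, _ = generate_corpus(
    SyntheticConfig(n_reports={"us": 600, "mr": 300}, seed=5))
corpora = prepare_corpora(reports)

src = train_skipgram(corpora["us"], dim=60, epochs=8, seed=0, domain="us")
counts = Counter(t for r in corpora["mr"] for t in r.tokens)
ft = finetune(transfer_initialize(src, counts, dim=60, seed=0, domain="mr"),
              corpora["mr"], epochs=5, seed=0)

train, test_t, test_u = split_target(corpora["mr"], 0.2, 0)
cnn = train_cnn([t.tokens for t in train], [t.label for t in train],
                ft.vocab, embedding_init=ft.vectors,
                hyperparams=CNNParams(dim=60, max_len=60), seed=0)

hm = sensitivity_heatmap(cnn, test_u[0])
top = sorted(zip(hm.tokens, hm.weights), key=lambda p: -p[1])[:5]
print(f"report {hm.report_id}: predicted {hm.predicted_label} "
      f"(true {hm.true_label}); highest-weight tokens:")
for tok, w in top:
    print(f"  {tok:<18} {w:.2f}")

proj = project_vocab((src, ft), perplexity=20, seed=0, max_iter=300)
n_new = sum(s == "new" for s in proj.tags["status"])
print(f"\nvocabulary projection: {len(proj.ids)} points, "
      f"{n_new} marked 'new' (target-only words learned in fine-tuning)")

vecs = [embed_report(ft, t) for t in corpora["mr"] if t.tokens]
rep = project_reports(vecs, styles={t.report_id: t.style
                                    for t in corpora["mr"]},
                      perplexity=20, seed=0, max_iter=300)
print(f"report projection: {len(rep.ids)} points; malignant/benign "
      f"silhouette in this space: {label_separation(vecs):.3f} "
      "(higher = classes better separated)")
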