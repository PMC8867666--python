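# xferlang

Cross-domain language-space transfer for classifying radiology-style
screening reports as **malignant** or **benign** when the evaluation domain
has little labelled (or even unlabelled) text.

Hepatocellular-carcinoma screening produces reports from different imaging
modalities — say an ultrasound-like domain and an MRI-like domain — that
share a core screening terminology but differ in modality-specific lexicon.
Structured (templated) reports carry a machine-readable label; the bulk of
reports are free-text and unlabelled. `xferlang` implements *similar-domain
adaptation* for this setting: train a language model on the data-rich
domain, transfer its shared-vocabulary representations to the data-poor
domain, fine-tune there, and use the resulting report representations to
train a classifier on the few templated reports — then label everything
else, including the harder untemplated reports.

Because real screening corpora contain PHI and cannot be shipped, the
package includes a first-class synthetic generator that emulates the
essential structure — two domains with controlled vocabulary overlap,
liver findings embedded among other organ sections, templated vs free-text
styles, class imbalance, and a tunable Bayes floor — with exact ground
truth for every pipeline stage.

## The method

**Language models.** Context-independent embeddings are trained with
skipgram and hierarchical softmax: for a center word $w_t$ and context word
$w_c$ within a window, the model maximises
$\log p(w_c \mid w_t) = \sum_{j} \log \sigma\!\big((1 - 2d_j)\, \mathbf{v}_{w_t}^\top \mathbf{u}_{n_j}\big)$,
the product running over the Huffman-tree path $(n_j, d_j)$ of $w_c$. The
context-dependent alternative is a compact transformer encoder trained as a
masked language model over a byte-pair subword vocabulary.

**Transfer.** For word embeddings, a target-domain model over vocabulary
$V_T$ is initialised from a source model over $V_S$ by copying
$\mathbf{v}_w^{(T)} \leftarrow \mathbf{v}_w^{(S)}$ *exactly* for every
$w \in V_T \cap V_S$ and drawing $w \in V_T \setminus V_S$ from
$\mathcal{U}(-0.5/d,\, 0.5/d)$; skipgram training then continues on the
target corpus with all rows trainable. For the masked LM, the source
subword vocabulary and all transformer weights are reused, with embedding
rows appended only for units the source never saw.

**Classifiers.** (i) a Random Forest on mean-of-token-vector report
embeddings $\bar{\mathbf{v}} = \frac{1}{n}\sum_i \mathbf{v}_{w_i}$;
(ii) a 1D-CNN (embedding → 1-D convolution → dropout → dense) with random
embedding initialisation; (iii) the same CNN with its embedding layer
initialised from the word-embedding model. Classifiers train on templated
reports only and are evaluated on both templated and untemplated test sets
with per-class precision/recall/f1 and support-weighted f1.

**Interpretation.** Per-token sensitivity heatmaps from the gradient of the
classification loss with respect to each token's embedding (L2 norm,
normalised per report), and t-SNE projections of vocabularies (common vs
new words after transfer) and report vectors (class and style separation).

Before any of that, reports are preprocessed: a lexicon-driven segmenter
extracts only liver-related findings sentences (resolving dependent terms
like "lesion" to their most recent anatomical anchor, and never reading the
Impression section, which restates the label), and cleaning lowercases,
replaces date/time stamps with `<datetoken>`, removes stop words and drops
tokens under a per-domain frequency threshold.

## Worked example

`examples/05_run_experiments.py` trains the target-domain word-embedding
model both from scratch and transfer-initialised from a 5x larger source
domain, then compares downstream classification:

```
                                                                  mean    std
title                                          test_set
MR Word2Vec+Random Forest Classifier           test_templated    0.796  0.032
                                               test_untemplated  0.584  0.042
MR-finetuned Word2Vec+Random Forest Classifier test_templated    0.852  0.032
                                               test_untemplated  0.827  0.023

per-seed untemplated weighted-f1 delta (finetuned - scratch): [0.211 0.203 0.313]; mean +0.242
```

Rows are support-weighted f1 over three replicate seeds. The scratch and
fine-tuned language models perform comparably on templated test reports,
but on the harder untemplated test set the transfer-initialised model is
clearly better — the central claim of similar-domain adaptation: with
little target-domain text, continuing from a related language space beats
learning one from scratch.

The other scripts in `examples/` each demonstrate one capability
(generation and cohort statistics, segmentation + cleaning, embedding
transfer, the three classifiers, heatmaps and projections). A thin CLI
mirrors the pipeline: `xferlang generate`, `xferlang preprocess`,
`xferlang train-w2v`, `xferlang transfer-w2v`, `xferlang train-mlm`,
`xferlang transfer-mlm`, `xferlang run`.

## Layout

- `src/xferlang/reports.py` — synthetic two-domain corpus generator + JSONL I/O
- `src/xferlang/preprocess.py` — liver segmentation, cleaning, cohort statistics
- `src/xferlang/w2v.py` — skipgram/hierarchical-softmax embeddings + transfer
- `src/xferlang/mlm.py` — BPE tokenizer, small transformer masked LM + transfer
- `src/xferlang/classify.py` — Random Forest / 1D-CNN classifiers, metrics
- `src/xferlang/experiments.py` — the four settings, benchmark, results tables
- `src/xferlang/interpret.py` — sensitivity heatmaps, t-SNE projections
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
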