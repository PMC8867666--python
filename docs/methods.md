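# Methods

This note records the modelling choices behind `xferlang`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic corpora do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## The pipeline and its assumptions

The package addresses binary malignancy labelling of liver-screening
reports across two related text domains (different imaging modalities,
possibly different institutions). Its working assumptions:

1. The domains share a core screening terminology; each also has a private
   modality-specific lexicon. Transfer is useful exactly because the
   shared part is large (here ~0.6 of the target vocabulary).
2. Only the liver-related findings carry the label signal worth modelling;
   the Impression section restates the assessment and must be excluded to
   keep the task honest.
3. Labelled (templated) reports are scarce relative to free-text reports,
   and the free-text style differs enough that a classifier trained on
   templated text degrades on untemplated text.
4. Language-model training needs no labels, so it may use every report of
   a domain; classifier training uses only the templated training split.

## Synthetic corpora

Real screening corpora are PHI-restricted, so the generator emulates their
load-bearing structure with exact ground truth. Defaults define the study
conditions and are frozen:

| parameter | default | rationale |
|---|---|---|
| `domains` | `("us", "mr")` | ultrasound-like source, MRI-like target |
| `malignant_prevalence` | us 0.10, mr 0.40 | severe imbalance in one domain, mild in the other |
| `templated_fraction` | 0.3 | templated (labelled) reports are the minority, as in LI-RADS adoption; the labelled training pool stays deliberately small |
| `shared_vocab_size` / `private_vocab_size` | 600 / 400 | vocabulary overlap 0.6; large enough that a 300-report corpus is genuinely data-starved (most tokens seen only a handful of times), which is the regime where transfer matters |
| `signal_strength` | 0.3 | fraction of liver-sentence content words drawn from class-signal groups |
| `signal_ambiguity` | 0.15 | fraction of signal draws taken from the *opposite* class's group: both classes mention the shared finding lexicon (real reports state absent findings too), which sets a Bayes floor below perfect classification |
| `freetext_signal_factor` | 0.7 | untemplated narrative states findings less densely, making the untemplated test set harder |
| `domain_variant_fraction` | 0.3 | chance a signal token is rendered as a domain-private surface synonym (`washout_mr`), giving fine-tuning genuinely new words to learn |
| `length_range` | (60, 200) | findings-body word counts; enforced exactly |

Construction guarantees used as oracles: label and style counts are the
deterministic rounding of fraction × n; class-signal tokens appear only in
the liver block; liver-block sentences are contiguous; dependent-term
sentences ("a lesion …") inside the liver block have the liver as most
recent anatomical anchor, while organ blocks mention their anchor
in-sentence; free-text rendering drops headers and shuffles organ order;
sentence boundaries are terminal periods only. Identical config + seed
yields byte-identical corpora.

**What the generator does not emulate:** real clinical syntax, negation
and uncertainty semantics, abbreviation-laden sentence boundaries,
misspellings, long-range discourse, and annotation noise. Passing tests
therefore demonstrate the *mechanics* of the pipeline (exact transfer,
correct gradients, the data-starvation/transfer interaction) on corpora
with known structure — not clinical-grade accuracy on real reports.

## Preprocessing

Sentence splitting is period-based (the generator guarantees unambiguous
periods). Segmentation: templated reports return the liver-labelled block
whole; free-text reports keep sentences containing a liver term, or a
dependent term whose most recent anatomical anchor is a liver term. The
anchor rule requires recognising *non-liver* anchors too, so the lexicon
carries an `other_terms` field alongside `liver_terms` and
`dependent_terms`; "most recent mention wins" is the simplest rule
consistent with attributing later lesion sentences to the liver.

Cleaning order is fixed and deliberate: lowercase → date/time regex →
blacklist-phrase removal → tokenise → stop-word removal → frequency
threshold. Frequencies are counted *after* stop-word removal and date
tokenisation, and the threshold's scope is the per-domain corpus (domains
are cleaned as separate cohorts). The shipped stop-word list is a static
snapshot of the standard English list so results cannot drift with library
versions. The date dialect covers `mm/dd/yyyy`, `m/d/yy`, ISO dates and
`hh:mm[:ss] [am|pm]`. The frequency default is 50 for realistic corpus
sizes; the experiment pipeline uses 2 because synthetic corpora are small.

## Word embeddings

Skipgram with hierarchical softmax, implemented in numpy with a
numba-jitted sequential inner loop. Defaults: dim 100, window 5 (dynamic
per-position shrink), 10 epochs base / 5 fine-tune, learning rate decaying
linearly 0.025 → 1e-4, min_count tied to the cleaning threshold. Training
is single-worker and bit-reproducible for a given seed; the window shrink
uses an internal 64-bit LCG so no global RNG state is involved.

Transfer initialisation copies shared-vocabulary rows bitwise (this
exactness is asserted, not approximate), initialises new rows from
uniform(−0.5/d, 0.5/d), and rebuilds the hierarchical-softmax tree from
target-corpus frequencies with fresh internal weights. All rows remain
trainable during fine-tuning with a single global learning rate; freezing
the copied rows is available as an ablation flag but is not the default,
since continued training of the whole table is the more natural reading of
fine-tuning.

## Masked language model

A deliberately small pre-LayerNorm transformer (2 layers, hidden 128,
2 heads, FFN 256, max sequence 128, ReLU FFN) over a byte-pair subword
vocabulary (cap 2000 units; merge ties break lexicographically, so the
tokenizer is deterministic). Masking is 15% of positions with the standard
80/10/10 mask/random/keep policy; loss is cross-entropy on masked
positions; optimisation is Adam at 1e-3. Forward and backward passes are
hand-written numpy (float64) and verified against central finite
differences. Held-out loss is evaluated with masks drawn from a fixed seed
so before/after comparisons use identical masks.

Transfer for subword models cannot copy "word vectors" — words are split
into units — so the whole weight set plus the subword vocabulary is reused
and only genuinely novel units (new characters in the target corpus) get
appended random rows. This full-weight-reuse interpretation is the
module's principal design decision. The small size is intentional: the
phenomenon of interest is that a context-dependent model underperforms
context-independent embeddings when corpora are thousands of reports, and
a desk-scale transformer reproduces that regime honestly.

## Classifiers

Random Forest: 200 trees, unlimited depth, sqrt features (scikit-learn,
fixed seed). CNN: embedding (pad index 0 frozen at zero) → 64 filters of
width 5 → ReLU → global max pool → dropout 0.5 → dense → sigmoid; Adam at
3e-3 for 30 epochs, batch 32, float64. The CNN training length was set so
the model reliably leaves the majority-class solution at the small
labelled-set sizes the study design imposes; with far fewer epochs it
predicts one class and comparisons become vacuous. No class re-weighting
by default (imbalance effects are part of the phenomenon; a flag exists).
Decision threshold 0.5. The embedding-initialisation contract — table
equals the supplied word-vector table exactly at step 0, all layers
trainable — is asserted bitwise.

Evaluation computes per-class precision/recall/f1 from the confusion
matrix directly and weighted f1 as the support-weighted mean; scikit-learn
serves as an independent cross-check in tests, never as the
implementation.

## Experiments

Four settings: {target-scratch, target-finetuned-from-source} × two
evaluation domains. Classifiers train on a stratified 80/20 templated
split (split seed recorded); untemplated reports are test-only. Each cell
runs over 5 replicate seeds with mean±sd reporting — the replicate layer is
an extension (single numbers hide variance) and is what makes the
stochastic trend checks meaningful. The default benchmark is 3000 source
reports vs 300 target reports at vocabulary overlap 0.6; the masked-LM arm
of the benchmark runs the scratch setting (the family comparison needs no
more), keeping the whole benchmark under ~4 minutes on one CPU. The
reproducibility check runs a moderate two-seed factorial twice rather than
the full benchmark — determinism does not depend on scale.

## Interpretation

Heatmap weights are L2 norms over the embedding dimension of the loss
gradient per token *occurrence* (repeated tokens get positional weights),
normalised to [0, 1] per report; pad positions are forced to zero. The
derivative is taken at the predicted label (the question of interest is
"what drove this decision"); the true label is an alternative the API
could expose but does not. Projections use t-SNE with perplexity
min(30, (N−1)/3), 1000 iterations, PCA initialisation and a fixed seed;
outputs are CSV/PNG-friendly so everything runs headless.

## Known limitations

- The generator's vocabulary is token-synthetic (`finding123`); semantic
  structure exists only through co-occurrence, so lexical-semantics claims
  beyond clustering should not be read into it.
- The masked LM is far below production scale by design; its absolute
  numbers characterise the small-corpus regime only.
- Skipgram determinism holds for the single-worker trainer; a
  multi-worker mode would trade it away.
- Segmentation targets the generator's dialect plus common liver-imaging
  anatomy; real reports would need a richer lexicon and a sentence
  splitter tolerant of abbreviations.
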