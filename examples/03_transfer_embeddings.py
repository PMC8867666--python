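"""Train domain embeddings and transfer them across domains.

Trains a skipgram/hierarchical-softmax model on the large source domain,
initialises a target-domain model by copying every shared-vocabulary vector
bitwise, fine-tunes it on the small target corpus, and shows (a) the copied
fraction, (b) that class-signal synonyms cluster more tightly than random
token pairs — the geometric property the downstream classifiers exploit.
"""

import itertools
from collections import Counter

import numpy as np

from xferlang import (SyntheticConfig, finetune, generate_corpus,
                      prepare_corpora, train_skipgram, transfer_initialize)
from xferlang.reports import MALIGNANT_TOKENS

reports, _ = generate_corpus(
    SyntheticConfig(n_reports={"us": 1000, "mr": 300}, seed=2))
corpora = prepare_corpora(reports)

source = train_skipgram(corpora["us"], dim=100, epochs=10, seed=0, domain="us")
counts = Counter(t for r in corpora["mr"] for t in r.tokens)
init = transfer_initialize(source, counts, dim=100, seed=0, domain="mr")
model = finetune(init, corpora["mr"], epochs=5, seed=0)

shared = [t for t in model.vocab if t in source.vocab]
print(f"source vocab {len(source.vocab)}, target vocab {len(model.vocab)}, "
      f"copied {len(shared)} shared vectors "
      f"({len(shared) / len(model.vocab):.2f} of the target vocabulary)")


def cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


group = [t for t in MALIGNANT_TOKENS if t in model.vocab]
within = np.mean([cos(model[a], model[b])
                  for a, b in itertools.combinations(group, 2)])
toks = list(model.vocab)
rng = np.random.default_rng(0)
rand = np.mean([cos(model[toks[i]], model[toks[j]])
                for i, j in zip(rng.integers(0, len(toks), 500),
                                rng.integers(0, len(toks), 500)) if i != j])
print(f"mean cosine within the malignant-signal group: {within:.3f}; "
      f"random token pairs: {rand:.3f} "
      "(higher within-group = semantically clustered space)")
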