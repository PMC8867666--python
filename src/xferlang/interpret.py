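"""Model inspection: gradient sensitivity heatmaps and 2-D projections.

The heatmap assigns each token of a report a non-negative weight: the L2
norm of the gradient of the classification loss (taken at the predicted
label) with respect to that token occurrence's embedding vector, normalised
to [0, 1] per report.  Projections reduce vocabulary vectors or mean report
vectors to two dimensions with t-SNE for qualitative reading of the language
space (domain overlap, new-vs-common words, class and style separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .classify import BENIGN, MALIGNANT, ClassifierModel, encode_sequences
from .preprocess import TokenizedReport
from .w2v import ReportVector, WordEmbeddingModel

__all__ = [
    "TokenHeatmap",
    "Projection2D",
    "sensitivity_heatmap",
    "project_vocab",
    "project_reports",
    "label_separation",
    "write_heatmap_csv",
    "write_heatmap_html",
]

PAD_TOKEN = "<pad>"


@dataclass(frozen=True)
class TokenHeatmap:
    """Per-position token weights of one report (pad positions weigh 0)."""
    report_id: str
    tokens: tuple[str, ...]
    weights: np.ndarray
    predicted_label: str
    true_label: str | None

    def __post_init__(self):
        if len(self.tokens) != len(self.weights):
            raise ValueError("one weight per token required")


def sensitivity_heatmap(model: ClassifierModel,
                        report: TokenizedReport | Sequence[str],
                        ) -> TokenHeatmap:
    """Gradient sensitivity of the CNN's predicted-label loss per token.

    Each token occurrence gets its own weight (positional); weights are
    normalised to [0, 1] by the report maximum.  Only CNN classifiers carry
    input gradients; vector-based models are rejected.
    """
    if model.kind == "rf":
        raise ValueError("sensitivity heatmaps require a CNN classifier, "
                         "not a vector-based Random Forest")
    if isinstance(report, TokenizedReport):
        tokens, rid, true_label = report.tokens, report.report_id, report.label
    else:
        tokens, rid, true_label = tuple(report), "", None
    seq = encode_sequences([tokens], model.vocab,
                           model.hyperparams.max_len)[0]
    prob = model.fitted.predict_proba(seq[None, :])[0]
    target = 1 if prob >= model.threshold else 0
    grad = model.fitted.input_gradient(seq, target)       # (L, d)
    weights = np.linalg.norm(grad, axis=1)
    weights[seq == 0] = 0.0
    m = weights.max()
    if m > 0:
        weights = weights / m
    inv = {i + 1: t for t, i in model.vocab.items()}
    shown = tuple(inv.get(int(i), PAD_TOKEN) for i in seq)
    return TokenHeatmap(report_id=rid, tokens=shown, weights=weights,
                        predicted_label=MALIGNANT if target else BENIGN,
                        true_label=true_label)


def write_heatmap_csv(heatmap: TokenHeatmap, path: str | Path) -> None:
    pd.DataFrame({
        "report_id": heatmap.report_id,
        "position": np.arange(len(heatmap.tokens)),
        "token": heatmap.tokens,
        "weight": heatmap.weights,
    }).to_csv(path, index=False, float_format="%.6f")


def write_heatmap_html(heatmap: TokenHeatmap, path: str | Path) -> None:
    """Blue-shaded token view; darker means more weight."""
    spans = []
    for tok, w in zip(heatmap.tokens, heatmap.weights):
        if tok == PAD_TOKEN:
            continue
        alpha = float(w)
        spans.append(
            f'<span style="background-color: rgba(30,80,200,{alpha:.3f})">'
            f"{tok}</span>")
    body = (f"<p>report {heatmap.report_id}: predicted "
            f"{heatmap.predicted_label}, true {heatmap.true_label}</p>"
            f"<p>{' '.join(spans)}</p>")
    Path(path).write_text(f"<html><body>{body}</body></html>")


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Projection2D:
    ids: tuple[str, ...]
    coordinates: np.ndarray          # N x 2
    method_meta: dict
    tags: dict = field(default_factory=dict)   # tag name -> tuple per point

    def __post_init__(self):
        if self.coordinates.shape != (len(self.ids), 2):
            raise ValueError("one 2-D point per id required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids,
                           "x": self.coordinates[:, 0],
                           "y": self.coordinates[:, 1]})
        for name, values in self.tags.items():
            df[name] = values
        return df


def _tsne(X: np.ndarray, perplexity: float, seed: int,
          max_iter: int) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a t-SNE layout")
    perplexity = min(perplexity, (n - 1) / 3)
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              max_iter=max_iter, init="pca")
    return ts.fit_transform(np.asarray(X, dtype=np.float64)), perplexity


def project_vocab(models: WordEmbeddingModel | Sequence[WordEmbeddingModel],
                  perplexity: float = 30.0, seed: int = 0,
                  max_iter: int = 1000) -> Projection2D:
    """2-D t-SNE layout of vocabulary vectors.

    With one model, every vocabulary token becomes a point.  With a pair
    ``(base, finetuned)`` the finetuned model's vocabulary is laid out and
    each point is tagged ``common`` (also in the base vocabulary) or ``new``
    (learned only in the finetuned space), mirroring the overlap reading of
    transferred language spaces.
    """
    if isinstance(models, WordEmbeddingModel):
        models = (models,)
    if len(models) not in (1, 2):
        raise ValueError("project_vocab takes one model or a (base, finetuned) pair")
    if len({m.dim for m in models}) != 1:
        raise ValueError("models must share embedding dimension")
    plot_model = models[-1]
    tokens = sorted(plot_model.vocab, key=plot_model.vocab.get)
    X = plot_model.vectors[[plot_model.vocab[t] for t in tokens]]
    coords, eff_perp = _tsne(X, perplexity, seed, max_iter)
    tags = {"domain": tuple([plot_model.provenance.get("domain", "")] * len(tokens))}
    if len(models) == 2:
        base = models[0]
        tags["status"] = tuple("common" if t in base.vocab else "new"
                               for t in tokens)
    return Projection2D(ids=tuple(tokens), coordinates=coords,
                        method_meta={"method": "tsne", "perplexity": eff_perp,
                                     "seed": seed, "max_iter": max_iter},
                        tags=tags)


def project_reports(vectors: Sequence[ReportVector],
                    styles: Mapping[str, str] | None = None,
                    perplexity: float = 30.0, seed: int = 0,
                    max_iter: int = 1000) -> Projection2D:
    """One 2-D point per report, tagged by label (and style when known)."""
    if not vectors:
        raise ValueError("no report vectors to project")
    dims = {v.values.shape[0] for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"inconsistent vector dimensions: {dims}")
    X = np.stack([v.values for v in vectors])
    coords, eff_perp = _tsne(X, perplexity, seed, max_iter)
    tags = {"label": tuple(v.label or "" for v in vectors)}
    if styles is not None:
        tags["style"] = tuple(styles.get(v.report_id, "") for v in vectors)
    return Projection2D(ids=tuple(v.report_id for v in vectors),
                        coordinates=coords,
                        method_meta={"method": "tsne", "perplexity": eff_perp,
                                     "seed": seed, "max_iter": max_iter},
                        tags=tags)


def label_separation(vectors: Sequence[ReportVector]) -> float:
    """Mean silhouette of malignant-vs-benign report vectors (higher means
    the classes are better separated in the language space)."""
    labels = [v.label for v in vectors]
    if len(set(labels)) < 2:
        raise ValueError("need both classes for a separation score")
    X = np.stack([v.values for v in vectors])
    return float(silhouette_score(X, labels))
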