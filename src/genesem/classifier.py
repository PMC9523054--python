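"""Functional-category classification of gene families from their embeddings.

A four-layer feed-forward network maps a k-dimensional gene embedding to a
softmax over functional categories: hidden layers of sizes 256, 128 and 64
with ReLU activations and dropout 0.2 (training only), trained with Adam on
categorical cross-entropy for 20 epochs. The predicted category is the
argmax of the softmax output.

Predictions for unannotated (hypothetical) families are reliability-weighted:
the raw softmax score is multiplied by the per-category AUPR measured in
cross-validation, and a prediction is kept as reliable when the weighted
score reaches t = 0.9 or the raw score alone reaches t' = 0.99.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .corpus import ANNOTATED, HYPOTHETICAL, Corpus
from .embedding import EmbeddingModel

logger = logging.getLogger(__name__)

OTHER = "Other"


class SchemeError(ValueError):
    pass


class MissingEmbeddingError(ValueError):
    pass


class MissingAUPRError(KeyError):
    pass


# -- category scheme ----------------------------------------------------------

@dataclass
class CategoryScheme:
    """Token -> functional category mapping over annotated tokens.

    ``categories`` is the ordered label list (the retained set C*, plus
    "Other" when built from a KO hierarchy table); argmax ties are broken by
    this order.
    """

    categories: list[str]
    token_to_category: dict[str, str]
    min_appearances: int = 80
    other_sample_size: int = 20
    other_min_appearances: int = 50
    seed: int = 0

    def labeled_tokens(self) -> list[str]:
        return sorted(self.token_to_category)


def build_category_scheme(
    ko_category_table: pd.DataFrame,
    corpus: Corpus,
    min_appearances: int = 80,
    other_sample_size: int = 20,
    other_min_appearances: int = 50,
    include: Optional[Sequence[str]] = None,
    priority: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> CategoryScheme:
    """Select the retained category set C* and build the token labeling.

    Categories with strictly more than ``min_appearances`` KO-words in the
    corpus (optionally intersected with an explicit ``include`` list) form
    C*. KOs listed under several categories are resolved by the ``priority``
    list (first match wins; default priority is table order). Excluded
    categories with more than ``other_min_appearances`` KO-words each
    contribute ``other_sample_size`` randomly sampled KOs to an "Other"
    category.
    """
    need = {"ko", "category"}
    if not need <= set(ko_category_table.columns):
        raise SchemeError(f"ko_category_table needs columns {sorted(need)}")

    cat_order = list(dict.fromkeys(ko_category_table["category"]))
    prio = list(priority) if priority is not None else cat_order
    rank = {c: i for i, c in enumerate(prio)}

    ko_cats: dict[str, list[str]] = {}
    for ko, cat in zip(ko_category_table["ko"], ko_category_table["category"]):
        ko_cats.setdefault(str(ko), []).append(str(cat))
    ko_to_cat = {
        ko: min(cats, key=lambda c: rank.get(c, len(rank)))
        for ko, cats in ko_cats.items()
    }

    # KO-words present in the corpus, grouped by resolved category
    words_by_cat: dict[str, list[str]] = {}
    for tok, g in corpus.vocabulary.items():
        if g.namespace != ANNOTATED or g.ko_label is None:
            continue
        cat = ko_to_cat.get(g.ko_label)
        if cat is not None:
            words_by_cat.setdefault(cat, []).append(tok)

    appearances = {c: len(ws) for c, ws in words_by_cat.items()}
    retained = [
        c for c in cat_order
        if appearances.get(c, 0) > min_appearances and (include is None or c in include)
    ]
    if not retained:
        raise SchemeError("no category passes the min_appearances cut (C* empty)")

    token_to_category: dict[str, str] = {}
    for c in retained:
        for tok in words_by_cat[c]:
            token_to_category[tok] = c

    rng = np.random.default_rng(seed)
    excluded = [c for c in cat_order if c not in retained]
    other_words = 0
    for c in excluded:
        if appearances.get(c, 0) <= other_min_appearances:
            continue
        kos = sorted({corpus.vocabulary[t].ko_label for t in words_by_cat[c]})
        take = min(other_sample_size, len(kos))
        chosen = set(rng.choice(len(kos), size=take, replace=False).tolist())
        chosen_kos = {kos[i] for i in chosen}
        for tok in words_by_cat[c]:
            if corpus.vocabulary[tok].ko_label in chosen_kos:
                token_to_category[tok] = OTHER
                other_words += 1

    categories = retained + ([OTHER] if other_words else [])
    return CategoryScheme(
        categories=categories,
        token_to_category=token_to_category,
        min_appearances=min_appearances,
        other_sample_size=other_sample_size,
        other_min_appearances=other_min_appearances,
        seed=seed,
    )


def scheme_from_truth(truth_tokens: pd.DataFrame, include_background: bool = False) -> CategoryScheme:
    """Category scheme straight from a synthetic truth table (system tokens only
    unless ``include_background``)."""
    sub = truth_tokens if include_background else truth_tokens[truth_tokens["system_id"] != ""]
    mapping = dict(zip(sub["token"], sub["category"]))
    categories = sorted(set(mapping.values()))
    return CategoryScheme(categories=categories, token_to_category=mapping)


# -- feed-forward network -----------------------------------------------------

@dataclass
class ClassifierModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_sizes: tuple[int, ...]
    dropout: float
    categories: list[str]
    epochs: int
    seed: int
    train_losses: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: ClassifierModel, x: np.ndarray, rng: Optional[np.random.Generator] = None):
    """Forward pass; with an rng, inverted dropout is applied to hidden layers."""
    acts = [x]
    h = x
    n_hidden = len(model.weights) - 1
    masks = []
    for i in range(n_hidden):
        h = np.maximum(0.0, h @ model.weights[i] + model.biases[i])
        if rng is not None and model.dropout > 0:
            mask = (rng.random(h.shape) >= model.dropout) / (1.0 - model.dropout)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    logits = h @ model.weights[-1] + model.biases[-1]
    return acts, masks, logits


EmbeddingSource = Union[EmbeddingModel, Mapping[str, np.ndarray]]


def _vector_of(embeddings: EmbeddingSource, token: str) -> Optional[np.ndarray]:
    if isinstance(embeddings, EmbeddingModel):
        if token in embeddings:
            return embeddings.embed(token)
        return None
    return embeddings.get(token)


def train_classifier(
    embeddings: EmbeddingSource,
    scheme: CategoryScheme,
    epochs: int = 20,
    hidden_sizes: tuple[int, ...] = (256, 128, 64),
    dropout: float = 0.2,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> ClassifierModel:
    """Train the feed-forward category classifier on labeled embeddings."""
    tokens = scheme.labeled_tokens()
    missing = [t for t in tokens if _vector_of(embeddings, t) is None]
    if missing:
        raise MissingEmbeddingError(
            f"{len(missing)} labeled tokens lack embeddings, e.g. {missing[:5]}"
        )
    present_cats = sorted({scheme.token_to_category[t] for t in tokens})
    if len(present_cats) < 2:
        raise SchemeError(f"need >= 2 categories with data, found {present_cats}")

    x = np.stack([_vector_of(embeddings, t) for t in tokens]).astype(np.float64)
    cat_index = {c: i for i, c in enumerate(scheme.categories)}
    y = np.array([cat_index[scheme.token_to_category[t]] for t in tokens])
    n, k = x.shape
    n_cat = len(scheme.categories)

    rng = np.random.default_rng(seed)
    sizes = [k, *hidden_sizes, n_cat]
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    model = ClassifierModel(
        weights=weights, biases=biases, hidden_sizes=tuple(hidden_sizes),
        dropout=dropout, categories=list(scheme.categories), epochs=epochs, seed=seed,
    )

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    losses = []
    onehot = np.eye(n_cat)[y]
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = x[idx], onehot[idx]
            acts, masks, logits = _forward(model, xb, rng=rng)
            probs = _softmax(logits)
            ep_loss += float(-np.sum(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12)))

            delta = (probs - yb) / len(idx)
            grads_w, grads_b = [], []
            for layer in range(len(weights) - 1, -1, -1):
                grads_w.append(acts[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = delta @ weights[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)
            grads_w.reverse()
            grads_b.reverse()

            step += 1
            for i in range(len(weights)):
                m_w[i] = b1 * m_w[i] + (1 - b1) * grads_w[i]
                v_w[i] = b2 * v_w[i] + (1 - b2) * grads_w[i] ** 2
                m_b[i] = b1 * m_b[i] + (1 - b1) * grads_b[i]
                v_b[i] = b2 * v_b[i] + (1 - b2) * grads_b[i] ** 2
                mw_hat = m_w[i] / (1 - b1 ** step)
                vw_hat = v_w[i] / (1 - b2 ** step)
                mb_hat = m_b[i] / (1 - b1 ** step)
                vb_hat = v_b[i] / (1 - b2 ** step)
                weights[i] -= learning_rate * mw_hat / (np.sqrt(vw_hat) + eps)
                biases[i] -= learning_rate * mb_hat / (np.sqrt(vb_hat) + eps)
        losses.append(ep_loss / n)
    model.train_losses = np.asarray(losses)
    return model


def predict(model: ClassifierModel, embeddings: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Score tokens (dropout off); returns one row per token.

    Columns: token, predicted_category, raw_score, then one ``score_<cat>``
    column per category. Argmax ties are broken by category order.
    """
    tokens = list(embeddings)
    if not tokens:
        cols = ["token", "predicted_category", "raw_score"] + [f"score_{c}" for c in model.categories]
        return pd.DataFrame(columns=cols)
    x = np.stack([np.asarray(embeddings[t], dtype=np.float64) for t in tokens])
    if x.shape[1] != model.input_dim:
        raise ValueError(f"embedding dim {x.shape[1]} != model input dim {model.input_dim}")
    _, _, logits = _forward(model, x)
    probs = _softmax(logits)
    pred_idx = probs.argmax(axis=1)  # first max wins -> category-order tie break
    out = pd.DataFrame(
        {
            "token": tokens,
            "predicted_category": [model.categories[i] for i in pred_idx],
            "raw_score": probs[np.arange(len(tokens)), pred_idx],
        }
    )
    for j, c in enumerate(model.categories):
        out[f"score_{c}"] = probs[:, j]
    return out


# -- reliability weighting ----------------------------------------------------

def score_reliability(
    records: pd.DataFrame,
    aupr_by_category: Mapping[str, float],
    t: float = 0.9,
    t_prime: float = 0.99,
) -> pd.DataFrame:
    """Add weighted_score and reliable columns (weighted = raw x category AUPR)."""
    out = records.copy()
    missing = sorted(set(out["predicted_category"]) - set(aupr_by_category))
    if missing:
        raise MissingAUPRError(f"no AUPR for predicted categories {missing}")
    aupr = out["predicted_category"].map(aupr_by_category).astype(float)
    out["weighted_score"] = out["raw_score"] * aupr
    out["reliable"] = (out["weighted_score"] >= t) | (out["raw_score"] >= t_prime)
    return out


def reliability_filter(
    records: pd.DataFrame,
    aupr_by_category: Mapping[str, float],
    t: float = 0.9,
    t_prime: float = 0.99,
) -> pd.DataFrame:
    """Reliable subset: weighted score >= t, or raw score >= t'."""
    scored = score_reliability(records, aupr_by_category, t=t, t_prime=t_prime)
    return scored[scored["reliable"]].reset_index(drop=True)


def predict_hypotheticals(
    model: ClassifierModel,
    embedding_model: EmbeddingModel,
    corpus: Corpus,
    scheme: CategoryScheme,
    aupr_by_category: Mapping[str, float],
    t: float = 0.9,
    t_prime: float = 0.99,
) -> pd.DataFrame:
    """Score every hypothetical-namespace token that has an embedding.

    Annotated tokens are excluded; hypothetical tokens filtered out of the
    embedding vocabulary are skipped and logged. Returns the full scored
    table (reliable and unreliable rows, flagged).
    """
    hypo = [t_ for t_, g in sorted(corpus.vocabulary.items()) if g.namespace == HYPOTHETICAL]
    present = [t_ for t_ in hypo if t_ in embedding_model]
    skipped = len(hypo) - len(present)
    if skipped:
        logger.info("predict_hypotheticals: %d hypothetical tokens lack embeddings, skipped", skipped)
    records = predict(model, {t_: embedding_model.embed(t_) for t_ in present})
    if records.empty:
        records["weighted_score"] = pd.Series(dtype=float)
        records["reliable"] = pd.Series(dtype=bool)
        return records
    return score_reliability(records, aupr_by_category, t=t, t_prime=t_prime)
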