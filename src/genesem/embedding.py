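"""Skip-gram negative-sampling (SGNS) embeddings over gene sentences.

Each gene family g_i is mapped to a k-dimensional vector f(g_i) by training
a single-hidden-layer skip-gram network to predict the families occurring
within a symmetric window of w positions around g_i on the same contig.
The softmax over the vocabulary is replaced by the negative-sampling
objective: for a (center, context) pair the model maximizes

    log sigma(u_ctx . v_center) + sum_{n in noise} log sigma(-u_n . v_center)

with noise families drawn from the unigram distribution raised to the 3/4
power. f(g_i) is row i of the input weight matrix (equivalently W^T applied
to the one-hot vector of g_i); the output (context) matrix is kept only for
reproducibility.

The training loop is a numba-compiled kernel with an explicit MINSTD linear
congruential RNG, so the compiled and pure-Python execution paths are
bit-identical and runs are deterministic given (seed, single thread).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import Corpus

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            f.py_func = f
            return f

        if args and callable(args[0]):
            return wrap(args[0])
        return wrap


class OOVError(KeyError):
    """Token not present in the embedding vocabulary."""


class CannotTrainError(ValueError):
    """Corpus too small to train on (vocabulary of size < 2)."""


class InvalidParameterError(ValueError):
    pass


# -- closed-form SGNS loss and gradients (used by tests as well) --------------

def log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(sigma(x))."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def sgns_pair_loss(v_center: np.ndarray, u_context: np.ndarray, u_negatives: np.ndarray) -> float:
    """Negative log-likelihood of one (center, context) pair with fixed noise draws."""
    pos = log_sigmoid(float(u_context @ v_center))
    neg = log_sigmoid(-(u_negatives @ v_center)).sum() if len(u_negatives) else 0.0
    return float(-(pos + neg))


def sgns_pair_gradients(
    v_center: np.ndarray, u_context: np.ndarray, u_negatives: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sgns_pair_loss` w.r.t. its three arguments."""
    s_pos = 1.0 / (1.0 + math.exp(-float(u_context @ v_center)))
    g_v = (s_pos - 1.0) * u_context
    g_ctx = (s_pos - 1.0) * v_center
    if len(u_negatives):
        s_neg = 1.0 / (1.0 + np.exp(-(u_negatives @ v_center)))  # sigma(u_n . v)
        g_v = g_v + s_neg @ u_negatives
        g_neg = np.outer(s_neg, v_center)
    else:
        g_neg = np.zeros((0, v_center.shape[0]))
    return g_v, g_ctx, g_neg


# -- training kernel ----------------------------------------------------------

_MINSTD_M = 2147483647  # 2^31 - 1
_MINSTD_A = 48271


@njit(cache=False)
def _sgns_kernel(tokens, offsets, w_in, w_out, window, negatives, noise_table,
                 alpha0, alpha_min, epochs, seed):
    """In-place SGD over all (center, context) pairs; returns mean loss per epoch.

    Deterministic: fixed symmetric window, sentences in order, MINSTD RNG.
    """
    k = w_in.shape[1]
    n_sent = offsets.shape[0] - 1
    table_size = noise_table.shape[0]

    total_pairs = 0
    for s in range(n_sent):
        length = offsets[s + 1] - offsets[s]
        for i in range(length):
            lo = i - window
            if lo < 0:
                lo = 0
            hi = i + window
            if hi > length - 1:
                hi = length - 1
            total_pairs += hi - lo
    total_updates = total_pairs * epochs
    if total_updates == 0:
        return np.zeros(epochs)

    state = np.int64(seed % (_MINSTD_M - 1) + 1)
    losses = np.zeros(epochs)
    grad_v = np.zeros(k)
    processed = 0
    for ep in range(epochs):
        ep_loss = 0.0
        for s in range(n_sent):
            start = offsets[s]
            length = offsets[s + 1] - offsets[s]
            for i in range(length):
                center = tokens[start + i]
                lo = i - window
                if lo < 0:
                    lo = 0
                hi = i + window
                if hi > length - 1:
                    hi = length - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    context = tokens[start + j]
                    alpha = alpha0 * (1.0 - processed / total_updates)
                    if alpha < alpha_min:
                        alpha = alpha_min
                    processed += 1

                    for d in range(k):
                        grad_v[d] = 0.0
                    pair_loss = 0.0
                    # positive + `negatives` noise contrasts
                    for contrast in range(negatives + 1):
                        if contrast == 0:
                            target = context
                            label = 1.0
                        else:
                            state = (state * _MINSTD_A) % _MINSTD_M
                            target = noise_table[state % table_size]
                            label = 0.0
                        dot = 0.0
                        for d in range(k):
                            dot += w_in[center, d] * w_out[target, d]
                        if dot > 30.0:
                            sig = 1.0
                        elif dot < -30.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + math.exp(-dot))
                        if label > 0.5:
                            pair_loss -= math.log(sig + 1e-12)
                        else:
                            pair_loss -= math.log(1.0 - sig + 1e-12)
                        g = (label - sig) * alpha
                        for d in range(k):
                            grad_v[d] += g * w_out[target, d]
                            w_out[target, d] += g * w_in[center, d]
                    for d in range(k):
                        w_in[center, d] += grad_v[d]
                    ep_loss += pair_loss
        losses[ep] = ep_loss / total_pairs
    return losses


def build_noise_table(counts: np.ndarray, table_size: int = 1_000_000, power: float = 0.75) -> np.ndarray:
    """Unigram^power sampling table (word2vec style deterministic fill)."""
    weights = np.asarray(counts, dtype=np.float64) ** power
    cum = np.cumsum(weights)
    cum /= cum[-1]
    positions = (np.arange(table_size) + 0.5) / table_size
    return np.searchsorted(cum, positions).astype(np.int32)


@dataclass
class EmbeddingModel:
    """Trained SGNS model: input (embedding) and output (context) matrices."""

    input_matrix: np.ndarray
    output_matrix: np.ndarray
    window: int
    dim: int
    negatives: int
    vocab_order: list[str]
    seed: int
    epoch_losses: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.index = {tok: i for i, tok in enumerate(self.vocab_order)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def embed(self, token: str) -> np.ndarray:
        return embed(self, token)


def encode_corpus(corpus: Corpus, vocab_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Flatten sentences (length >= 2) into int32 token ids + sentence offsets."""
    index = {tok: i for i, tok in enumerate(vocab_order)}
    flat: list[int] = []
    offsets = [0]
    for s in corpus.sentences:
        if len(s.tokens) < 2:
            continue
        flat.extend(index[t] for t in s.tokens)
        offsets.append(len(flat))
    return np.asarray(flat, dtype=np.int32), np.asarray(offsets, dtype=np.int64)


def vocab_ordering(corpus: Corpus) -> list[str]:
    """Deterministic vocabulary order: count descending, token id ascending."""
    return sorted(corpus.vocabulary, key=lambda t: (-corpus.vocabulary[t].count, t))


def train_embeddings(
    corpus: Corpus,
    window: int = 5,
    dim: int = 300,
    negatives: int = 5,
    epochs: int = 5,
    alpha: float = 0.025,
    alpha_min: float = 1e-4,
    seed: int = 0,
    table_size: int = 1_000_000,
    compiled: bool = True,
) -> EmbeddingModel:
    """Train SGNS embeddings on a tokenized corpus.

    ``compiled=False`` runs the identical kernel through its pure-Python path
    (useful for tiny corpora and for verifying the compiled path bit-for-bit).
    """
    if dim < 1:
        raise InvalidParameterError(f"dim must be >= 1, got {dim}")
    if window < 1:
        raise InvalidParameterError(f"window must be >= 1, got {window}")
    order = vocab_ordering(corpus)
    if len(order) < 2:
        raise CannotTrainError(f"vocabulary of size {len(order)} < 2")

    counts = np.array([corpus.vocabulary[t].count for t in order], dtype=np.float64)
    tokens, offsets = encode_corpus(corpus, order)
    if tokens.size == 0:
        raise CannotTrainError("no sentence of length >= 2 to train on")
    noise_table = build_noise_table(counts, table_size=table_size)

    rng = np.random.default_rng(seed)
    w_in = ((rng.random((len(order), dim)) - 0.5) / dim).astype(np.float64)
    w_out = np.zeros((len(order), dim), dtype=np.float64)

    kernel = _sgns_kernel if (compiled and HAVE_NUMBA) else _sgns_kernel.py_func
    losses = kernel(
        tokens, offsets, w_in, w_out, int(window), int(negatives), noise_table,
        float(alpha), float(alpha_min), int(epochs), int(seed),
    )
    return EmbeddingModel(
        input_matrix=w_in,
        output_matrix=w_out,
        window=window,
        dim=dim,
        negatives=negatives,
        vocab_order=order,
        seed=seed,
        epoch_losses=np.asarray(losses),
    )


# -- queries ------------------------------------------------------------------

def embed(model: EmbeddingModel, token: str) -> np.ndarray:
    """f(g) = the input-matrix row of g; pure lookup."""
    try:
        return model.input_matrix[model.index[token]]
    except KeyError:
        raise OOVError(f"token {token!r} not in embedding vocabulary") from None


def _cosine_to_all(model: EmbeddingModel, vector: np.ndarray) -> np.ndarray:
    mat = model.input_matrix
    norms = np.linalg.norm(mat, axis=1) * (np.linalg.norm(vector) or 1.0)
    norms[norms == 0] = 1.0  # cosine with a zero vector defined as 0
    return (mat @ vector) / norms


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def nearest_neighbors(model: EmbeddingModel, token: str, n: int) -> list[tuple[str, float]]:
    """Top-n tokens by input-vector cosine; query excluded, ties by vocab order."""
    if not (1 <= n < len(model.vocab_order)):
        raise InvalidParameterError(f"n must be in [1, |V|-1], got {n}")
    sims = _cosine_to_all(model, embed(model, token))
    sims[model.index[token]] = -np.inf
    ranked = np.argsort(-sims, kind="stable")[:n]
    return [(model.vocab_order[i], float(sims[i])) for i in ranked]


def analogy(model: EmbeddingModel, a: str, b: str, c: str, n: int) -> list[tuple[str, float]]:
    """Top-n tokens by cosine to (v_b - v_a + v_c), excluding a, b, c."""
    target = embed(model, b) - embed(model, a) + embed(model, c)
    sims = _cosine_to_all(model, target)
    for tok in (a, b, c):
        sims[model.index[tok]] = -np.inf
    n = min(n, len(model.vocab_order) - len({a, b, c}))
    ranked = np.argsort(-sims, kind="stable")[:n]
    return [(model.vocab_order[i], float(sims[i])) for i in ranked]


# -- planted-structure diagnostics --------------------------------------------

def system_cosine_separation(
    model: EmbeddingModel, system_of: dict[str, str]
) -> tuple[float, float]:
    """Mean within-system vs between-system cosine over system tokens in vocab.

    ``system_of`` maps token -> system id ("" or missing = not in a system).
    """
    toks = [t for t, s in system_of.items() if s and t in model.index]
    within, between = [], []
    for i, a in enumerate(toks):
        va = embed(model, a)
        for b in toks[i + 1:]:
            sim = cosine(va, embed(model, b))
            (within if system_of[a] == system_of[b] else between).append(sim)
    mean_within = float(np.mean(within)) if within else float("nan")
    mean_between = float(np.mean(between)) if between else float("nan")
    return mean_within, mean_between
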