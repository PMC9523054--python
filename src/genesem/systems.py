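"""Candidate multi-gene systems from co-occurrence of predicted families.

Families that are frequent in the corpus and share a predicted functional
category are screened for co-occurrence: a binary contig x word incidence
matrix is built (1 iff the word occurs on the contig), pairwise Pearson
correlation between binary columns (the phi coefficient) is computed, and
clusters of highly correlated words — connected components of the graph
whose edges are pairs with r >= threshold — are reported as candidate
systems, ranked by mean within-cluster correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .corpus import Corpus

logger = logging.getLogger(__name__)


@dataclass
class IncidenceMatrix:
    """Binary contig x word presence matrix."""

    matrix: np.ndarray  # n_contigs x m_words, entries in {0, 1}
    contig_ids: list[str]
    word_ids: list[str]
    min_count: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class CandidateSystem:
    members: list[str]
    min_correlation: float
    mean_correlation: float
    supporting_contigs: list[str]  # contigs carrying >= 2 members
    category: str = ""

    @property
    def support(self) -> int:
        return len(self.supporting_contigs)


def build_incidence(
    corpus: Corpus,
    predictions: pd.DataFrame,
    category: str,
    min_count: int = 1000,
) -> IncidenceMatrix:
    """Incidence matrix over reliable predicted words of one category.

    Columns are the predicted words of ``category`` whose corpus count is
    strictly greater than ``min_count`` (the default presumes a corpus of
    hundreds of millions of genes; scale it down for small corpora).
    Multiplicity is collapsed: an entry is 1 iff the word occurs at least
    once on the contig.
    """
    if "reliable" in predictions.columns:
        predictions = predictions[predictions["reliable"]]
    words = sorted(
        t
        for t in predictions.loc[predictions["predicted_category"] == category, "token"]
        if t in corpus.vocabulary and corpus.vocabulary[t].count > min_count
    )
    if not words:
        logger.warning("build_incidence: no word of category %r exceeds count %d", category, min_count)
    col = {w: j for j, w in enumerate(words)}
    mat = np.zeros((len(corpus.sentences), len(words)), dtype=np.int8)
    for i, s in enumerate(corpus.sentences):
        for t in s.tokens:
            j = col.get(t)
            if j is not None:
                mat[i, j] = 1
    return IncidenceMatrix(matrix=mat, contig_ids=[s.contig_id for s in corpus.sentences],
                           word_ids=words, min_count=min_count)


def correlation_matrix(incidence: IncidenceMatrix) -> tuple[np.ndarray, list[str]]:
    """Phi (Pearson on binary columns) correlation matrix.

    Constant (all-zero or all-one) columns have undefined correlation and
    are dropped with a warning. Returns (matrix, retained word ids).
    """
    mat = incidence.matrix.astype(np.float64)
    keep = [j for j in range(mat.shape[1]) if 0 < mat[:, j].sum() < mat.shape[0]]
    dropped = set(range(mat.shape[1])) - set(keep)
    if dropped:
        logger.warning("correlation_matrix: dropped %d constant columns", len(dropped))
    words = [incidence.word_ids[j] for j in keep]
    if len(keep) < 2:
        return np.ones((len(keep), len(keep))), words
    corr = np.corrcoef(mat[:, keep], rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr, words


def extract_clusters(
    corr: np.ndarray,
    word_ids: Sequence[str],
    threshold: float = 0.8,
    min_cluster_size: int = 3,
    incidence: Optional[IncidenceMatrix] = None,
    category: str = "",
) -> list[CandidateSystem]:
    """Connected components of the r >= threshold graph as candidate systems.

    Component semantics: every member is linked to every other along a
    spanning path of edges with r >= threshold, so the reported minimum
    pairwise correlation (over all member pairs) can fall below the
    threshold for chain-shaped clusters. Candidates are ranked by mean
    within-cluster correlation.
    """
    m = corr.shape[0]
    if m == 0:
        return []
    adj = (corr >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    word_index = {w: j for j, w in enumerate(word_ids)}
    out = []
    for c in range(n_comp):
        members = [word_ids[j] for j in range(m) if labels[j] == c]
        if len(members) < min_cluster_size:
            continue
        idx = [word_index[w] for w in members]
        sub = corr[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(len(idx), k=1)]
        supporting: list[str] = []
        if incidence is not None:
            col = {w: incidence.word_ids.index(w) for w in members}
            counts = incidence.matrix[:, list(col.values())].sum(axis=1)
            supporting = [cid for cid, k in zip(incidence.contig_ids, counts) if k >= 2]
        out.append(
            CandidateSystem(
                members=sorted(members),
                min_correlation=float(pairs.min()),
                mean_correlation=float(pairs.mean()),
                supporting_contigs=supporting,
                category=category,
            )
        )
    out.sort(key=lambda cs: (-cs.mean_correlation, cs.members))
    return out


def candidates_to_frame(candidates: Sequence[CandidateSystem]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": f"cand_{i + 1}",
            "members": ",".join(cs.members),
            "n_members": len(cs.members),
            "mean_correlation": cs.mean_correlation,
            "min_correlation": cs.min_correlation,
            "support": cs.support,
            "category": cs.category,
        }
        for i, cs in enumerate(candidates)
    ]
    cols = ["cluster_id", "members", "n_members", "mean_correlation",
            "min_correlation", "support", "category"]
    return pd.DataFrame(rows, columns=cols)
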