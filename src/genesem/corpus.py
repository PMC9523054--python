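"""Tokenized gene corpus: contigs as sentences, gene families as words.

A corpus is built from a gene-annotation table (one row per predicted gene)
and filtered the way a desk-scale "genomic language" corpus is prepared:
contigs shorter than 10 kbp are discarded, rare gene families (fewer than
24 occurrences) are removed, and ubiquitous families (corpus frequency
above 1e-3) are removed. Annotated families carry KO-subcluster identifiers
of the form ``KXXXXX.YY``; unannotated (hypothetical) families carry
``hypo.clst.ZZZZ`` identifiers.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATED_RE = re.compile(r"^K\d{5}\.\d+$")
HYPOTHETICAL_RE = re.compile(r"^hypo\.clst\.\d+$")

ANNOTATED = "annotated"
HYPOTHETICAL = "hypothetical"


class MalformedInputError(ValueError):
    """Raised when a gene table violates the (contig, position) contract."""


class NamespaceError(ValueError):
    """Raised when a token matches neither the KO nor the hypothetical pattern."""


class InvalidParameterError(ValueError):
    """Raised when a filter parameter is outside its documented domain."""


def token_namespace(token: str) -> str:
    """Classify a token id as annotated (KO subcluster) or hypothetical."""
    if ANNOTATED_RE.match(token):
        return ANNOTATED
    if HYPOTHETICAL_RE.match(token):
        return HYPOTHETICAL
    raise NamespaceError(f"token {token!r} matches neither 'KXXXXX.YY' nor 'hypo.clst.ZZZZ'")


def ko_of(token: str) -> Optional[str]:
    """KO identifier (the KXXXXX part) of an annotated token, else None."""
    if ANNOTATED_RE.match(token):
        return token.split(".", 1)[0]
    return None


@dataclass
class GeneToken:
    """One vocabulary word: a gene family with its corpus count."""

    id: str
    namespace: str
    count: int
    ko_label: Optional[str] = None


@dataclass
class Sentence:
    """One contig: an ordered list of gene-family tokens."""

    contig_id: str
    tokens: list[str]
    length_bp: Optional[int] = None
    group: Optional[str] = None


@dataclass
class Corpus:
    """Ordered sentences plus vocabulary statistics."""

    sentences: list[Sentence] = field(default_factory=list)
    vocabulary: dict[str, GeneToken] = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        return sum(len(s.tokens) for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)

    def recount(self) -> None:
        """Rebuild the vocabulary from the current sentences."""
        counts: Counter[str] = Counter()
        for s in self.sentences:
            counts.update(s.tokens)
        vocab: dict[str, GeneToken] = {}
        for tok, n in counts.items():
            prev = self.vocabulary.get(tok)
            ns = prev.namespace if prev is not None else token_namespace(tok)
            ko = prev.ko_label if prev is not None else ko_of(tok)
            vocab[tok] = GeneToken(id=tok, namespace=ns, count=n, ko_label=ko)
        self.vocabulary = vocab

    def copy(self) -> "Corpus":
        return Corpus(
            sentences=[replace(s, tokens=list(s.tokens)) for s in self.sentences],
            vocabulary={t: replace(g) for t, g in self.vocabulary.items()},
        )


def from_sentences(sentences: Iterable[Sentence]) -> Corpus:
    """Build a corpus (with vocabulary) from ready-made sentences."""
    c = Corpus(sentences=list(sentences))
    c.recount()
    return c


def tokenize(gene_table: pd.DataFrame) -> Corpus:
    """Build a corpus from a gene-annotation table.

    Parameters
    ----------
    gene_table
        One row per gene with columns ``contig_id``, ``position``, ``token``
        and optionally ``length_bp`` and ``group`` (constant per contig).

    Raises
    ------
    MalformedInputError
        If a (contig_id, position) pair occurs twice.
    NamespaceError
        If a token id fits neither namespace pattern.
    """
    required = {"contig_id", "position", "token"}
    missing = required - set(gene_table.columns)
    if missing:
        raise MalformedInputError(f"gene table missing columns: {sorted(missing)}")
    if gene_table.empty:
        return Corpus()
    dup = gene_table.duplicated(subset=["contig_id", "position"])
    if dup.any():
        bad = gene_table.loc[dup, ["contig_id", "position"]].head(5).to_dict("records")
        raise MalformedInputError(f"duplicate (contig, position) pairs, e.g. {bad}")
    for tok in pd.unique(gene_table["token"]):
        token_namespace(str(tok))  # raises NamespaceError on bad ids

    sentences = []
    has_len = "length_bp" in gene_table.columns
    has_group = "group" in gene_table.columns
    # groupby(sort=False) keeps first-appearance contig order
    for contig_id, sub in gene_table.groupby("contig_id", sort=False):
        sub = sub.sort_values("position")
        length_bp = int(sub["length_bp"].iloc[0]) if has_len and pd.notna(sub["length_bp"].iloc[0]) else None
        group = str(sub["group"].iloc[0]) if has_group and pd.notna(sub["group"].iloc[0]) else None
        sentences.append(
            Sentence(
                contig_id=str(contig_id),
                tokens=[str(t) for t in sub["token"]],
                length_bp=length_bp,
                group=group,
            )
        )
    return from_sentences(sentences)


def filter_contigs(corpus: Corpus, min_length_bp: int = 10_000) -> Corpus:
    """Drop sentences whose contig is shorter than ``min_length_bp``.

    Contigs below 10 kbp carry too little context to be informative, so they
    are removed before training. The cut is strict: a contig of exactly
    ``min_length_bp`` is retained. Corpora without length metadata are
    returned unchanged with a logged warning.
    """
    if any(s.length_bp is None for s in corpus.sentences):
        logger.warning("filter_contigs skipped: sentences lack length_bp metadata")
        return corpus.copy()
    out = Corpus(sentences=[replace(s, tokens=list(s.tokens)) for s in corpus.sentences if s.length_bp >= min_length_bp])
    out.vocabulary = dict(corpus.vocabulary)
    out.recount()
    return out


def filter_tokens(corpus: Corpus, min_count: int = 24, max_freq: float = 1e-3) -> Corpus:
    """Remove rare then ubiquitous gene families from the corpus.

    Families with fewer than ``min_count`` occurrences ("at least 24" is
    inclusive, so count 24 survives) are deleted first; frequencies for the
    ubiquity cut are then computed on the min-count-filtered corpus, and
    families with frequency strictly above ``max_freq`` are deleted.
    Removed tokens are deleted in place (remaining tokens close ranks — no
    placeholder), and sentences left with fewer than 2 tokens are dropped,
    since a 1-token sentence yields no context pairs.
    """
    if min_count < 1:
        raise InvalidParameterError(f"min_count must be >= 1, got {min_count}")
    if not (0 < max_freq <= 1):
        raise InvalidParameterError(f"max_freq must be in (0, 1], got {max_freq}")

    sentences = [replace(s, tokens=list(s.tokens)) for s in corpus.sentences]
    # Removing a ubiquitous family shrinks the denominator and dropping short
    # sentences shrinks counts, either of which can push another family over a
    # threshold; iterating to a fixed point makes the filter idempotent.
    while True:
        counts: Counter[str] = Counter()
        for s in sentences:
            counts.update(s.tokens)
        keep = {t for t, n in counts.items() if n >= min_count}
        mid_total = sum(n for t, n in counts.items() if t in keep)
        if mid_total > 0:
            keep = {t for t in keep if counts[t] / mid_total <= max_freq}
        new_sentences = []
        changed = False
        for s in sentences:
            kept = [t for t in s.tokens if t in keep]
            if len(kept) >= 2:
                if len(kept) != len(s.tokens):
                    changed = True
                new_sentences.append(replace(s, tokens=kept))
            elif kept:
                changed = True  # dropped sentence still carried counts
        sentences = new_sentences
        if not changed:
            break
    out = Corpus(sentences=sentences)
    out.vocabulary = dict(corpus.vocabulary)
    out.recount()
    return out


def vocab_report(corpus: Corpus) -> pd.DataFrame:
    """Per-namespace family and gene counts, plus the annotated-family fraction.

    Returns a tidy table with one row per namespace and a ``total`` row;
    columns: namespace, n_families, n_genes, family_fraction.
    """
    rows = []
    by_ns: dict[str, list[GeneToken]] = {ANNOTATED: [], HYPOTHETICAL: []}
    for g in corpus.vocabulary.values():
        by_ns[g.namespace].append(g)
    n_families_total = len(corpus.vocabulary)
    for ns in (ANNOTATED, HYPOTHETICAL):
        toks = by_ns[ns]
        rows.append(
            {
                "namespace": ns,
                "n_families": len(toks),
                "n_genes": sum(t.count for t in toks),
                "family_fraction": (len(toks) / n_families_total) if n_families_total else 0.0,
            }
        )
    rows.append(
        {
            "namespace": "total",
            "n_families": n_families_total,
            "n_genes": corpus.total_genes,
            "family_fraction": 1.0 if n_families_total else 0.0,
        }
    )
    return pd.DataFrame(rows)
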