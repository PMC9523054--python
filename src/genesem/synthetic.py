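"""Synthetic gene corpora with known ground truth.

Emulates the statistical structure of a real microbial corpus at the token
level: contigs are sentences of gene-family tokens; background families
follow a Zipf law (few large families, a long tail); co-functioning genes
are planted as contiguous multi-token blocks ("systems") that recur across
contigs, mirroring operonic organization; a configurable fraction of system
members is relabeled into the hypothetical namespace so that
"predict the function of unannotated genes" is testable against known truth.
No nucleotide or protein sequences are emitted — simulation is purely at the
token level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .corpus import ANNOTATED, HYPOTHETICAL, Corpus, Sentence, from_sentences

BACKGROUND = "background"


class InvalidConfigError(ValueError):
    """Synthetic configuration violates its documented domain."""


@dataclass
class PlantedSystem:
    """A block of co-occurring tokens planted into contigs.

    insertion_rate is the fraction of contigs carrying the block; when
    ``contiguous`` the block is inserted unbroken (operon-like), otherwise
    its members are scattered across the contig.
    """

    token_ids: list[str]
    category_label: str
    insertion_rate: float = 0.2
    contiguous: bool = True
    system_id: str = ""

    def validate(self) -> None:
        if not self.token_ids:
            raise InvalidConfigError("system has no tokens")
        if len(set(self.token_ids)) != len(self.token_ids):
            raise InvalidConfigError(f"system {self.system_id}: duplicate token ids")
        if not (0 < self.insertion_rate <= 1):
            raise InvalidConfigError(
                f"system {self.system_id}: insertion_rate must be in (0, 1]"
            )


@dataclass
class SyntheticConfig:
    n_contigs: int = 2000
    genes_per_contig: tuple[int, int] = (15, 40)
    n_background_families: int = 300
    zipf_exponent: float = 1.2
    systems: list[PlantedSystem] = field(default_factory=list)
    n_categories: int = 5
    group_labels: list[tuple[str, float]] = field(default_factory=lambda: [("g1", 1.0)])
    hypothetical_fraction: float = 0.0
    dropout_rate: float = 0.0
    subclusters_per_ko: int = 1
    bp_per_gene: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise InvalidConfigError("n_contigs must be >= 1")
        lo, hi = self.genes_per_contig
        if not (1 <= lo <= hi):
            raise InvalidConfigError("genes_per_contig must be a non-empty range")
        if self.n_background_families < 1 and not self.systems:
            raise InvalidConfigError("empty vocabulary: no background families and no systems")
        if self.zipf_exponent <= 0:
            raise InvalidConfigError("zipf_exponent must be > 0")
        if not (0 <= self.hypothetical_fraction <= 1):
            raise InvalidConfigError("hypothetical_fraction must be in [0, 1]")
        if not (0 <= self.dropout_rate <= 1):
            raise InvalidConfigError("dropout_rate must be in [0, 1]")
        if abs(sum(p for _, p in self.group_labels) - 1.0) > 1e-9:
            raise InvalidConfigError("group proportions must sum to 1")
        bg = set(background_token_ids(self.n_background_families, self.subclusters_per_ko))
        for sys_ in self.systems:
            sys_.validate()
            clash = bg & set(sys_.token_ids)
            if clash:
                raise InvalidConfigError(
                    f"system {sys_.system_id} tokens collide with background ids: {sorted(clash)[:3]}"
                )


@dataclass
class TruthTable:
    """Ground truth for a synthetic corpus.

    ``tokens``: one row per vocabulary token — token, category ("background"
    for non-system tokens), system_id ("" for background), namespace.
    ``contig_groups``: one row per contig — contig_id, group.
    """

    tokens: pd.DataFrame
    contig_groups: pd.DataFrame

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.tokens["token"], self.tokens["category"]))

    def system_of(self) -> dict[str, str]:
        return dict(zip(self.tokens["token"], self.tokens["system_id"]))

    def write(self, path: gio.PathLike) -> None:
        self.tokens.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read(path: gio.PathLike, contig_groups: Optional[pd.DataFrame] = None) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if contig_groups is None:
            contig_groups = pd.DataFrame(columns=["contig_id", "group"])
        return TruthTable(tokens=df, contig_groups=contig_groups)


def background_token_ids(n_families: int, subclusters_per_ko: int = 1) -> list[str]:
    """Annotated KO-subcluster ids for background families.

    Family ``i`` is subcluster ``i % m`` of KO ``i // m``, so consecutive
    families share a KO when ``subclusters_per_ko > 1`` (used to exercise
    leave-one-KO-out splits). KO numbers stay below 90000; planted-system
    helpers allocate from 90000 up, keeping the namespaces disjoint.
    """
    m = max(1, subclusters_per_ko)
    return [f"K{1 + i // m:05d}.{1 + i % m:02d}" for i in range(n_families)]


def make_systems(
    n_systems: int,
    tokens_per_system: int = 5,
    n_categories: int = 5,
    insertion_rate: float = 0.2,
    contiguous: bool = True,
) -> list[PlantedSystem]:
    """Allocate planted systems with disjoint KO ids (from K90000 up).

    Categories are assigned round-robin: system ``s`` gets category
    ``cat_{s % n_categories}``.
    """
    systems = []
    for s in range(n_systems):
        toks = [f"K{90000 + s * 10 + t:05d}.01" for t in range(tokens_per_system)]
        systems.append(
            PlantedSystem(
                token_ids=toks,
                category_label=f"cat_{s % n_categories}",
                insertion_rate=insertion_rate,
                contiguous=contiguous,
                system_id=f"sys_{s}",
            )
        )
    return systems


def _relabel_hypotheticals(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, str]:
    """Map a fraction of system tokens into the hypothetical namespace."""
    mapping: dict[str, str] = {}
    counter = 1
    for sys_ in config.systems:
        for tok in sys_.token_ids:
            if rng.random() < config.hypothetical_fraction:
                mapping[tok] = f"hypo.clst.{counter:04d}"
                counter += 1
    return mapping


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, TruthTable]:
    """Generate a corpus and its ground truth; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    bg_tokens = background_token_ids(config.n_background_families, config.subclusters_per_ko)
    ranks = np.arange(1, len(bg_tokens) + 1, dtype=np.float64)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum() if len(probs) else 1.0

    hypo_map = _relabel_hypotheticals(config, rng)

    group_names = [g for g, _ in config.group_labels]
    group_probs = np.array([p for _, p in config.group_labels], dtype=np.float64)

    lo, hi = config.genes_per_contig
    sentences: list[Sentence] = []
    for i in range(config.n_contigs):
        n_bg = int(rng.integers(lo, hi + 1))
        if len(bg_tokens):
            toks = [bg_tokens[j] for j in rng.choice(len(bg_tokens), size=n_bg, p=probs)]
        else:
            toks = []
        for sys_ in config.systems:
            if rng.random() >= sys_.insertion_rate:
                continue
            members = [t for t in sys_.token_ids if rng.random() >= config.dropout_rate]
            members = [hypo_map.get(t, t) for t in members]
            if not members:
                continue
            if sys_.contiguous:
                pos = int(rng.integers(0, len(toks) + 1))
                toks = toks[:pos] + members + toks[pos:]
            else:
                for m in members:
                    pos = int(rng.integers(0, len(toks) + 1))
                    toks.insert(pos, m)
        group = group_names[int(rng.choice(len(group_names), p=group_probs))]
        sentences.append(
            Sentence(
                contig_id=f"synctg_{i + 1:05d}",
                tokens=toks,
                length_bp=config.bp_per_gene * max(1, len(toks)),
                group=group,
            )
        )

    corpus = from_sentences(sentences)

    truth_rows = []
    for tok in bg_tokens:
        truth_rows.append(
            {"token": tok, "category": BACKGROUND, "system_id": "", "namespace": ANNOTATED}
        )
    for sys_ in config.systems:
        for tok in sys_.token_ids:
            visible = hypo_map.get(tok, tok)
            truth_rows.append(
                {
                    "token": visible,
                    "category": sys_.category_label,
                    "system_id": sys_.system_id,
                    "namespace": HYPOTHETICAL if visible != tok else ANNOTATED,
                }
            )
    truth = TruthTable(
        tokens=pd.DataFrame(truth_rows, columns=["token", "category", "system_id", "namespace"]),
        contig_groups=pd.DataFrame(
            {"contig_id": [s.contig_id for s in sentences], "group": [s.group for s in sentences]}
        ),
    )
    return corpus, truth


def generate_hit_table(truth: TruthTable, recall: float, seed: int) -> pd.DataFrame:
    """Emit a best-hit table for the homology baseline with a known recall.

    A fraction ``recall`` of annotated queries receive one best hit to a
    same-category subject from a different KO; the remainder receive no row,
    emulating the sensitivity ceiling of sequence search.
    """
    if not (0 <= recall <= 1):
        raise InvalidConfigError(f"recall must be in [0, 1], got {recall}")
    rng = np.random.default_rng(seed)
    annotated = truth.tokens[truth.tokens["namespace"] == ANNOTATED]
    by_cat: dict[str, list[str]] = {
        cat: list(sub["token"]) for cat, sub in annotated.groupby("category")
    }
    rows = []
    for tok, cat in zip(annotated["token"], annotated["category"]):
        if rng.random() >= recall:
            continue
        ko = tok.split(".", 1)[0]
        candidates = [t for t in by_cat[cat] if t.split(".", 1)[0] != ko]
        if not candidates:
            continue
        subject = candidates[int(rng.integers(0, len(candidates)))]
        evalue = 10.0 ** rng.uniform(-30, -4)
        rows.append({"query": tok, "subject": subject, "evalue": evalue})
    return pd.DataFrame(rows, columns=["query", "subject", "evalue"])


def write_outputs(corpus: Corpus, truth: TruthTable, out_dir: gio.PathLike) -> None:
    """Write corpus text, metadata and truth TSV into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_corpus(corpus, out / "corpus.txt", out / "contigs.tsv")
    gio.write_vocab(corpus, out / "vocabulary.tsv")
    truth.write(out / "truth.tsv")
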