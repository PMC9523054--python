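"""Cross-validation schemes, classification metrics and the homology baseline.

Three complementary validation schemes:

* naive k-fold over contigs (embeddings retrained per fold on the training
  contigs only);
* leave-one-taxonomic-group-out — hold out every contig of one taxon to
  measure generalization across evolutionary distance;
* leave-one-KO-out — hold out all subcluster words of one orthologous
  family (embeddings fixed, classifier retrained per fold) to emulate
  encountering a never-seen gene family.

Metrics are one-vs-rest precision-recall curves with step-wise AUPR
(average precision), per-category F1, support-weighted F1, and a confusion
matrix; folds are aggregated by pooling scores (micro-average).

The remote-homology baseline assigns each query the category of its best
(lowest E-value) hit after discarding same-KO self hits and hits with
E-value >= 1e-3; queries with no surviving hit are labeled "no hit".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    precision_recall_curve,
    precision_recall_fscore_support,
)

from .classifier import CategoryScheme, predict, train_classifier
from .corpus import Corpus, from_sentences
from .embedding import EmbeddingModel, train_embeddings

NO_HIT = "no hit"


class SplitError(ValueError):
    pass


@dataclass
class Fold:
    name: str
    train_sentences: list[str] = field(default_factory=list)  # contig ids
    test_sentences: list[str] = field(default_factory=list)
    test_tokens: set[str] = field(default_factory=set)
    train_tokens: list[str] = field(default_factory=list)  # used by leave-one-KO-out


@dataclass
class SplitPlan:
    scheme: str  # kfold_contigs | leave_one_group_out | leave_one_ko_out
    folds: list[Fold]
    seed: int = 0


# -- split construction -------------------------------------------------------

def kfold_split(corpus: Corpus, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition contigs uniformly at random into k folds."""
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    if k > len(corpus.sentences):
        raise SplitError(f"k={k} exceeds number of contigs ({len(corpus.sentences)})")
    rng = np.random.default_rng(seed)
    ids = [s.contig_id for s in corpus.sentences]
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    tokens_by_contig = {s.contig_id: set(s.tokens) for s in corpus.sentences}
    folds = []
    for f, chunk in enumerate(chunks):
        test = [ids[i] for i in sorted(chunk)]
        train = [cid for cid in ids if cid not in set(test)]
        test_tokens = set().union(*(tokens_by_contig[cid] for cid in test)) if test else set()
        folds.append(Fold(name=f"fold_{f}", train_sentences=train, test_sentences=test,
                          test_tokens=test_tokens))
    return SplitPlan(scheme="kfold_contigs", folds=folds, seed=seed)


def leave_one_group_out_split(corpus: Corpus) -> SplitPlan:
    """One fold per taxonomy group: test = that group's contigs."""
    missing = [s.contig_id for s in corpus.sentences if s.group is None]
    if missing:
        raise SplitError(f"{len(missing)} contigs lack a group label, e.g. {missing[:5]}")
    groups = sorted({s.group for s in corpus.sentences})
    if len(groups) < 2:
        raise SplitError(f"need >= 2 groups, found {groups}")
    folds = []
    for g in groups:
        test = [s.contig_id for s in corpus.sentences if s.group == g]
        train = [s.contig_id for s in corpus.sentences if s.group != g]
        test_tokens = set().union(*(set(s.tokens) for s in corpus.sentences if s.group == g))
        folds.append(Fold(name=f"group_{g}", train_sentences=train, test_sentences=test,
                          test_tokens=test_tokens))
    return SplitPlan(scheme="leave_one_group_out", folds=folds)


def leave_one_ko_out_split(scheme: CategoryScheme, vocabulary: Mapping[str, object]) -> SplitPlan:
    """One fold per unique KO; all its subcluster words form the test set."""
    ko_words: dict[str, list[str]] = {}
    for tok in scheme.labeled_tokens():
        g = vocabulary.get(tok)
        ko = getattr(g, "ko_label", None) if g is not None else None
        if ko is None:
            ko = tok.split(".", 1)[0] if tok.startswith("K") else tok
        ko_words.setdefault(ko, []).append(tok)
    folds = []
    all_tokens = set(scheme.labeled_tokens())
    for ko in sorted(ko_words):
        test = set(ko_words[ko])
        folds.append(Fold(name=f"ko_{ko}", test_tokens=test,
                          train_tokens=sorted(all_tokens - test)))
    return SplitPlan(scheme="leave_one_ko_out", folds=folds)


# -- metrics ------------------------------------------------------------------

@dataclass
class EvalReport:
    per_category: pd.DataFrame  # category, precision, recall, f1, aupr, support
    weighted_f1: float
    macro_f1: float
    confusion: pd.DataFrame
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    n_unscorable: int = 0

    @property
    def aupr_by_category(self) -> dict[str, float]:
        return dict(zip(self.per_category["category"], self.per_category["aupr"]))


def evaluate(predictions: pd.DataFrame, truth: Mapping[str, str],
             categories: Optional[Sequence[str]] = None) -> EvalReport:
    """Score pooled predictions against true categories.

    ``predictions`` carries token, predicted_category and one ``score_<cat>``
    column per category (as produced by :func:`genesem.classifier.predict`).
    """
    missing = [t for t in predictions["token"] if t not in truth]
    if missing:
        raise SplitError(f"{len(missing)} predicted tokens lack truth labels, e.g. {missing[:5]}")
    if categories is None:
        categories = [c[len("score_"):] for c in predictions.columns if c.startswith("score_")]
    y_true = np.array([truth[t] for t in predictions["token"]])
    y_pred = predictions["predicted_category"].to_numpy()

    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(categories), zero_division=0
    )
    rows = []
    curves = {}
    for j, cat in enumerate(categories):
        scores = predictions[f"score_{cat}"].to_numpy(dtype=float)
        binary = (y_true == cat).astype(int)
        if binary.any():
            aupr = float(average_precision_score(binary, scores))
            p_curve, r_curve, _ = precision_recall_curve(binary, scores)
        else:
            aupr = float("nan")
            p_curve, r_curve = np.array([]), np.array([])
        curves[cat] = (p_curve, r_curve)
        rows.append({"category": cat, "precision": prec[j], "recall": rec[j],
                     "f1": f1[j], "aupr": aupr, "support": int(support[j])})
    per_category = pd.DataFrame(rows)
    weighted_f1 = float(f1_score(y_true, y_pred, labels=list(categories),
                                 average="weighted", zero_division=0))
    macro_f1 = float(f1_score(y_true, y_pred, labels=list(categories),
                              average="macro", zero_division=0))
    cm = confusion_matrix(y_true, y_pred, labels=list(categories))
    confusion = pd.DataFrame(cm, index=list(categories), columns=list(categories))
    return EvalReport(per_category=per_category, weighted_f1=weighted_f1,
                      macro_f1=macro_f1, confusion=confusion, curves=curves)


# -- cross-validation drivers -------------------------------------------------

def _subcorpus(corpus: Corpus, contig_ids: Sequence[str]) -> Corpus:
    wanted = set(contig_ids)
    return from_sentences([s for s in corpus.sentences if s.contig_id in wanted])


def cross_validate_contigs(
    corpus: Corpus,
    scheme: CategoryScheme,
    plan: SplitPlan,
    embed_params: Optional[dict] = None,
    clf_params: Optional[dict] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, EvalReport, list[EvalReport]]:
    """Run a contig-partitioning CV plan (k-fold or leave-one-group-out).

    Per fold: embeddings retrained on the training contigs, classifier
    trained on labeled tokens present in the training vocabulary, held-out
    labeled tokens scored via their retrained embedding. Tokens absent from
    the training vocabulary are counted as unscorable, not as errors.
    Returns (pooled predictions with a ``fold`` column, pooled report,
    per-fold reports).
    """
    embed_params = dict(embed_params or {})
    clf_params = dict(clf_params or {})
    truth = scheme.token_to_category
    pooled = []
    fold_reports = []
    n_unscorable = 0
    for i, fold in enumerate(plan.folds):
        train_corpus = _subcorpus(corpus, fold.train_sentences)
        emb = train_embeddings(train_corpus, seed=seed + i, **embed_params)
        train_scheme = CategoryScheme(
            categories=list(scheme.categories),
            token_to_category={t: c for t, c in truth.items() if t in emb},
        )
        model = train_classifier(emb, train_scheme, seed=seed + i, **clf_params)
        test_tokens = sorted(t for t in fold.test_tokens if t in truth)
        scorable = [t for t in test_tokens if t in emb]
        n_unscorable += len(test_tokens) - len(scorable)
        if not scorable:
            continue
        recs = predict(model, {t: emb.embed(t) for t in scorable})
        recs.insert(0, "fold", fold.name)
        pooled.append(recs)
        fold_reports.append(evaluate(recs, truth, categories=scheme.categories))
    if not pooled:
        raise SplitError("no scorable test tokens in any fold")
    pooled_df = pd.concat(pooled, ignore_index=True)
    report = evaluate(pooled_df, truth, categories=scheme.categories)
    report.n_unscorable = n_unscorable
    return pooled_df, report, fold_reports


def cross_validate_kos(
    embedding_model: EmbeddingModel,
    scheme: CategoryScheme,
    plan: SplitPlan,
    clf_params: Optional[dict] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, EvalReport]:
    """Leave-one-KO-out: one full-corpus embedding, classifier retrained per fold."""
    clf_params = dict(clf_params or {})
    truth = scheme.token_to_category
    pooled = []
    for i, fold in enumerate(plan.folds):
        train_tokens = [t for t in fold.train_tokens if t in embedding_model]
        fold_scheme = CategoryScheme(
            categories=list(scheme.categories),
            token_to_category={t: truth[t] for t in train_tokens},
        )
        model = train_classifier(embedding_model, fold_scheme, seed=seed, **clf_params)
        scorable = sorted(t for t in fold.test_tokens if t in embedding_model)
        if not scorable:
            continue
        recs = predict(model, {t: embedding_model.embed(t) for t in scorable})
        recs.insert(0, "fold", fold.name)
        pooled.append(recs)
    pooled_df = pd.concat(pooled, ignore_index=True)
    report = evaluate(pooled_df, truth, categories=scheme.categories)
    return pooled_df, report


# -- remote-homology baseline -------------------------------------------------

def best_hit_baseline(
    hit_table: pd.DataFrame,
    scheme: CategoryScheme,
    evalue_threshold: float = 1e-3,
    queries: Optional[Sequence[str]] = None,
    ko_of_token: Optional[Callable[[str], Optional[str]]] = None,
) -> pd.DataFrame:
    """Category assignment by best surviving hit.

    Same-KO ("self") hits are discarded, then hits with E-value >=
    ``evalue_threshold``; each query is assigned the category of its
    minimum-E-value subject (ties broken by subject token order); queries
    with no surviving hit get the category "no hit".
    """
    if ko_of_token is None:
        ko_of_token = lambda t: t.split(".", 1)[0] if t.startswith("K") else None  # noqa: E731
    if queries is None:
        queries = scheme.labeled_tokens()

    df = hit_table.copy()
    bad = [s for s in df["subject"].unique() if ko_of_token(s) is None]
    if bad:
        raise SplitError(f"subjects without KO labels, e.g. {bad[:5]}")
    df["query_ko"] = df["query"].map(ko_of_token)
    df["subject_ko"] = df["subject"].map(ko_of_token)
    df = df[df["subject_ko"] != df["query_ko"]]
    df = df[df["evalue"].astype(float) < evalue_threshold]
    df = df.sort_values(["query", "evalue", "subject"], kind="stable")
    best = df.drop_duplicates(subset="query", keep="first").set_index("query")

    rows = []
    for q in queries:
        if q in best.index:
            subj = best.loc[q, "subject"]
            cat = scheme.token_to_category.get(subj)
            if cat is None:
                raise SplitError(f"best-hit subject {subj!r} has no category in the scheme")
            rows.append({"token": q, "predicted_category": cat,
                         "best_subject": subj, "best_evalue": float(best.loc[q, "evalue"])})
        else:
            rows.append({"token": q, "predicted_category": NO_HIT,
                         "best_subject": "", "best_evalue": float("nan")})
    return pd.DataFrame(rows, columns=["token", "predicted_category", "best_subject", "best_evalue"])
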