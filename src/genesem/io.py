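"""Plain-text file formats shared across the pipeline.

Formats (all tab- or space-separated text):

* corpus text — one contig per line, space-separated tokens
* corpus metadata TSV — contig_id, length_bp, group (aligned with corpus text)
* vocabulary TSV — token, namespace, count, ko
* embedding — word2vec text format: header "<vocab_size> <dim>", then one
  token followed by its coordinates per line
* prediction TSV — token, predicted_category, raw_score, weighted_score,
  reliable, then one score column per category
* hit TSV — query, subject, evalue
* curve TSV — n, mean, lo, hi

Floats are rendered at 6 significant digits so canonical files round-trip
byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .corpus import Corpus, Sentence, from_sentences

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed line in one of the documented text formats."""


def fmt_float(x: float) -> str:
    """Canonical 6-significant-digit float rendering."""
    return format(float(x), ".6g")


# -- corpus text + metadata ---------------------------------------------------

def write_corpus(corpus: Corpus, text_path: PathLike, meta_path: Optional[PathLike] = None) -> None:
    with open(text_path, "w") as fh:
        for s in corpus.sentences:
            fh.write(" ".join(s.tokens) + "\n")
    if meta_path is not None:
        rows = [
            {
                "contig_id": s.contig_id,
                "length_bp": "" if s.length_bp is None else s.length_bp,
                "group": "" if s.group is None else s.group,
            }
            for s in corpus.sentences
        ]
        pd.DataFrame(rows, columns=["contig_id", "length_bp", "group"]).to_csv(
            meta_path, sep="\t", index=False
        )


def read_corpus(text_path: PathLike, meta_path: Optional[PathLike] = None) -> Corpus:
    sentences = []
    with open(text_path) as fh:
        for i, line in enumerate(fh):
            toks = line.split()
            if not toks:
                raise FormatError(f"{text_path}: empty sentence at line {i + 1}")
            sentences.append(Sentence(contig_id=f"contig_{i + 1}", tokens=toks))
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"contig_id": str, "group": str})
        if len(meta) != len(sentences):
            raise FormatError(
                f"{meta_path}: {len(meta)} metadata rows for {len(sentences)} sentences"
            )
        for s, row in zip(sentences, meta.itertuples(index=False)):
            s.contig_id = str(row.contig_id)
            s.length_bp = None if pd.isna(row.length_bp) else int(row.length_bp)
            s.group = None if pd.isna(row.group) else str(row.group)
    return from_sentences(sentences)


# -- vocabulary TSV -----------------------------------------------------------

def write_vocab(corpus: Corpus, path: PathLike) -> None:
    rows = [
        {"token": g.id, "namespace": g.namespace, "count": g.count, "ko": g.ko_label or ""}
        for g in sorted(corpus.vocabulary.values(), key=lambda g: g.id)
    ]
    pd.DataFrame(rows, columns=["token", "namespace", "count", "ko"]).to_csv(path, sep="\t", index=False)


def read_vocab(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"token": str, "namespace": str, "ko": str})
    need = {"token", "namespace", "count"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: vocabulary TSV needs columns {sorted(need)}")
    return df


# -- embedding word2vec text format -------------------------------------------

def write_embedding(tokens: list[str], matrix: np.ndarray, path: PathLike) -> None:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
        raise FormatError("embedding matrix shape does not match token list")
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for tok, row in zip(tokens, matrix):
            fh.write(tok + " " + " ".join(fmt_float(x) for x in row) + "\n")


def read_embedding(path: PathLike) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: bad word2vec header at line 1")
        n, k = int(header[0]), int(header[1])
        tokens, rows = [], []
        for i, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != k + 1:
                raise FormatError(f"{path}: expected {k + 1} fields at line {i}, got {len(parts)}")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != n:
        raise FormatError(f"{path}: header promises {n} rows, file has {len(tokens)}")
    return tokens, np.asarray(rows, dtype=np.float64)


# -- prediction / hit / curve TSVs --------------------------------------------

def write_predictions(df: pd.DataFrame, path: PathLike) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(fmt_float)
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"token": str, "predicted_category": str})
    if "token" not in df.columns:
        raise FormatError(f"{path}: prediction TSV needs a 'token' column")
    return df


def write_hit_table(df: pd.DataFrame, path: PathLike) -> None:
    out = df.loc[:, ["query", "subject", "evalue"]].copy()
    out["evalue"] = out["evalue"].map(fmt_float)
    out.to_csv(path, sep="\t", index=False)


def read_hit_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "subject": str})
    need = {"query", "subject", "evalue"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: hit TSV needs columns {sorted(need)}")
    return df


def write_curve(df: pd.DataFrame, path: PathLike) -> None:
    out = df.copy()
    for col in ("mean", "lo", "hi"):
        out[col] = out[col].map(fmt_float)
    out.to_csv(path, sep="\t", index=False)


def read_curve(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"n", "mean", "lo", "hi"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: curve TSV needs columns {sorted(need)}")
    return df
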