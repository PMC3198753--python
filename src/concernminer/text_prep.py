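"""Tokenization and weighted term-document matrix construction.

The semantic space is computed from a sparse term-document matrix. Two
weighting schemes are supported: raw counts, and the log-entropy scheme that
is standard for latent semantic analysis — local weight ``log(1 + tf)`` times
a global weight ``1 - H_t / log D`` where ``H_t`` is the Shannon entropy of
term *t*'s distribution over the ``D`` documents. A term spread uniformly over
every document carries no information and gets global weight 0; a term
concentrated in one document gets weight 1.

No stop list and no stemming are applied here: every surface form in every
document enters the matrix, and context alone disambiguates polysemous words.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "tokenize",
    "Vocabulary",
    "build_vocabulary",
    "build_term_doc_matrix",
    "TermDocMatrix",
]

# Keep letters; collapse internal hyphens/apostrophes ("don't" -> "dont");
# digits and all other punctuation become separators.
_JOINERS = re.compile(r"(?<=[a-z])[\'’-](?=[a-z])")
_NON_ALPHA = re.compile(r"[^a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens, order preserved; '' -> []."""
    lowered = text.lower()
    joined = _JOINERS.sub("", lowered)
    return [t for t in _NON_ALPHA.split(joined) if t]


@dataclass
class Vocabulary:
    """Bijection term -> contiguous index, plus corpus frequencies."""

    index: dict[str, int]
    frequency: dict[str, int]

    def __len__(self) -> int:
        return len(self.index)

    @property
    def terms(self) -> list[str]:
        """Terms ordered by index."""
        out = [""] * len(self.index)
        for t, i in self.index.items():
            out[i] = t
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "term": list(self.index),
                "index": [self.index[t] for t in self.index],
                "frequency": [self.frequency[t] for t in self.index],
            }
        ).sort_values("index").to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"term": str})
        return cls(
            index=dict(zip(df["term"], df["index"].astype(int))),
            frequency=dict(zip(df["term"], df["frequency"].astype(int))),
        )


def build_vocabulary(docs: list[list[str]] | list[str], min_count: int = 1) -> Vocabulary:
    """Count terms over tokenized documents and index those with freq >= min_count.

    `docs` may be raw strings (tokenized here) or pre-tokenized lists.
    Indices are assigned in sorted term order, so the vocabulary is a pure
    function of the corpus.
    """
    if not docs:
        raise ValueError("empty corpus: at least one document required")
    counts: dict[str, int] = {}
    for doc in docs:
        tokens = tokenize(doc) if isinstance(doc, str) else doc
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
    kept = {t: c for t, c in counts.items() if c >= min_count}
    if not kept:
        warnings.warn("vocabulary is empty: min_count exceeds every term frequency")
    index = {t: i for i, t in enumerate(sorted(kept))}
    return Vocabulary(index=index, frequency=kept)


@dataclass
class TermDocMatrix:
    """Sparse T x D weighted matrix tied to its vocabulary."""

    matrix: sp.csr_matrix
    weighting: str
    vocab: Vocabulary
    raw: sp.csr_matrix = field(repr=False, default=None)  # raw counts, kept for fold-in

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def global_weights(self) -> np.ndarray:
        """Per-term global weight implied by the scheme (1.0 for raw)."""
        if self.weighting == "raw":
            return np.ones(self.matrix.shape[0])
        return _entropy_global_weights(self.raw)

    def to_mtx(self, path) -> None:
        scipy.io.mmwrite(str(path), self.matrix)


def _count_matrix(docs, vocab: Vocabulary) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for d, doc in enumerate(docs):
        tokens = tokenize(doc) if isinstance(doc, str) else doc
        local: dict[int, int] = {}
        for t in tokens:
            i = vocab.index.get(t)
            if i is not None:
                local[i] = local.get(i, 0) + 1
        rows.extend(local)
        cols.extend([d] * len(local))
        vals.extend(local.values())
    return sp.csr_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)),
        shape=(len(vocab), len(docs)),
    )


def _entropy_global_weights(counts: sp.csr_matrix) -> np.ndarray:
    """1 - H_t/log D with H_t the entropy of each term's document distribution.

    Terms absent everywhere get weight 0 (their rows are zero anyway).
    """
    n_docs = counts.shape[1]
    if n_docs == 1:
        # log D = 0: a single document carries no distributional information;
        # by convention every present term gets full weight.
        return np.ones(counts.shape[0])
    gf = np.asarray(counts.sum(axis=1)).ravel()
    c = counts.tocoo()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = c.data / gf[c.row]
    plogp = np.zeros(counts.shape[0])
    np.add.at(plogp, c.row, np.where(p > 0, p * np.log(p), 0.0))
    entropy = -plogp
    weights = np.where(gf > 0, 1.0 - entropy / np.log(n_docs), 0.0)
    # clip tiny negative values from float round-off at maximum entropy
    return np.clip(weights, 0.0, 1.0)


def build_term_doc_matrix(
    docs: list[list[str]] | list[str],
    vocab: Vocabulary,
    weighting: str = "log_entropy",
) -> TermDocMatrix:
    """Weighted sparse T x D matrix over `docs` restricted to `vocab`.

    raw:          entry (t, d) = count of t in d
    log_entropy:  entry (t, d) = log(1 + count) * (1 - H_t / log D)
    """
    if weighting not in ("raw", "log_entropy"):
        raise ValueError(f"unknown weighting {weighting!r}; use 'raw' or 'log_entropy'")
    counts = _count_matrix(docs, vocab)
    if weighting == "raw":
        return TermDocMatrix(matrix=counts, weighting="raw", vocab=vocab, raw=counts)
    gw = _entropy_global_weights(counts)
    weighted = counts.tocoo()
    weighted.data = np.log1p(weighted.data) * gw[weighted.row]
    return TermDocMatrix(
        matrix=weighted.tocsr(), weighting="log_entropy", vocab=vocab, raw=counts
    )
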