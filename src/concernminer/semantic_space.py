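"""The rank-k semantic space: truncated SVD, fold-in, cosine similarity.

The weighted term-document matrix A is factored as A ≈ U_k Σ_k V_kᵀ, the best
rank-k approximation in Frobenius norm. Rows of U_k (optionally scaled by Σ_k)
are term vectors; rows of V_k are document vectors. A new passage with weighted
count vector a is folded in as Σ_k⁻¹ U_kᵀ a, which reproduces the passage's
document vector exactly when the passage is one of the training documents.

The full-scale configuration uses k = 300 dimensions; small corpora use
whatever rank they support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .text_prep import TermDocMatrix, Vocabulary

__all__ = ["SemanticSpace", "build_space", "cosine"]

_DENSE_LIMIT = 3000  # below this min-dimension a dense LAPACK SVD is cheaper and exact


@dataclass
class SemanticSpace:
    """Rank-k factorization of a weighted term-document matrix."""

    term_vectors: np.ndarray      # T x k, columns of U_k (orthonormal)
    singular_values: np.ndarray   # length k, nonincreasing, > 0
    doc_vectors: np.ndarray       # D x k, columns of V_k (orthonormal)
    vocab: Vocabulary
    weighting: str = "raw"
    global_weights: np.ndarray | None = None  # per-term weight applied at fold-in

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def scaled_term_vectors(self) -> np.ndarray:
        """Rows of U_k Σ_k — the term-space convention for term-term cosines."""
        return self.term_vectors * self.singular_values

    def term_vector(self, term: str, scaled: bool = True) -> np.ndarray:
        i = self.vocab.index.get(term)
        if i is None:
            raise KeyError(f"term {term!r} not in vocabulary")
        v = self.term_vectors[i]
        return v * self.singular_values if scaled else v

    def fold_in(self, tokens: list[str]) -> tuple[np.ndarray, bool]:
        """Project a token sequence into the space: Σ⁻¹ Uᵀ a.

        `a` holds weighted in-vocabulary counts (local log weight and the
        space's per-term global weights when the space was built with
        log-entropy weighting). Returns (k-vector, in_vocabulary_flag); an
        empty or fully out-of-vocabulary sequence yields the zero vector
        flagged False.
        """
        counts: dict[int, int] = {}
        for t in tokens:
            i = self.vocab.index.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        if not counts:
            return np.zeros(self.k), False
        idx = np.fromiter(counts.keys(), dtype=int)
        val = np.fromiter(counts.values(), dtype=float)
        if self.weighting == "log_entropy":
            gw = self.global_weights if self.global_weights is not None else 1.0
            val = np.log1p(val) * (gw[idx] if np.ndim(gw) else gw)
        projected = self.term_vectors[idx].T @ val
        return projected / self.singular_values, True

    # --- persistence: portable .npy arrays + JSON manifest -----------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "term_vectors.npy", self.term_vectors)
        np.save(d / "singular_values.npy", self.singular_values)
        np.save(d / "doc_vectors.npy", self.doc_vectors)
        if self.global_weights is not None:
            np.save(d / "global_weights.npy", self.global_weights)
        (d / "manifest.json").write_text(
            json.dumps(
                {
                    "k": int(self.k),
                    "weighting": self.weighting,
                    "n_terms": len(self.vocab),
                    "vocab_hash": _vocab_hash(self.vocab),
                }
            )
        )
        self.vocab.to_tsv(d / "vocabulary.tsv")

    @classmethod
    def load(cls, directory) -> "SemanticSpace":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        vocab = Vocabulary.from_tsv(d / "vocabulary.tsv")
        gw_path = d / "global_weights.npy"
        return cls(
            term_vectors=np.load(d / "term_vectors.npy"),
            singular_values=np.load(d / "singular_values.npy"),
            doc_vectors=np.load(d / "doc_vectors.npy"),
            vocab=vocab,
            weighting=manifest["weighting"],
            global_weights=np.load(gw_path) if gw_path.exists() else None,
        )


def _vocab_hash(vocab: Vocabulary) -> str:
    import hashlib

    h = hashlib.sha256()
    for t in vocab.terms:
        h.update(t.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def _fix_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each singular pair so U's largest-magnitude entry is positive.

    SVD is only defined up to per-pair sign; this convention makes
    serialization round-trips bit-stable across runs and BLAS builds.
    """
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    return u * flip, vt * flip[:, None]


def build_space(tdm: TermDocMatrix, k: int) -> SemanticSpace:
    """Best rank-k factorization of the weighted matrix.

    Trailing zero (or numerically negligible) singular values are dropped,
    reducing k, so the returned space always has strictly positive spectrum.
    """
    n_terms, n_docs = tdm.shape
    if k < 1 or k > min(n_terms, n_docs):
        raise ValueError(f"k={k} outside [1, min(T, D)] = [1, {min(n_terms, n_docs)}]")
    norm = sp.linalg.norm(tdm.matrix)
    if norm == 0:
        raise ValueError("degenerate input: all-zero term-document matrix")

    if min(n_terms, n_docs) <= _DENSE_LIMIT:
        u, s, vt = scipy.linalg.svd(tdm.matrix.toarray(), full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        # large sparse problems: Lanczos with a fixed start vector for determinism
        v0 = np.ones(min(n_terms, n_docs))
        u, s, vt = scipy.sparse.linalg.svds(tdm.matrix.tocsc(), k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]

    keep = s > max(n_terms, n_docs) * np.finfo(float).eps * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    u, vt = _fix_signs(u, vt)
    return SemanticSpace(
        term_vectors=np.ascontiguousarray(u),
        singular_values=s,
        doc_vectors=np.ascontiguousarray(vt.T),
        vocab=tdm.vocab,
        weighting=tdm.weighting,
        global_weights=tdm.global_weights() if tdm.weighting == "log_entropy" else None,
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖); 0 when either vector is zero (no similarity)."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))
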