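"""Clustering-term selection, cosine distance matrix, and PAM k-medoids.

High-frequency terms from the meaningful responses (token count strictly
greater than a threshold, default 70, minus a function-word stop list) are
clustered on their semantic-space vectors. The dissimilarity is
1 − cosine, and the partition is found by PAM — partitioning around medoids,
the deterministic k-medoids algorithm of Kaufman & Rousseeuw as implemented
by the R ``cluster::pam`` function: a greedy BUILD phase seeds the medoids,
then a SWAP phase exhaustively tests every (medoid, non-medoid) exchange and
applies the best strictly improving one until no swap lowers the total cost.
Each cluster is represented by its medoid, the member most central to it.

PAM here is written against the distance matrix only (no coordinates), with
all ties broken by lowest index, so a given matrix always yields the same
clustering.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .semantic_space import SemanticSpace
from .text_prep import tokenize

__all__ = [
    "ClusterTermSet",
    "default_stoplist",
    "select_cluster_terms",
    "build_distance_matrix",
    "Clustering",
    "pam_cluster",
    "describe_clusters",
]


def default_stoplist() -> frozenset[str]:
    """~150 high-frequency function words excluded from clustering terms
    (the semantic space itself is built without any stop list)."""
    with resources.as_file(
        resources.files("concernminer") / "data" / "cluster_stoplist.txt"
    ) as p:
        lines = Path(p).read_text(encoding="utf-8").splitlines()
    return frozenset(
        w.strip() for w in lines if w.strip() and not w.startswith("#")
    )


@dataclass
class ClusterTermSet:
    """Selected clustering terms with their response-corpus token counts."""

    terms: list[str]
    frequency: dict[str, int]

    def __len__(self) -> int:
        return len(self.terms)


def select_cluster_terms(
    meaningful_texts: list[str],
    min_freq: int = 70,
    stoplist: frozenset[str] | None = None,
    vocabulary: set[str] | None = None,
) -> ClusterTermSet:
    """Terms whose total occurrence count across meaningful responses is
    STRICTLY greater than `min_freq`, excluding stop-list members and
    (optionally) terms outside the semantic-space vocabulary.

    Frequency is token count, not document frequency. Terms are returned in
    descending frequency (ties alphabetical) so the set is deterministic.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    stop = default_stoplist() if stoplist is None else stoplist
    counts: Counter[str] = Counter()
    for text in meaningful_texts:
        counts.update(tokenize(text))
    selected = {
        t: c
        for t, c in counts.items()
        if c > min_freq
        and t not in stop
        and (vocabulary is None or t in vocabulary)
    }
    if not selected:
        warnings.warn("no clustering terms selected (threshold too high?)")
    terms = sorted(selected, key=lambda t: (-selected[t], t))
    return ClusterTermSet(terms=terms, frequency=selected)


def build_distance_matrix(space: SemanticSpace, terms: ClusterTermSet) -> np.ndarray:
    """Symmetric matrix of 1 − cosine over scaled term vectors (rows of UΣ)."""
    missing = [t for t in terms.terms if t not in space.vocab.index]
    if missing:
        raise ValueError(f"terms not in semantic space: {missing[:5]}")
    idx = np.array([space.vocab.index[t] for t in terms.terms])
    vectors = space.scaled_term_vectors()[idx]
    norms = np.linalg.norm(vectors, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = vectors / safe[:, None]
    unit[norms == 0] = 0.0  # zero vectors: cosine 0 with everything -> distance 1
    cos = unit @ unit.T
    dist = 1.0 - cos
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return (dist + dist.T) / 2.0


@dataclass
class Clustering:
    """Medoid indices plus per-point assignment and total within-cluster cost."""

    medoids: np.ndarray      # indices into the term list, sorted
    assignment: np.ndarray   # point -> medoid index (value is a medoid entry)
    total_cost: float

    @property
    def k(self) -> int:
        return len(self.medoids)

    def members(self, medoid: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == medoid)

    def to_json(self, path, terms: list[str] | None = None) -> None:
        payload = {
            "medoids": [int(m) for m in self.medoids],
            "assignment": [int(a) for a in self.assignment],
            "total_cost": self.total_cost,
        }
        if terms is not None:
            payload["medoid_terms"] = [terms[m] for m in self.medoids]
            payload["members"] = {
                terms[m]: [terms[i] for i in self.members(m)] for m in self.medoids
            }
        Path(path).write_text(json.dumps(payload, indent=1))


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = dist[:, medoids]
    nearest = np.argmin(sub, axis=1)  # argmin takes first on ties = lowest medoid index
    assignment = medoids[nearest]
    return assignment, float(sub[np.arange(len(dist)), nearest].sum())


def pam_cluster(dist: np.ndarray, k: int) -> Clustering:
    """Classic PAM: greedy BUILD then exhaustive best-improvement SWAP.

    Deterministic: no randomness, ties broken by lowest index. Cost never
    increases across swaps, so termination is guaranteed.
    """
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")

    # BUILD: first medoid minimizes total distance; each next medoid is the
    # point whose addition most reduces the cost.
    totals = dist.sum(axis=1)
    medoids = [int(np.argmin(totals))]
    nearest_d = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest_d[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))  # argmax takes first on ties
        medoids.append(best)
        nearest_d = np.minimum(nearest_d, dist[best])

    medoid_arr = np.sort(np.array(medoids))
    _, cost = _assign(dist, medoid_arr)

    # SWAP: evaluate every (medoid m, candidate h) exchange; apply the best
    # strictly improving one; repeat to convergence.
    while k < n:
        sub = dist[:, medoid_arr]                      # n x k
        order = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(n), order[:, 0]]            # nearest medoid distance
        d2 = (
            sub[np.arange(n), order[:, 1]]
            if k > 1
            else np.full(n, np.inf)
        )
        nearest_col = order[:, 0]

        best_delta = 0.0
        best_swap: tuple[int, int] | None = None
        non_medoids = np.setdiff1d(np.arange(n), medoid_arr)
        for col, m in enumerate(medoid_arr):
            owned = nearest_col == col
            # candidate h replaces medoid m; cost change summed over points
            dh = dist[non_medoids]                     # |H| x n
            new_owned = np.minimum(dh[:, owned], d2[owned][None, :])
            delta = (new_owned - d1[owned][None, :]).sum(axis=1)
            other = ~owned
            gain_other = np.minimum(dh[:, other] - d1[other][None, :], 0.0)
            delta = delta + gain_other.sum(axis=1)
            j = int(np.argmin(delta))
            if delta[j] < best_delta - 1e-12:
                best_delta = float(delta[j])
                best_swap = (int(m), int(non_medoids[j]))
            elif best_swap is not None and abs(delta[j] - best_delta) <= 1e-12:
                # tie across medoids: keep the swap with the lowest indices
                cand = (int(m), int(non_medoids[j]))
                if cand < best_swap:
                    best_swap = cand
        if best_swap is None:
            break
        m, h = best_swap
        medoid_arr = np.sort(np.append(medoid_arr[medoid_arr != m], h))

    assignment, cost = _assign(dist, medoid_arr)
    assignment[medoid_arr] = medoid_arr  # medoids belong to themselves (distance 0)
    return Clustering(medoids=medoid_arr, assignment=assignment, total_cost=cost)


def describe_clusters(
    clustering: Clustering,
    dist: np.ndarray,
    terms: list[str],
    top_m: int = 5,
    excluded: set[int] | None = None,
) -> pd.DataFrame:
    """Per-cluster summary for human labeling: medoid plus the `top_m`
    members nearest it. Clusters in `excluded` (no discernable semantic
    meaning) are marked so downstream concern tables drop them; they still
    count in any demographic analysis of who responded.
    """
    excluded = excluded or set()
    rows = []
    for m in clustering.medoids:
        members = clustering.members(m)
        others = members[members != m]
        nearest = others[np.argsort(dist[m, others], kind="stable")][:top_m]
        rows.append(
            {
                "cluster_id": int(m),
                "medoid": terms[m],
                "size": len(members),
                "top_terms": ", ".join(terms[i] for i in nearest),
                "excluded": int(m) in excluded,
            }
        )
    return pd.DataFrame(rows)
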