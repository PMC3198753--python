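"""Assigning meaningful responses to areas of concern.

Each meaningful response is folded into the semantic space and compared, by
cosine, with every cluster medoid's term vector. Membership is multi-label:
the response joins every cluster whose medoid cosine is STRICTLY greater
than the threshold (default 0.2); a response may belong to zero, one, or
several clusters. Clusters are then ranked by how many responses they hold,
and the labeled clusters are tabulated into an area-of-concern table whose
percentages are taken over the table's total assignment count, one decimal,
half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import pct
from .semantic_space import SemanticSpace, cosine
from .term_clustering import Clustering
from .text_prep import tokenize

__all__ = [
    "AssignmentTable",
    "assign_responses",
    "rank_clusters",
    "build_concern_table",
]


@dataclass
class AssignmentTable:
    """response id -> list of (cluster id, cosine); plus unassigned ids."""

    memberships: dict[str, list[tuple[int, float]]]
    unassigned: set[str] = field(default_factory=set)
    threshold: float = 0.2

    @property
    def n_responses(self) -> int:
        return len(self.memberships) + len(self.unassigned)

    @property
    def n_assigned(self) -> int:
        return len(self.memberships)

    def multi_membership_rate(self) -> float:
        """Fraction of assigned responses in more than one cluster."""
        if not self.memberships:
            return 0.0
        multi = sum(1 for m in self.memberships.values() if len(m) > 1)
        return multi / len(self.memberships)

    def best_cluster(self, response_id: str) -> int | None:
        """Highest-cosine cluster (ties: lowest cluster id), or None."""
        pairs = self.memberships.get(response_id)
        if not pairs:
            return None
        return min(pairs, key=lambda p: (-p[1], p[0]))[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"response_id": rid, "cluster_id": cid, "cosine": cos}
            for rid, pairs in self.memberships.items()
            for cid, cos in pairs
        ]
        return pd.DataFrame(rows, columns=["response_id", "cluster_id", "cosine"])


def assign_responses(
    space: SemanticSpace,
    responses: pd.DataFrame,
    clustering: Clustering,
    terms: list[str],
    threshold: float = 0.2,
    text_col: str = "text",
    id_col: str = "response_id",
) -> AssignmentTable:
    """Multi-label cosine-threshold assignment of responses to medoids.

    The medoid vector is its scaled term vector (row of UΣ); the response
    vector is the fold-in projection of its tokens. All-out-of-vocabulary
    responses have a zero vector, cosine 0 everywhere, hence stay unassigned
    for any threshold >= 0.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must be in (-1, 1)")
    medoid_vectors = np.stack(
        [space.term_vector(terms[m], scaled=True) for m in clustering.medoids]
    )
    norms = np.linalg.norm(medoid_vectors, axis=1)
    memberships: dict[str, list[tuple[int, float]]] = {}
    unassigned: set[str] = set()
    for rid, text in zip(responses[id_col], responses[text_col]):
        vec, in_vocab = space.fold_in(tokenize(str(text)))
        vnorm = np.linalg.norm(vec)
        if not in_vocab or vnorm == 0.0:
            unassigned.add(rid)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = medoid_vectors @ vec / (norms * vnorm)
        cos = np.where(norms == 0, 0.0, cos)
        hits = np.flatnonzero(cos > threshold)
        if hits.size:
            memberships[rid] = [
                (int(clustering.medoids[h]), float(cos[h])) for h in hits
            ]
        else:
            unassigned.add(rid)
    return AssignmentTable(
        memberships=memberships, unassigned=unassigned, threshold=threshold
    )


def rank_clusters(assignments: AssignmentTable) -> pd.DataFrame:
    """Clusters ordered by descending response count (ties by cluster id),
    with coverage = assigned / all responses in the table."""
    counts: dict[int, int] = {}
    for pairs in assignments.memberships.values():
        for cid, _ in pairs:
            counts[cid] = counts.get(cid, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    coverage = (
        assignments.n_assigned / assignments.n_responses
        if assignments.n_responses
        else 0.0
    )
    df = pd.DataFrame(ranked, columns=["cluster_id", "n_responses"])
    df.attrs["coverage"] = coverage
    return df


def build_concern_table(
    assignments: AssignmentTable | pd.DataFrame,
    labels: dict[int, str],
    strata: dict[str, str] | None = None,
    related_terms: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Area-of-concern table over the labeled clusters.

    Accepts either an AssignmentTable or a long frame (response_id,
    cluster_id). Clusters absent from `labels` (the ones judged to lack
    semantic meaning) are dropped BEFORE totals, so percentages are over the
    table's own total assignment count; per-stratum percentages are over the
    stratum's assignment total. One decimal, half-up. Rows are ordered by
    descending total count.
    """
    frame = (
        assignments.to_frame()
        if isinstance(assignments, AssignmentTable)
        else assignments.copy()
    )
    frame = frame[frame["cluster_id"].isin(labels)]
    if strata is not None:
        missing = set(frame["response_id"]) - set(strata)
        if missing:
            raise ValueError(f"no stratum for response(s): {sorted(missing)[:5]}")
        frame["stratum"] = frame["response_id"].map(strata)
    total = len(frame)
    rows = []
    stratum_levels = sorted(frame["stratum"].unique()) if strata is not None else []
    stratum_totals = {s: int((frame["stratum"] == s).sum()) for s in stratum_levels}
    for cid, group in frame.groupby("cluster_id"):
        row = {
            "cluster_id": int(cid),
            "area_of_concern": labels[int(cid)],
            "n": len(group),
            "percent": pct(len(group), total) if total else float("nan"),
        }
        for s in stratum_levels:
            ns = int((group["stratum"] == s).sum())
            row[f"n_{s}"] = ns
            row[f"pct_{s}"] = (
                pct(ns, stratum_totals[s]) if stratum_totals[s] else float("nan")
            )
        if related_terms:
            row["related_terms"] = related_terms.get(int(cid), "")
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["n", "cluster_id"], ascending=[False, True], ignore_index=True
    )
    out.attrs["total_assignments"] = total
    out.attrs["stratum_totals"] = stratum_totals
    return out


def render_concern_table_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering mirroring the published layout."""
    total = table.attrs.get("total_assignments", int(table["n"].sum()))
    lines = [f"| Area of Concern | n (total = {total:,}) | % |", "| --- | --- | --- |"]
    for _, row in table.iterrows():
        lines.append(
            f"| {row['area_of_concern']} | {int(row['n']):,} | {row['percent']:.1f} |"
        )
    return "\n".join(lines)
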