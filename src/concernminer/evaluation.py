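"""Ground-truth evaluation experiments for the synthetic pipeline.

Two standard experiments quantify whether the analysis chain recovers what
the generator planted:

* `recovery_experiment` — run the full text pipeline on a synthetic cohort
  and score cluster assignments against the planted topic labels: the share
  of single-topic responses assigned to the cluster carrying their topic's
  seed terms, and the adjusted Rand index between planted labels and each
  response's best cluster (multi-topic responses excluded from both).
* `propensity_coverage` — repeatedly regenerate the cohort and refit the
  propensity model, recording how often each planted nonzero log-odds
  coefficient falls inside its 95% Wald interval.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .assignment import assign_responses
from .cohort_stats import fit_propensity
from .null_filter import default_patterns, split_responses
from .semantic_space import build_space
from .synthetic import (
    default_propensity_config,
    default_topic_model,
    generate_background_docs,
    generate_participants,
    generate_responses,
    match_topics_to_clusters,
)
from .term_clustering import build_distance_matrix, pam_cluster, select_cluster_terms
from .text_prep import build_term_doc_matrix, build_vocabulary

__all__ = ["recovery_experiment", "propensity_coverage"]


def recovery_experiment(
    seed: int,
    n_docs: int = 5000,
    n_participants: int = 26500,
    k: int = 50,
    k_c: int = 12,
    min_freq: int = 70,
    threshold: float = 0.2,
    null_rate: float = 0.546,
) -> dict:
    """Full pipeline on default synthetic settings, scored against ground
    truth. The default participant count yields on the order of 10,000
    responses at the default response propensity."""
    model = default_topic_model()
    docs = generate_background_docs(n_docs, model, seed)
    participants = generate_participants(n_participants, seed=seed)
    responses, truth = generate_responses(participants, model, null_rate, seed)
    meaningful, meaningless = split_responses(responses, default_patterns())

    corpus = list(docs) + [str(t) for t in meaningful["text"]]
    vocab = build_vocabulary(corpus)
    tdm = build_term_doc_matrix(corpus, vocab)
    space = build_space(tdm, min(k, min(tdm.shape)))
    terms = select_cluster_terms(
        [str(t) for t in meaningful["text"]],
        min_freq=min_freq,
        vocabulary=set(vocab.index),
    )
    dist = build_distance_matrix(space, terms)
    clustering = pam_cluster(dist, min(k_c, len(terms)))
    table = assign_responses(space, meaningful, clustering, terms.terms, threshold)

    topic_to_cluster = match_topics_to_clusters(clustering, terms.terms, model)
    single = [
        rid
        for rid in meaningful["response_id"]
        if len(truth.response_topic_labels[rid]) == 1
    ]
    hits = 0
    planted, predicted = [], []
    for rid in single:
        label = truth.response_topic_labels[rid][0]
        memberships = dict(table.memberships.get(rid, []))
        if topic_to_cluster.get(label) in memberships:
            hits += 1
        planted.append(label)
        best = table.best_cluster(rid)
        predicted.append(-1 if best is None else best)
    return {
        "n_responses": len(responses),
        "n_meaningful": len(meaningful),
        "n_single_topic": len(single),
        "n_cluster_terms": len(terms),
        "coverage": table.n_assigned / table.n_responses,
        "multi_membership_rate": table.multi_membership_rate(),
        "single_topic_assignment_rate": hits / len(single) if single else float("nan"),
        "ari": float(adjusted_rand_score(planted, predicted)) if single else float("nan"),
    }


def propensity_coverage(seed: int, n_replicates: int = 100, n: int = 20000) -> dict:
    """Per-coefficient 95% Wald CI coverage of the planted log-odds over
    seeded cohort replicates, plus the pooled rate and the fair/poor-health
    estimates."""
    cfg = default_propensity_config()
    planted = {
        (name, level): coef
        for name, spec in cfg.covariates.items()
        for level, coef in zip(spec.levels, spec.coefficients)
        if coef != 0.0
    }
    hits = {key: 0 for key in planted}
    fair_poor_aors = []
    rng = np.random.SeedSequence(seed)
    rep_seeds = rng.generate_state(n_replicates) % (2**31)
    for s in rep_seeds:
        parts = generate_participants(n, cfg, seed=int(s))
        parts["outcome"] = parts["responded"]
        fit = fit_propensity(parts, list(cfg.covariates))
        tab = fit.table.set_index(["covariate", "level"])
        for (name, level), coef in planted.items():
            row = tab.loc[(name, level)]
            if row["ci_low"] <= np.exp(coef) <= row["ci_high"]:
                hits[(name, level)] += 1
        fair_poor_aors.append(fit.aor("general_health", "Fair/poor"))
    per_coef = {f"{n_}:{l}": h / n_replicates for (n_, l), h in hits.items()}
    return {
        "n_replicates": n_replicates,
        "per_coefficient_coverage": per_coef,
        "pooled_coverage": float(np.mean(list(per_coef.values()))),
        "min_coverage": float(min(per_coef.values())),
        "fair_poor_coverage": per_coef["general_health:Fair/poor"],
        "mean_fair_poor_aor": float(np.mean(fair_poor_aors)),
    }
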