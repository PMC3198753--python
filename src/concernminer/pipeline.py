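"""End-to-end orchestration: simulate → prep → space → filter → cluster →
assign → tabulate → stats, as a configured, logged, reproducible run.

Every stage reads its inputs from, and persists its outputs into, a run
directory, so a run can be resumed or audited stage by stage and two runs
with the same config and seed produce identical artifacts. Stage failures
abort with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up
from . import synthetic
from .assignment import (
    assign_responses,
    build_concern_table,
    rank_clusters,
    render_concern_table_markdown,
)
from .cohort_stats import fit_propensity, tabulate_characteristics
from .null_filter import NullPatternSet, default_patterns, split_responses
from .semantic_space import SemanticSpace, build_space
from .synthetic import default_topic_model
from .term_clustering import (
    build_distance_matrix,
    describe_clusters,
    pam_cluster,
    select_cluster_terms,
    ClusterTermSet,
)
from .text_prep import build_term_doc_matrix, build_vocabulary

__all__ = ["RunConfig", "run_pipeline", "summarize_counts", "PipelineError"]

log = logging.getLogger("concernminer")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of a run. Defaults are the full-scale analysis constants:
    300 space dimensions, clustering terms occurring more than 70 times,
    20 clusters, assignment cosine threshold 0.2, null rate 54.6%."""

    seed: int = 0
    n_docs: int = 5000
    n_participants: int = 30000
    k: int = 300
    min_freq: int = 70
    k_c: int = 20
    threshold: float = 0.2
    null_rate: float = 0.546
    weighting: str = "log_entropy"
    out_dir: str = "run"
    pattern_file: str | None = None
    override_file: str | None = None
    label_file: str | None = None      # cluster id -> human label (JSON)
    exclusion_file: str | None = None  # cluster ids lacking semantic meaning

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def summarize_counts(counts: dict) -> dict:
    """One-decimal half-up percentage summary of the stage counts.

    Keys used: n_surveys, n_responses, n_meaningless, n_meaningful,
    n_assigned. A zero denominator yields the marker string 'undefined'.
    """

    def _pct(num, den):
        return round_half_up(100.0 * num / den) if den else "undefined"

    return {
        "pct_any_response": _pct(counts["n_responses"], counts["n_surveys"]),
        "pct_meaningless_of_responses": _pct(
            counts["n_meaningless"], counts["n_responses"]
        ),
        "pct_meaningful_of_responses": _pct(
            counts["n_meaningful"], counts["n_responses"]
        ),
        "pct_meaningful_of_surveys": _pct(counts["n_meaningful"], counts["n_surveys"]),
        "pct_assigned_of_meaningful": _pct(counts["n_assigned"], counts["n_meaningful"]),
    }


# --------------------------------------------------------------------------
# stages — each persists into the run directory
# --------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(cfg: RunConfig, out: Path):
    model = default_topic_model()
    docs = synthetic.generate_background_docs(cfg.n_docs, model, cfg.seed)
    participants = synthetic.generate_participants(cfg.n_participants, seed=cfg.seed)
    responses, truth = synthetic.generate_responses(
        participants, model, cfg.null_rate, cfg.seed
    )
    (out / "docs.txt").write_text("\n".join(docs) + "\n")
    participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    responses.to_csv(out / "responses.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    return docs, participants, responses, truth


@_stage("filter")
def stage_filter(cfg: RunConfig, out: Path, responses: pd.DataFrame):
    patterns = (
        NullPatternSet.from_file(cfg.pattern_file)
        if cfg.pattern_file
        else default_patterns()
    )
    overrides = None
    if cfg.override_file:
        odf = pd.read_csv(cfg.override_file, sep="\t")
        overrides = dict(zip(odf["response_id"], odf["label"].astype(bool)))
    meaningful, meaningless = split_responses(responses, patterns, overrides)
    meaningful.to_csv(out / "meaningful.tsv", sep="\t", index=False)
    meaningless.to_csv(out / "meaningless.tsv", sep="\t", index=False)
    if meaningful.empty:
        warnings.warn("no meaningful responses; downstream stages will be empty")
    return meaningful, meaningless


@_stage("prep")
def stage_prep(cfg: RunConfig, out: Path, docs, meaningful: pd.DataFrame):
    # the open-ended responses join the corpus: response-specific usage
    # patterns must be representable in the space
    corpus = list(docs) + [str(t) for t in meaningful["text"]]
    vocab = build_vocabulary(corpus)
    tdm = build_term_doc_matrix(corpus, vocab, weighting=cfg.weighting)
    vocab.to_tsv(out / "vocabulary.tsv")
    tdm.to_mtx(out / "term_doc.mtx")
    return corpus, vocab, tdm


@_stage("space")
def stage_space(cfg: RunConfig, out: Path, tdm):
    k = min(cfg.k, min(tdm.shape))
    space = build_space(tdm, k)
    space.save(out / "space")
    return space


@_stage("cluster")
def stage_cluster(cfg: RunConfig, out: Path, meaningful, space):
    terms = select_cluster_terms(
        [str(t) for t in meaningful["text"]],
        min_freq=cfg.min_freq,
        vocabulary=set(space.vocab.index),
    )
    if len(terms) == 0:
        warnings.warn("empty clustering stage")
        return terms, None, None
    dist = build_distance_matrix(space, terms)
    k_c = min(cfg.k_c, len(terms))
    clustering = pam_cluster(dist, k_c)
    clustering.to_json(out / "clustering.json", terms=terms.terms)
    excluded = _load_exclusions(cfg)
    summary = describe_clusters(clustering, dist, terms.terms, excluded=excluded)
    summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
    return terms, dist, clustering


def _load_exclusions(cfg: RunConfig) -> set[int]:
    if not cfg.exclusion_file:
        return set()
    text = Path(cfg.exclusion_file).read_text()
    return {int(x) for x in text.split()}


def _load_labels(cfg: RunConfig, clustering, terms: ClusterTermSet) -> dict[int, str]:
    if cfg.label_file:
        raw = json.loads(Path(cfg.label_file).read_text())
        labels = {int(k): v for k, v in raw.items()}
    else:
        # default label: the medoid term itself
        labels = {int(m): terms.terms[m] for m in clustering.medoids}
    for cid in _load_exclusions(cfg):
        labels.pop(cid, None)
    return labels


@_stage("assign")
def stage_assign(cfg: RunConfig, out: Path, space, meaningful, clustering, terms):
    table = assign_responses(
        space, meaningful, clustering, terms.terms, threshold=cfg.threshold
    )
    table.to_frame().to_csv(out / "assignments.tsv", sep="\t", index=False)
    ranking = rank_clusters(table)
    ranking.to_csv(out / "cluster_ranking.tsv", sep="\t", index=False)
    return table


@_stage("tabulate")
def stage_tabulate(cfg: RunConfig, out: Path, table, meaningful, clustering, terms):
    labels = _load_labels(cfg, clustering, terms)
    strata = dict(zip(meaningful["response_id"], meaningful["stratum"]))
    concern = build_concern_table(table, labels, strata=strata)
    concern.to_csv(out / "concern_table.tsv", sep="\t", index=False)
    (out / "concern_table.md").write_text(render_concern_table_markdown(concern))
    return concern


@_stage("stats")
def stage_stats(cfg: RunConfig, out: Path, participants, meaningful):
    records = participants.copy()
    # meaningless responders count as non-responders to the open-ended field
    meaningful_ids = set(meaningful["participant_id"])
    records["outcome"] = records["participant_id"].isin(meaningful_ids)
    covariates = [
        c
        for c in records.columns
        if c not in ("participant_id", "responded", "true_logit", "outcome", "stratum")
    ]
    chars = tabulate_characteristics(records, covariates)
    chars.to_csv(out / "characteristics.tsv", sep="\t", index=False)
    if records["outcome"].nunique() < 2:
        warnings.warn("outcome is constant; skipping propensity model")
        (out / "aor.tsv").write_text("")
        return records, chars, None
    fit = fit_propensity(records, covariates)
    fit.table.to_csv(out / "aor.tsv", sep="\t", index=False)
    return records, chars, fit


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return (and persist) the run report.

    The report carries the stage counts (surveys, responses, meaningless,
    meaningful, assigned) and their percentage summary, so a run's headline
    numbers can be recomputed from the report alone.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    try:
        cfg.to_yaml(out / "config.yaml")
        docs, participants, responses, truth = stage_simulate(cfg, out)
        meaningful, meaningless = stage_filter(cfg, out, responses)
        counts = {
            "n_surveys": len(participants),
            "n_responses": len(responses),
            "n_meaningless": len(meaningless),
            "n_meaningful": len(meaningful),
            "n_assigned": 0,
        }
        concern_rows = 0
        clustering = None
        if not meaningful.empty:
            docs_list, vocab, tdm = stage_prep(cfg, out, docs, meaningful)
            space = stage_space(cfg, out, tdm)
            terms, dist, clustering = stage_cluster(cfg, out, meaningful, space)
            if clustering is not None:
                table = stage_assign(cfg, out, space, meaningful, clustering, terms)
                counts["n_assigned"] = table.n_assigned
                concern = stage_tabulate(
                    cfg, out, table, meaningful, clustering, terms
                )
                concern_rows = len(concern)
        stage_stats(cfg, out, participants, meaningful)
        report = {
            "config": dataclasses.asdict(cfg),
            "counts": counts,
            "percentages": summarize_counts(counts),
            "n_labeled_clusters": concern_rows,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
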