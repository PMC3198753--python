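"""Synthetic cohort and corpus generator with known ground truth.

Real open-ended cohort data (and the background document corpus a semantic
space would be trained on) are proprietary, so the analysis is exercised on
synthetic data that emulates its statistical structure:

* a **background corpus** of bag-of-words documents drawn from a topic
  mixture — each document is dominated by one (occasionally two) of a set of
  health-concern topics, diluted with common function words;
* **open-ended responses** from the participants who chose to respond: with
  probability ``null_rate`` a contentless string drawn from a bank of null
  variants, otherwise a short topic-structured token sequence whose planted
  topic labels are recorded as ground truth;
* a **participant table** whose covariates follow configured marginal
  distributions and whose probability of responding follows a logistic model
  with known coefficients, emulating the observed pattern that, e.g.,
  participants in fair/poor self-rated health respond about three times as
  often as those in very good/excellent health.

Everything is a deterministic function of one integer seed; each operation
draws from its own substream, so corpora, participants and responses can be
regenerated independently.

Word order carries no signal by design: latent semantic analysis treats a
passage as a bag of words, so the generator only needs to control the joint
term-frequency structure, not grammar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import substream

__all__ = [
    "Topic",
    "TopicModel",
    "default_topic_model",
    "CovariateSpec",
    "PropensityConfig",
    "default_propensity_config",
    "GroundTruth",
    "generate_background_docs",
    "generate_participants",
    "generate_responses",
    "match_topics_to_clusters",
]


# --------------------------------------------------------------------------
# topic model
# --------------------------------------------------------------------------

@dataclass
class Topic:
    """One area of concern: a term pool with weights; the first `n_seed`
    terms are high-weight seed terms exclusive to this topic."""

    label: str
    terms: list[str]
    weights: np.ndarray
    n_seed: int = 6

    @property
    def seed_terms(self) -> list[str]:
        return self.terms[: self.n_seed]

    def term_probability(self, term: str) -> float:
        try:
            return float(self.weights[self.terms.index(term)])
        except ValueError:
            return 0.0


@dataclass
class TopicModel:
    """Mixture model generating documents and meaningful responses."""

    topics: list[Topic]
    background_terms: list[str]
    background_weights: np.ndarray
    topic_share: float = 0.7        # fraction of tokens drawn from the topic pool
    p_single: float = 0.8           # P(document has a single dominant topic)
    doc_length_mean: float = 60.0   # background documents
    doc_length_shape: float = 10.0  # negative-binomial dispersion
    response_length_mean: float = 15.0
    response_length_shape: float = 5.0

    @property
    def n_topics(self) -> int:
        return len(self.topics)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.topics]

    def validate(self) -> None:
        for t in self.topics:
            if abs(t.weights.sum() - 1.0) > 1e-9:
                raise ValueError(f"topic {t.label!r} weights sum to {t.weights.sum()}")
        if abs(self.background_weights.sum() - 1.0) > 1e-9:
            raise ValueError("background weights do not sum to 1")
        pools = {t.label: set(t.terms) for t in self.topics}
        for t in self.topics:
            others = set().union(*(p for l, p in pools.items() if l != t.label))
            exclusive = [s for s in t.seed_terms if s not in others]
            if len(exclusive) < 5:
                raise ValueError(f"topic {t.label!r} has < 5 exclusive seed terms")

    def expected_token_probability(self, term: str) -> float:
        """Marginal P(token == term) in a generated document.

        Topic choice is uniform, and single- vs two-topic mixing preserves the
        uniform expected weight 1/K per topic, so the marginal is
        topic_share * mean_over_topics(w_topic(term)) + (1 - topic_share) * w_bg(term).
        """
        topic_part = float(np.mean([t.term_probability(term) for t in self.topics]))
        try:
            bg = float(self.background_weights[self.background_terms.index(term)])
        except ValueError:
            bg = 0.0
        return self.topic_share * topic_part + (1.0 - self.topic_share) * bg


def _topic(label: str, seeds: list[str], others: list[str]) -> Topic:
    terms = seeds + others
    w = np.empty(len(terms))
    w[: len(seeds)] = 0.6 / len(seeds)
    w[len(seeds):] = 0.4 / len(others)
    return Topic(label=label, terms=terms, weights=w / w.sum(), n_seed=len(seeds))


# Twelve areas of concern: eleven named topics patterned on the concern
# categories large military-cohort surveys elicit, plus one diffuse
# general-health topic. Seed terms (first six) are exclusive to their topic;
# later terms may be shared (pain, chronic, anxiety ... ) to make the
# clustering problem realistic rather than block-diagonal.
_TOPIC_POOLS: list[tuple[str, list[str], list[str]]] = [
    ("illness_injury",
     ["suffered", "recovered", "developed", "diagnosed", "hypertension", "medication"],
     ["illness", "injury", "blood", "pressure", "chronic", "condition",
      "doctor", "hospital", "treatment", "symptoms", "pain", "health"]),
    ("exposure",
     ["chemicals", "radiation", "asbestos", "fumes", "uranium", "toxic"],
     ["exposed", "exposure", "welding", "hazardous", "smoke", "dust",
      "burning", "depleted", "contact", "environment", "air", "materials"]),
    ("exercise",
     ["walking", "biking", "vigorous", "jogging", "fitness", "workout"],
     ["running", "exercise", "gym", "training", "activity", "weekly",
      "minutes", "strength", "cardio", "physical", "weight", "program"]),
    ("back_pain",
     ["discs", "herniation", "lumbar", "spine", "sciatica", "vertebrae"],
     ["back", "lower", "pain", "chronic", "ache", "nerve",
      "disc", "posture", "stiffness", "mobility", "therapy", "injury"]),
    ("deployment",
     ["bosnia", "barracks", "kuwait", "iraq", "afghanistan", "convoy"],
     ["deployment", "deployed", "overseas", "region", "base", "desert",
      "oil", "wells", "water", "conditions", "theater", "tour"]),
    ("arm",
     ["elbow", "pronate", "grip", "wrist", "forearm", "shoulder"],
     ["arm", "hand", "fingers", "numbness", "tingling", "strain",
      "lifting", "joint", "pain", "weakness", "motion", "carpal"]),
    ("mental_health",
     ["emotional", "interpersonal", "depression", "counseling", "ptsd", "psychological"],
     ["mental", "stress", "anxiety", "mood", "therapy", "trauma",
      "abuse", "adjustment", "readjustment", "family", "coping", "support"]),
    ("weight",
     ["lose", "dieting", "obesity", "overweight", "pounds", "bmi"],
     ["weight", "gain", "diet", "eating", "appetite", "nutrition",
      "calories", "body", "fat", "metabolism", "habits", "portion"]),
    ("vaccination",
     ["vaers", "influenza", "boosters", "anthrax", "smallpox", "immunization"],
     ["vaccine", "vaccination", "shot", "reaction", "allergic", "series",
      "shots", "dose", "immunized", "record", "adverse", "flu"]),
    ("anxiety_disorientation",
     ["shortness", "sweating", "tiredness", "dizziness", "palpitations", "insomnia"],
     ["anxiety", "panic", "attacks", "heart", "racing", "breath",
      "chest", "sleep", "fatigue", "lightheaded", "episodes", "stress"]),
    ("surgery",
     ["incision", "stitches", "sutures", "postoperative", "anesthesia", "biopsy"],
     ["surgery", "removed", "tape", "wrapped", "procedure", "recovery",
      "knee", "repair", "scar", "operation", "healing", "surgeon"]),
    ("general_health",
     ["wondering", "curious", "checkup", "advice", "suggestion", "feedback"],
     ["health", "general", "overall", "question", "information", "concern",
      "feel", "think", "body", "doctor", "care", "wellness"]),
]

# Background filler drawn from common function words (a subset of the
# clustering stop list), Zipf-like weights.
_BACKGROUND_TERMS = [
    "the", "of", "and", "to", "a", "in", "that", "is", "was", "for",
    "it", "with", "as", "on", "be", "at", "by", "this", "had", "not",
    "are", "but", "from", "or", "have", "an", "they", "which", "you", "were",
    "her", "all", "she", "there", "would", "their", "we", "him", "been", "has",
    "when", "who", "will", "more", "no", "if", "out", "so", "said", "what",
    "up", "its", "about", "into", "than", "them", "can", "only", "other", "new",
    "some", "could", "time", "these", "two", "may", "then", "do", "first", "any",
    "my", "now", "such", "like", "our", "over", "man", "me", "even", "most",
    "made", "after", "also", "did", "many", "before", "must", "through", "years",
    "where", "much", "your", "way", "well", "down", "should", "because", "each",
    "just", "those",
]


def default_topic_model() -> TopicModel:
    topics = [_topic(label, seeds, others) for label, seeds, others in _TOPIC_POOLS]
    ranks = np.arange(1, len(_BACKGROUND_TERMS) + 1, dtype=float)
    zipf = 1.0 / ranks
    model = TopicModel(
        topics=topics,
        background_terms=list(_BACKGROUND_TERMS),
        background_weights=zipf / zipf.sum(),
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# document generation
# --------------------------------------------------------------------------

def _negbin_lengths(rng, n, mean, shape, minimum):
    p = shape / (shape + mean)
    lengths = rng.negative_binomial(shape, p, size=n)
    return np.maximum(lengths, minimum)


def _sample_doc(rng, model: TopicModel, topic_idx: np.ndarray, length: int) -> list[str]:
    """One bag-of-words document over the given (1 or 2) topics."""
    n_topic = rng.binomial(length, model.topic_share)
    tokens: list[str] = []
    if n_topic > 0:
        # split topic tokens equally in expectation across the doc's topics
        alloc = rng.multinomial(n_topic, np.full(len(topic_idx), 1.0 / len(topic_idx)))
        for ti, cnt in zip(topic_idx, alloc):
            if cnt:
                t = model.topics[ti]
                tokens.extend(rng.choice(t.terms, size=cnt, p=t.weights))
    n_bg = length - n_topic
    if n_bg > 0:
        tokens.extend(
            rng.choice(model.background_terms, size=n_bg, p=model.background_weights)
        )
    rng.shuffle(tokens)
    return tokens


def _draw_topics(rng, model: TopicModel) -> np.ndarray:
    if rng.random() < model.p_single:
        return rng.integers(0, model.n_topics, size=1)
    return rng.choice(model.n_topics, size=2, replace=False)


def generate_background_docs(
    n_docs: int, topic_model: TopicModel | None = None, seed: int = 0
) -> list[str]:
    """Generate `n_docs` space-joined bag-of-words documents."""
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    model = topic_model or default_topic_model()
    rng = substream(seed, "background_docs")
    lengths = _negbin_lengths(
        rng, n_docs, model.doc_length_mean, model.doc_length_shape, minimum=10
    )
    docs = []
    for length in lengths:
        topic_idx = _draw_topics(rng, model)
        docs.append(" ".join(_sample_doc(rng, model, topic_idx, int(length))))
    return docs


# --------------------------------------------------------------------------
# participants
# --------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Levels of one categorical covariate: first level is the reference
    (coefficient 0); margins are the marginal category probabilities."""

    levels: list[str]
    margins: list[float]
    coefficients: list[float]

    def validate(self, name: str) -> None:
        if abs(sum(self.margins) - 1.0) > 1e-9:
            raise ValueError(f"margins of {name!r} sum to {sum(self.margins)}, not 1")
        if self.coefficients[0] != 0.0:
            raise ValueError(f"reference level of {name!r} must have coefficient 0")
        if not (len(self.levels) == len(self.margins) == len(self.coefficients)):
            raise ValueError(f"length mismatch in covariate {name!r}")


@dataclass
class PropensityConfig:
    """Logistic model P(respond) = expit(intercept + sum of level coefficients)."""

    covariates: dict[str, CovariateSpec]
    intercept: float
    strata: CovariateSpec | None = None  # panel/survey membership, no coefficient

    def validate(self) -> None:
        for name, spec in self.covariates.items():
            spec.validate(name)
        if self.strata is not None:
            self.strata.validate("stratum")

    def coefficient(self, covariate: str, level: str) -> float:
        spec = self.covariates[covariate]
        return spec.coefficients[spec.levels.index(level)]


def _norm(margins: list[float]) -> list[float]:
    s = sum(margins)
    return [m / s for m in margins]


def default_propensity_config() -> PropensityConfig:
    """Margins patterned on a large military cohort; log-odds patterned on the
    observed adjusted odds of open-text response (fair/poor health ~ 3x)."""
    ln = np.log
    cov = {
        "sex": CovariateSpec(
            ["Male", "Female"], _norm([0.732, 0.268]), [0.0, float(ln(1.07))]
        ),
        "birth_year": CovariateSpec(
            ["Before 1960", "1960-1969", "1970-1979", "1980 or later"],
            _norm([0.216, 0.379, 0.346, 0.059]),
            [0.0, float(ln(0.83)), float(ln(0.65)), float(ln(0.52))],
        ),
        "education": CovariateSpec(
            ["High school or less", "Some college", "Bachelor's degree", "Advanced degree"],
            _norm([0.489, 0.255, 0.165, 0.091]),
            [0.0, float(ln(1.03)), float(ln(1.07)), float(ln(1.07))],
        ),
        "marital_status": CovariateSpec(
            ["Married", "Not married"], _norm([0.631, 0.369]), [0.0, float(ln(1.09))]
        ),
        "race_ethnicity": CovariateSpec(
            ["White non-Hispanic", "Black non-Hispanic", "Other"],
            _norm([0.696, 0.138, 0.167]),
            [0.0, float(ln(0.71)), float(ln(0.95))],
        ),
        "deployment": CovariateSpec(
            ["No", "Yes"], _norm([0.576, 0.425]), [0.0, float(ln(0.88))]
        ),
        "rank": CovariateSpec(
            ["Enlisted", "Officer"], _norm([0.770, 0.230]), [0.0, float(ln(1.07))]
        ),
        "component": CovariateSpec(
            ["Reserve/Guard", "Active duty"], _norm([0.430, 0.570]), [0.0, float(ln(1.50))]
        ),
        "branch": CovariateSpec(
            ["Air Force", "Army", "Navy/Coast Guard", "Marine Corps"],
            _norm([0.290, 0.474, 0.185, 0.051]),
            [0.0, float(ln(1.30)), float(ln(1.26)), float(ln(1.42))],
        ),
        "occupation": CovariateSpec(
            ["Others", "Combat specialists", "Health care specialists"],
            _norm([0.699, 0.200, 0.104]),
            [0.0, float(ln(1.07)), float(ln(0.90))],
        ),
        "general_health": CovariateSpec(
            ["Very good/excellent", "Good", "Fair/poor", "Missing"],
            _norm([0.590, 0.303, 0.077, 0.030]),
            [0.0, float(ln(1.55)), float(ln(3.0)), 0.0],
        ),
    }
    strata = CovariateSpec(
        ["Panel 1 baseline", "Panel 1 follow-up", "Panel 2 baseline"],
        _norm([0.472, 0.337, 0.191]),
        [0.0, 0.0, 0.0],
    )
    # intercept set so the marginal response rate is ~0.38, the share of
    # surveys with any open-ended response in large cohort questionnaires
    cfg = PropensityConfig(covariates=cov, intercept=-0.86, strata=strata)
    cfg.validate()
    return cfg


def generate_participants(
    n: int, cfg: PropensityConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Participant table: independent covariates plus a Bernoulli `responded`
    flag from the logistic propensity model; `true_logit` retains the planted
    linear predictor."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or default_propensity_config()
    cfg.validate()
    rng = substream(seed, "participants")
    data: dict[str, np.ndarray] = {
        "participant_id": np.array([f"p{i:07d}" for i in range(n)])
    }
    logit = np.full(n, cfg.intercept)
    for name, spec in cfg.covariates.items():
        idx = rng.choice(len(spec.levels), size=n, p=spec.margins)
        data[name] = np.asarray(spec.levels, dtype=object)[idx]
        logit += np.asarray(spec.coefficients)[idx]
    if cfg.strata is not None:
        sidx = rng.choice(len(cfg.strata.levels), size=n, p=cfg.strata.margins)
        data["stratum"] = np.asarray(cfg.strata.levels, dtype=object)[sidx]
        logit += np.asarray(cfg.strata.coefficients)[sidx]
    prob = 1.0 / (1.0 + np.exp(-logit))
    data["responded"] = rng.random(n) < prob
    data["true_logit"] = logit
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# responses
# --------------------------------------------------------------------------

# Raw null variants the generator emits: casing/punctuation variants that
# all normalize into the shipped pattern bank.
_NULL_BANK = [
    "No", "no", "NO", "No.", "N/A", "n/a", "NA", "none", "None.", "NONE",
    "nothing", "Nothing to add.", "nothing to report", "Nothing else!",
    "no concerns", "No concerns at this time.", "no comment", "nope",
    "not at this time", "Not really.", "I have nothing to say",
    "all good", "I'm fine.", "fine", "negative", "No issues", "no problems",
    "see above", "Same as above", "not applicable",
]


@dataclass
class GroundTruth:
    """Planted labels for every generated response."""

    response_topic_labels: dict[str, tuple[str, ...]]
    null_flags: dict[str, bool]
    propensity_used: PropensityConfig | None = None

    def validate(self) -> None:
        for rid, flag in self.null_flags.items():
            if flag != (len(self.response_topic_labels[rid]) == 0):
                raise ValueError(f"null flag inconsistent with labels for {rid}")

    def single_topic_ids(self) -> list[str]:
        return [
            rid
            for rid, labels in self.response_topic_labels.items()
            if len(labels) == 1
        ]

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "response_topic_labels": {
                        k: list(v) for k, v in self.response_topic_labels.items()
                    },
                    "null_flags": self.null_flags,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(
            response_topic_labels={
                k: tuple(v) for k, v in d["response_topic_labels"].items()
            },
            null_flags=d["null_flags"],
        )


def generate_responses(
    participants: pd.DataFrame,
    topic_model: TopicModel | None = None,
    null_rate: float = 0.546,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One response per responding participant.

    With probability `null_rate` the response is a contentless string from the
    null bank; otherwise a topic-structured token sequence. The default
    null_rate reflects the observed share of open-ended responses that carry
    no information (54.6%).
    """
    if not 0.0 <= null_rate <= 1.0:
        raise ValueError("null_rate must be in [0, 1]")
    model = topic_model or default_topic_model()
    rng = substream(seed, "responses")
    responders = participants[participants["responded"]]
    n = len(responders)
    rows = []
    labels: dict[str, tuple[str, ...]] = {}
    null_flags: dict[str, bool] = {}
    lengths = _negbin_lengths(
        rng, n, model.response_length_mean, model.response_length_shape, minimum=3
    )
    is_null = rng.random(n) < null_rate
    for j, (_, p) in enumerate(responders.iterrows()):
        rid = f"r{j:07d}"
        if is_null[j]:
            text = _NULL_BANK[rng.integers(len(_NULL_BANK))]
            labels[rid] = ()
            null_flags[rid] = True
        else:
            topic_idx = _draw_topics(rng, model)
            text = " ".join(_sample_doc(rng, model, topic_idx, int(lengths[j])))
            labels[rid] = tuple(model.topics[ti].label for ti in topic_idx)
            null_flags[rid] = False
        rows.append(
            {
                "response_id": rid,
                "participant_id": p["participant_id"],
                "stratum": p.get("stratum", "all"),
                "text": text,
            }
        )
    columns = ["response_id", "participant_id", "stratum", "text"]
    responses = pd.DataFrame(rows, columns=columns)
    truth = GroundTruth(response_topic_labels=labels, null_flags=null_flags)
    truth.validate()
    return responses, truth


# --------------------------------------------------------------------------
# planted-structure evaluation
# --------------------------------------------------------------------------

def match_topics_to_clusters(clustering, terms: list[str], model: TopicModel) -> dict[str, int]:
    """Map each topic to the cluster holding the plurality of its exclusive
    seed terms (among the clustering terms); topics with no seed term in the
    clustering vocabulary are omitted."""
    term_to_cluster = {t: int(c) for t, c in zip(terms, clustering.assignment)}
    mapping: dict[str, int] = {}
    for topic in model.topics:
        votes: dict[int, int] = {}
        for s in topic.seed_terms:
            c = term_to_cluster.get(s)
            if c is not None:
                votes[c] = votes.get(c, 0) + 1
        if votes:
            mapping[topic.label] = max(sorted(votes), key=votes.get)
    return mapping
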