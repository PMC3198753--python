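"""Ground-truthed generator: determinism, planted frequencies, propensity."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import concernminer as cm
from concernminer.synthetic import (
    CovariateSpec,
    PropensityConfig,
    default_propensity_config,
    default_topic_model,
)
from concernminer.text_prep import tokenize


class TestTopicModel:
    def test_distributions_normalized_and_seeds_exclusive(self, topic_model):
        topic_model.validate()  # raises on violation
        for t in topic_model.topics:
            assert abs(t.weights.sum() - 1.0) < 1e-9
            assert len(t.seed_terms) >= 5

    def test_marginal_token_probabilities_sum_to_one(self, topic_model):
        all_terms = set(topic_model.background_terms)
        for t in topic_model.topics:
            all_terms.update(t.terms)
        total = sum(topic_model.expected_token_probability(w) for w in all_terms)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestBackgroundDocs:
    def test_empty_request_rejected(self, topic_model):
        with pytest.raises(ValueError):
            cm.generate_background_docs(0, topic_model, seed=1)

    def test_same_seed_byte_identical(self, topic_model):
        a = cm.generate_background_docs(100, topic_model, seed=4)
        b = cm.generate_background_docs(100, topic_model, seed=4)
        assert a == b
        c = cm.generate_background_docs(100, topic_model, seed=5)
        assert a != c

    def test_every_exclusive_term_occurs(self, topic_model):
        docs = cm.generate_background_docs(50 * topic_model.n_topics, topic_model, 2)
        seen = set(" ".join(docs).split())
        for t in topic_model.topics:
            assert set(t.seed_terms) <= seen

    def test_seed_term_frequencies_match_compound_expectation(self, topic_model):
        """Observed per-seed-term counts versus a closed-form oracle.

        The oracle derives E and Var of a term's corpus count by the law of
        total variance over document length (truncated negative binomial),
        topic membership (single topic w.p. p_single, else one of two), and
        binomial token draws. Per-term |z| is bounded at 4, a family-wise
        bound across the ~72 simultaneous seed-term checks.
        """
        n_docs = 5000
        model = topic_model
        docs = cm.generate_background_docs(n_docs, model, seed=1)
        counts: dict[str, int] = {}
        for doc in docs:
            for tok in doc.split():
                counts[tok] = counts.get(tok, 0) + 1

        # truncated-NB moments: L = max(raw, 10)
        r, m = model.doc_length_shape, model.doc_length_mean
        nb = scipy.stats.nbinom(r, r / (r + m))
        ls = np.arange(0, 2000)
        pmf = nb.pmf(ls)
        lt = np.maximum(ls, 10)
        e_l = float(np.sum(lt * pmf))
        e_l2 = float(np.sum(lt.astype(float) ** 2 * pmf))

        tau, ps, K = model.topic_share, model.p_single, model.n_topics
        p1, p2 = ps / K, (1 - ps) * 2 / K
        for topic in model.topics:
            for s in topic.seed_terms:
                w = topic.term_probability(s)
                q1, q2 = tau * w, tau * w / 2
                mean_c = p1 * e_l * q1 + p2 * e_l * q2
                e_c2 = p1 * (e_l * q1 * (1 - q1) + e_l2 * q1**2) + p2 * (
                    e_l * q2 * (1 - q2) + e_l2 * q2**2
                )
                var_c = e_c2 - mean_c**2
                z = (counts.get(s, 0) - n_docs * mean_c) / np.sqrt(n_docs * var_c)
                assert abs(z) <= 4.0, f"{s}: z={z:.2f}"


class TestParticipants:
    def test_margin_validation(self):
        bad = PropensityConfig(
            covariates={
                "x": CovariateSpec(["a", "b"], [0.6, 0.6], [0.0, 1.0]),
            },
            intercept=0.0,
        )
        with pytest.raises(ValueError):
            cm.generate_participants(10, bad, seed=0)

    def test_reference_coefficient_must_be_zero(self):
        bad = PropensityConfig(
            covariates={"x": CovariateSpec(["a", "b"], [0.5, 0.5], [0.2, 1.0])},
            intercept=0.0,
        )
        with pytest.raises(ValueError):
            cm.generate_participants(10, bad, seed=0)

    def test_null_model_gives_half_response(self):
        cfg = PropensityConfig(
            covariates={"x": CovariateSpec(["a", "b"], [0.5, 0.5], [0.0, 0.0])},
            intercept=0.0,
        )
        n = 4000
        parts = cm.generate_participants(n, cfg, seed=6)
        frac = parts["responded"].mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_same_seed_identical_tables(self):
        a = cm.generate_participants(500, seed=8)
        b = cm.generate_participants(500, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_margins_match_configured(self):
        """Empirical level frequencies against configured margins; |z| <= 4
        is a family-wise bound over the ~34 simultaneous level checks."""
        cfg = default_propensity_config()
        n = 20000
        parts = cm.generate_participants(n, cfg, seed=10)
        for name, spec in cfg.covariates.items():
            for level, margin in zip(spec.levels, spec.margins):
                obs = (parts[name] == level).mean()
                se = np.sqrt(margin * (1 - margin) / n)
                assert abs(obs - margin) <= 4 * se + 1e-9, (name, level)

    def test_fair_poor_health_odds_ratio_envelope(self):
        """With only the health coefficients nonzero, the marginal empirical
        odds ratio fair/poor vs reference must sit in the 3-SE envelope
        around the planted odds ratio of 3."""
        base = default_propensity_config()
        cov = {
            name: CovariateSpec(s.levels, s.margins, [0.0] * len(s.levels))
            for name, s in base.covariates.items()
        }
        cov["general_health"] = base.covariates["general_health"]
        cfg = PropensityConfig(covariates=cov, intercept=base.intercept)
        parts = cm.generate_participants(10000, cfg, seed=12)
        fp = parts[parts["general_health"] == "Fair/poor"]
        ref = parts[parts["general_health"] == "Very good/excellent"]
        a, b = fp["responded"].sum(), (~fp["responded"]).sum()
        c, d = ref["responded"].sum(), (~ref["responded"]).sum()
        orr = (a * d) / (b * c)
        assert 2.4 <= orr <= 3.75


class TestResponses:
    def test_null_rate_bounds_enforced(self, topic_model):
        parts = cm.generate_participants(50, seed=1)
        with pytest.raises(ValueError):
            cm.generate_responses(parts, topic_model, 1.2, seed=1)

    def test_boundary_rates(self, topic_model):
        parts = cm.generate_participants(400, seed=2)
        all_null, truth1 = cm.generate_responses(parts, topic_model, 1.0, seed=2)
        assert all(truth1.null_flags.values())
        none_null, truth0 = cm.generate_responses(parts, topic_model, 0.0, seed=2)
        assert not any(truth0.null_flags.values())
        assert all(len(v) >= 1 for v in truth0.response_topic_labels.values())

    def test_null_fraction_envelope(self, topic_model):
        parts = cm.generate_participants(25000, seed=3)
        responses, truth = cm.generate_responses(parts, topic_model, 0.546, seed=3)
        n = len(responses)
        frac = np.mean(list(truth.null_flags.values()))
        assert abs(frac - 0.546) <= 3 * np.sqrt(0.546 * 0.454 / n)

    def test_null_flags_iff_empty_labels(self, small_run):
        small_run["truth"].validate()

    def test_only_responders_get_responses(self, small_run):
        parts = small_run["participants"]
        responders = set(parts.loc[parts["responded"], "participant_id"])
        assert set(small_run["responses"]["participant_id"]) == responders

    def test_meaningful_texts_use_topic_and_background_terms(
        self, small_run, topic_model
    ):
        legal = set(topic_model.background_terms)
        for t in topic_model.topics:
            legal.update(t.terms)
        for text, rid in zip(
            small_run["responses"]["text"], small_run["responses"]["response_id"]
        ):
            if not small_run["truth"].null_flags[rid]:
                assert set(tokenize(str(text))) <= legal
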