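"""Clustering-term selection, cosine distance matrix, and PAM k-medoids."""

import itertools

import numpy as np
import pytest

import concernminer as cm
from concernminer.synthetic import match_topics_to_clusters
from concernminer.term_clustering import (
    build_distance_matrix,
    describe_clusters,
    pam_cluster,
    select_cluster_terms,
)


def brute_force_kmedoids(dist: np.ndarray, k: int):
    """Exhaustive enumeration over all medoid subsets (oracle, tiny n only)."""
    n = len(dist)
    best_cost, best_medoids = np.inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = dist[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, medoids
    return np.array(best_medoids), best_cost


class TestSelectTerms:
    def test_empty_response_set(self):
        with pytest.warns(UserWarning):
            terms = select_cluster_terms([], min_freq=70)
        assert len(terms) == 0

    def test_strict_threshold_and_stoplist(self):
        texts = (
            ["pain"] * 71 + ["the"] * 500 + ["knee"] * 70
        )  # one word per response
        terms = select_cluster_terms(texts, min_freq=70)
        assert terms.terms == ["pain"]
        assert terms.frequency == {"pain": 71}

    def test_token_count_not_document_frequency(self):
        texts = ["ache ache ache"] * 30  # 90 tokens in 30 responses
        terms = select_cluster_terms(texts, min_freq=70)
        assert terms.terms == ["ache"]

    def test_vocabulary_restriction(self):
        texts = ["mystery"] * 80
        terms = select_cluster_terms(texts, min_freq=70, vocabulary={"other"})
        assert len(terms) == 0

    def test_invalid_min_freq(self):
        with pytest.raises(ValueError):
            select_cluster_terms(["a"], min_freq=0)


class TestDistanceMatrix:
    def test_matches_bruteforce_pairwise_cosines(self, small_run):
        terms = small_run["terms"]
        space = small_run["space"]
        sub_terms = terms.terms[:30]
        sub = type(terms)(terms=sub_terms, frequency=terms.frequency)
        dist = build_distance_matrix(space, sub)
        for i, ti in enumerate(sub_terms):
            for j, tj in enumerate(sub_terms):
                expected = 1.0 - cm.cosine(
                    space.term_vector(ti, scaled=True),
                    space.term_vector(tj, scaled=True),
                )
                if i == j:
                    expected = 0.0
                assert abs(dist[i, j] - expected) < 1e-12

    def test_symmetric_zero_diagonal_bounded(self, small_run):
        dist = small_run["dist"]
        assert np.allclose(dist, dist.T, atol=1e-12)
        assert np.allclose(np.diag(dist), 0.0)
        assert dist.min() >= 0.0 and dist.max() <= 2.0

    def test_missing_term_named_in_error(self, small_run):
        terms = small_run["terms"]
        bad = type(terms)(terms=["notinspace"], frequency={"notinspace": 99})
        with pytest.raises(ValueError, match="notinspace"):
            build_distance_matrix(small_run["space"], bad)


class TestPAM:
    def test_k_equals_n_costs_zero(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 2))
        dist = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
        np.fill_diagonal(dist, 0)
        c = pam_cluster(dist, 6)
        assert c.total_cost == 0.0
        assert sorted(c.medoids) == list(range(6))

    def test_k1_matches_linear_scan(self):
        rng = np.random.default_rng(2)
        pts = rng.random(9)
        dist = np.abs(pts[:, None] - pts[None, :])
        c = pam_cluster(dist, 1)
        assert c.medoids[0] == int(np.argmin(dist.sum(axis=1)))
        assert c.total_cost == pytest.approx(dist[c.medoids[0]].sum())

    def test_two_separated_groups_recovered_exactly(self):
        """Eight points on a line in two tight groups: PAM must match the
        enumeration optimum, partitioning the groups."""
        pts = np.array([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 10.2, 10.3])
        dist = np.abs(pts[:, None] - pts[None, :])
        c = pam_cluster(dist, 2)
        medoids, cost = brute_force_kmedoids(dist, 2)
        assert c.total_cost == pytest.approx(cost, abs=1e-12)
        groups = {tuple(sorted(c.members(m))) for m in c.medoids}
        assert groups == {(0, 1, 2, 3), (4, 5, 6, 7)}

    @pytest.mark.parametrize("seed", range(12))
    def test_near_optimal_on_random_instances(self, seed):
        """PAM is a heuristic: on every tiny instance its cost must be within
        5% of the exhaustive optimum (exact on most)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        k = int(rng.integers(1, 4))
        pts = rng.random((n, 3))
        dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(dist, 0)
        c = pam_cluster(dist, k)
        _, opt = brute_force_kmedoids(dist, k)
        assert c.total_cost <= 1.05 * opt + 1e-12

    def test_deterministic_and_exhaustive(self, small_run):
        dist = small_run["dist"]
        a = pam_cluster(dist, 12)
        b = pam_cluster(dist, 12)
        assert np.array_equal(a.medoids, b.medoids)
        assert np.array_equal(a.assignment, b.assignment)
        # exhaustive, non-overlapping, medoids self-assigned
        assert set(a.assignment) <= set(a.medoids)
        assert len(a.assignment) == len(dist)
        assert all(a.assignment[m] == m for m in a.medoids)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((3, 3)), 4)

    def test_swap_phase_never_worse_than_build(self, small_run):
        """Final cost is a lower bound certificate: re-assigning points to
        the reported medoids reproduces total_cost exactly."""
        c = small_run["clustering"]
        dist = small_run["dist"]
        recomputed = dist[:, c.medoids].min(axis=1).sum()
        assert c.total_cost == pytest.approx(recomputed, abs=1e-9)


class TestDescribe:
    def test_singleton_cluster_summary(self):
        dist = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.1], [1.0, 0.1, 0.0]])
        c = pam_cluster(dist, 2)
        summary = describe_clusters(c, dist, ["a", "b", "c"], top_m=5)
        sizes = dict(zip(summary["medoid"], summary["size"]))
        singletons = summary[summary["size"] == 1]
        assert (singletons["top_terms"] == "").all()
        assert sizes["a"] == 1

    def test_excluded_clusters_flagged(self, small_run):
        c = small_run["clustering"]
        excluded = {int(c.medoids[0])}
        summary = describe_clusters(
            c, small_run["dist"], small_run["terms"].terms, excluded=excluded
        )
        assert summary.loc[summary["cluster_id"] == c.medoids[0], "excluded"].all()
        assert not summary.loc[summary["cluster_id"] != c.medoids[0], "excluded"].any()

    def test_planted_seed_terms_cocluster(self, small_run, topic_model):
        """For >= 80% of topics, the topic's seed terms that survived term
        selection should land in a single cluster."""
        c = small_run["clustering"]
        terms = small_run["terms"].terms
        term_to_cluster = dict(zip(terms, c.assignment))
        ok = total = 0
        for topic in topic_model.topics:
            present = [s for s in topic.seed_terms if s in term_to_cluster]
            if len(present) < 2:
                continue
            total += 1
            clusters = {term_to_cluster[s] for s in present}
            ok += len(clusters) == 1
        assert total >= 8
        assert ok / total >= 0.8

    def test_topic_cluster_map_covers_topics(self, small_run, topic_model):
        mapping = match_topics_to_clusters(
            small_run["clustering"], small_run["terms"].terms, topic_model
        )
        assert len(mapping) >= 10
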