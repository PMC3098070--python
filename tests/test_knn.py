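"""Voting KNN: exhaustive scan vs cached batch path, ties, determinism."""

import numpy as np
import pytest

from triadnet.dataset import NETWORKING, NON_NETWORKING, Triad
from triadnet.knn import SimilarityCache, k_nearest, predict, predict_batch
from triadnet.metric import MetricConfig
from triadnet.similarity import enzyme_kernel_from_profiles
from triadnet.synthetic import build_dataset


def constant_kernel(value):
    def kernel(a, b):
        return 1.0 if a == b else value

    return kernel


def make_training(compound_sims):
    """Training triads whose distance to query (q,e,q2) is controlled per-triad.

    Each training triad i uses its own substrate/product ids with a preset
    similarity to the query's, and the shared enzyme (similarity 1), so the
    distance at w=1/4 is 0.75 * (1 - sim_i).
    """
    triads = []
    sims = {}
    for i, (sim, label) in enumerate(compound_sims):
        triads.append(Triad(f"s{i}", "e", f"p{i}", label))
        sims[frozenset(("qs", f"s{i}"))] = sim
        sims[frozenset(("qp", f"p{i}"))] = sim

    def compound_kernel(a, b):
        if a == b:
            return 1.0
        return sims.get(frozenset((a, b)), 0.0)

    return triads, compound_kernel, constant_kernel(1.0)


QUERY = Triad("qs", "e", "qp")
CFG = MetricConfig(w=0.25)


class TestKNearest:
    def test_identical_training_triad_at_distance_zero(self):
        triads, ck, ek = make_training([(0.5, NETWORKING)])
        training = [QUERY._replace(label=NETWORKING)] + triads
        (rec,) = k_nearest(QUERY, training, 1, CFG, ck, ek)
        assert rec.training_index == 0
        assert rec.distance == 0.0

    def test_k_smallest_by_bruteforce_construction(self):
        # distances 0.75*(1-sim): sims 0.9/0.8/0.6 -> 0.075/0.15/0.3
        triads, ck, ek = make_training(
            [(0.9, NETWORKING), (0.8, NON_NETWORKING), (0.6, NETWORKING)]
        )
        recs = k_nearest(QUERY, triads, 2, CFG, ck, ek)
        assert [r.training_index for r in recs] == [0, 1]
        assert recs[0].distance == pytest.approx(0.075)
        assert recs[1].distance == pytest.approx(0.15)

    def test_equal_distance_tie_broken_by_lower_index(self):
        triads, ck, ek = make_training([(0.7, NON_NETWORKING), (0.7, NETWORKING)])
        (rec,) = k_nearest(QUERY, triads, 1, CFG, ck, ek)
        assert rec.training_index == 0

    def test_k_exceeding_training_rejected(self):
        triads, ck, ek = make_training([(0.5, NETWORKING)])
        with pytest.raises(ValueError, match="K must satisfy"):
            k_nearest(QUERY, triads, 2, CFG, ck, ek)

    def test_records_sorted_ascending(self):
        triads, ck, ek = make_training(
            [(0.5, NETWORKING), (0.95, NETWORKING), (0.7, NON_NETWORKING)]
        )
        recs = k_nearest(QUERY, triads, 3, CFG, ck, ek)
        dists = [r.distance for r in recs]
        assert dists == sorted(dists)


class TestPredict:
    def test_k1_nearest_label(self):
        triads, ck, ek = make_training([(0.9, NETWORKING), (0.5, NON_NETWORKING)])
        assert predict(QUERY, triads, 1, CFG, ck, ek) == NETWORKING

    def test_k3_majority(self):
        triads, ck, ek = make_training(
            [(0.9, NETWORKING), (0.8, NON_NETWORKING), (0.7, NON_NETWORKING)]
        )
        assert predict(QUERY, triads, 3, CFG, ck, ek) == NON_NETWORKING

    def test_even_k_tie_resolved_by_nearest(self):
        triads, ck, ek = make_training([(0.9, NON_NETWORKING), (0.8, NETWORKING)])
        assert predict(QUERY, triads, 2, CFG, ck, ek) == NON_NETWORKING


@pytest.fixture(scope="module")
def instance(small_config, small_benchmark):
    """~480 training triads, 54 queries, both classes represented."""
    store, profiles, positives = small_benchmark
    dataset = build_dataset(small_config, store, positives)
    queries, true_labels = dataset.test_triads_labels()
    training, _ = dataset.training_triads_labels()
    cache = SimilarityCache.from_kernels(
        queries + training, store.similarity, enzyme_kernel_from_profiles(profiles)
    )
    return store, profiles, dataset, queries, cache


class TestBatch:
    def test_batch_equals_exhaustive_scan(self, instance):
        store, profiles, dataset, queries, cache = instance
        ek = enzyme_kernel_from_profiles(profiles)
        for K in (1, 3):
            result = predict_batch(queries, dataset, K, CFG, cache)
            training, _ = dataset.training_triads_labels()
            scan = [predict(q, training, K, CFG, store.similarity, ek) for q in queries]
            assert list(result.labels) == scan

    def test_batch_nearest_distance_equals_scan(self, instance):
        store, profiles, dataset, queries, cache = instance
        ek = enzyme_kernel_from_profiles(profiles)
        result = predict_batch(queries, dataset, 1, CFG, cache)
        training, _ = dataset.training_triads_labels()
        for i, q in enumerate(queries[:10]):
            (rec,) = k_nearest(q, training, 1, CFG, store.similarity, ek)
            assert result.nearest_distance[i] == rec.distance

    def test_batch_of_one_equals_predict(self, instance):
        store, profiles, dataset, queries, cache = instance
        ek = enzyme_kernel_from_profiles(profiles)
        training, _ = dataset.training_triads_labels()
        result = predict_batch(queries[:1], dataset, 3, CFG, cache)
        assert result.labels[0] == predict(queries[0], training, 3, CFG, store.similarity, ek)

    def test_empty_batch(self, instance):
        _, _, dataset, _, cache = instance
        result = predict_batch([], dataset, 1, CFG, cache)
        assert len(result.labels) == 0

    def test_determinism(self, instance):
        _, _, dataset, queries, cache = instance
        a = predict_batch(queries, dataset, 3, CFG, cache)
        b = predict_batch(queries, dataset, 3, CFG, cache)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.nearest_distance, b.nearest_distance)

    def test_cache_miss_names_missing_id(self, instance):
        _, _, dataset, queries, cache = instance
        alien = Triad("C9999x", "E0000", "C0001")
        with pytest.raises(KeyError, match="C9999x"):
            predict_batch([alien], dataset, 1, CFG, cache)

    def test_pn_distances_bracket_nearest(self, instance):
        _, _, dataset, queries, cache = instance
        r = predict_batch(queries, dataset, 1, CFG, cache)
        near = np.minimum(r.nearest_positive_distance, r.nearest_negative_distance)
        assert np.array_equal(near, r.nearest_distance)
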