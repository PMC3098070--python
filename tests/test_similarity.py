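"""Similarity kernels: cosine over domain sets, floored compound scores, Tanimoto."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadnet.similarity import (
    CompoundSimilarityStore,
    DomainProfile,
    compound_similarity,
    domain_cosine_similarity,
    enzyme_kernel_from_profiles,
    normalize_smiles_score,
    tanimoto_bitvector,
)


def profile(*domains):
    return DomainProfile("E", frozenset(domains))


class TestDomainCosine:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"IPR001", "IPR002"}, {"IPR001", "IPR002"}, 1.0),
            ({"IPR001"}, {"IPR002"}, 0.0),
            ({"IPR001", "IPR002"}, {"IPR002", "IPR003"}, 0.5),
            ({"IPR001"}, {"IPR001", "IPR002", "IPR003", "IPR004"}, 0.5),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert domain_cosine_similarity(profile(*a), profile(*b)) == pytest.approx(expected)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty functional-domain"):
            domain_cosine_similarity(profile(), profile("IPR001"))

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_matches_dense_vector_oracle(self, a, b):
        """Set-based cosine equals the brute-force binary-vector cosine."""
        va = np.zeros(31)
        vb = np.zeros(31)
        va[list(a)] = 1
        vb[list(b)] = 1
        oracle = float(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
        got = domain_cosine_similarity(profile(*map(str, a)), profile(*map(str, b)))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert 0.0 <= got <= 1.0
        assert got == domain_cosine_similarity(profile(*map(str, b)), profile(*map(str, a)))

    def test_one_iff_equal_sets(self):
        assert domain_cosine_similarity(profile("a", "b"), profile("b", "a")) == 1.0
        assert domain_cosine_similarity(profile("a", "b"), profile("a", "b", "c")) < 1.0


class TestCompoundStore:
    def make_store(self, **entries_kw):
        store = CompoundSimilarityStore(floor=0.4)
        for c in ("C1", "C2", "C3"):
            store.add_compound(c)
        return store

    def test_self_similarity_is_one(self):
        store = self.make_store()
        assert compound_similarity("C1", "C1", store) == 1.0

    def test_floor_rule(self):
        store = self.make_store()
        store.add_entry("C1", "C2", 0.39)
        store.add_entry("C1", "C3", 0.44)
        assert store.similarity("C1", "C2") == 0.0
        assert store.similarity("C1", "C3") == 0.44

    def test_missing_pair_served_as_zero(self):
        store = self.make_store()
        assert store.similarity("C2", "C3") == 0.0

    def test_symmetry(self):
        store = self.make_store()
        store.add_entry("C1", "C2", 0.7)
        assert store.similarity("C1", "C2") == store.similarity("C2", "C1") == 0.7

    def test_unknown_compound_named_in_error(self):
        store = self.make_store()
        with pytest.raises(KeyError, match="CX"):
            store.similarity("C1", "CX")

    def test_conflicting_duplicate_rejected_equal_tolerated(self):
        store = self.make_store()
        store.add_entry("C1", "C2", 0.5)
        store.add_entry("C2", "C1", 0.5)  # symmetric duplicate, same score
        with pytest.raises(ValueError, match="conflicting"):
            store.add_entry("C1", "C2", 0.6)

    def test_self_score_not_one_rejected(self):
        store = self.make_store()
        with pytest.raises(ValueError, match="must be 1"):
            store.add_entry("C1", "C1", 0.9)

    def test_refloor_without_reload(self):
        store = self.make_store()
        store.add_entry("C1", "C2", 0.45)
        assert store.similarity("C1", "C2") == 0.45
        store.floor = 0.5
        assert store.similarity("C1", "C2") == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(score=st.floats(0.0, 1.0))
    def test_served_scores_zero_or_above_floor(self, score):
        store = CompoundSimilarityStore(compound_ids=["A", "B"], floor=0.4)
        if score == 1.0:
            return  # self-score semantics only
        store.add_entry("A", "B", score)
        served = store.similarity("A", "B")
        assert served == 0.0 or 0.4 <= served <= 1.0


class TestScoreNormalisation:
    @pytest.mark.parametrize("raw, expected", [(1000, 1.0), (0, 0.0), (440, 0.44)])
    def test_rescale(self, raw, expected):
        assert normalize_smiles_score(raw) == pytest.approx(expected)

    @pytest.mark.parametrize("raw", [-1, 1001])
    def test_out_of_range(self, raw):
        with pytest.raises(ValueError):
            normalize_smiles_score(raw)


class TestTanimoto:
    def bits(self, positions, n=8):
        v = np.zeros(n, dtype=bool)
        v[list(positions)] = True
        return v

    def test_identical(self):
        assert tanimoto_bitvector(self.bits({1, 4}), self.bits({1, 4})) == 1.0

    def test_disjoint(self):
        assert tanimoto_bitvector(self.bits({0, 1}), self.bits({2, 3})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto_bitvector(self.bits({1, 2, 3}), self.bits({2, 3, 4})) == 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto_bitvector(self.bits(set()), self.bits({1}))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_bitvector(self.bits({1}, n=8), self.bits({1}, n=9))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.sets(st.integers(0, 15), min_size=1),
        b=st.sets(st.integers(0, 15), min_size=1),
    )
    def test_matches_set_enumeration_and_symmetry(self, a, b):
        va, vb = self.bits(a, 16), self.bits(b, 16)
        assert tanimoto_bitvector(va, vb) == len(a & b) / len(a | b)
        assert tanimoto_bitvector(va, vb) == tanimoto_bitvector(vb, va)


def test_enzyme_kernel_names_unknown_id():
    profiles = {"E1": DomainProfile("E1", frozenset({"D1"}))}
    kernel = enzyme_kernel_from_profiles(profiles)
    assert kernel("E1", "E1") == 1.0
    with pytest.raises(KeyError, match="EX"):
        kernel("E1", "EX")
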