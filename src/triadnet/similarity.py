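"""Pairwise similarity kernels for compounds and enzymes.

Two kinds of molecular similarity feed the triad metric:

* **Compound similarity** is consumed as precomputed pairwise scores in
  [0, 1] (e.g. 2D molecular-graph alignment scores, or fingerprint
  Tanimoto scores exported on a 0-1000 scale and normalised by 1000).
  Scores below a floor (default 0.4, matching the cutoff below which
  graph-alignment servers report nothing) are served as 0.

* **Enzyme similarity** is the cosine of two binary functional-domain
  vectors: a protein is encoded as the set of functional-domain
  accessions (InterPro-style) it hits, and the cosine of two such
  binary vectors reduces to ``|A ∩ B| / sqrt(|A| |B|)``.

A self-contained Tanimoto kernel on caller-supplied bit vectors is
provided so the pipeline can run end-to-end without external similarity
services.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainProfile",
    "CompoundSimilarityStore",
    "domain_cosine_similarity",
    "compound_similarity",
    "normalize_smiles_score",
    "tanimoto_bitvector",
    "enzyme_kernel_from_profiles",
]

DEFAULT_FLOOR = 0.4


@dataclass(frozen=True)
class DomainProfile:
    """An enzyme's functional-domain composition.

    The sparse realisation of the binary domain-hit vector: only the
    accessions with a hit are stored.  Enzymes with an empty profile
    carry no functional-domain information and must be filtered out
    before dataset assembly; the cosine kernel refuses them.
    """

    enzyme_id: str
    domains: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", frozenset(self.domains))

    def __len__(self) -> int:
        return len(self.domains)


def domain_cosine_similarity(p1: DomainProfile, p2: DomainProfile) -> float:
    """Cosine similarity of two binary functional-domain vectors.

    For binary vectors the dot product is the intersection size and the
    modulus the square root of the set size, so the cosine is
    ``|A ∩ B| / (sqrt(|A|) * sqrt(|B|))``.

    Raises
    ------
    ValueError
        If either profile is empty (such enzymes should have been
        removed at load time).
    """
    for p in (p1, p2):
        if len(p.domains) == 0:
            raise ValueError(
                f"enzyme {p.enzyme_id!r} has an empty functional-domain "
                "profile; it should have been filtered out at load time"
            )
    inter = len(p1.domains & p2.domains)
    if inter == 0:
        return 0.0
    # sqrt of the product, not product of sqrts: exact (1.0) for equal sets
    return inter / math.sqrt(len(p1.domains) * len(p2.domains))


class CompoundSimilarityStore:
    """Sparse symmetric map of pairwise compound similarity scores.

    Scores are stored unfloored; the floor is applied when a score is
    served, so the same store can be re-floored without re-reading the
    input.  Self-similarity is hard-wired to 1 and a pair with no
    stored entry is served as 0 (sparse absence means "no detectable
    similarity", consistent with sources that only report scores above
    the floor).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], float] | None = None,
        compound_ids: Iterable[str] = (),
        floor: float = DEFAULT_FLOOR,
    ) -> None:
        if not 0.0 <= floor <= 1.0:
            raise ValueError(f"floor must lie in [0, 1], got {floor}")
        self.floor = floor
        self._entries: dict[tuple[str, str], float] = {}
        self._ids: set[str] = set(compound_ids)
        if entries:
            for (c1, c2), score in entries.items():
                self.add_entry(c1, c2, score)

    # -- construction -------------------------------------------------

    @staticmethod
    def _key(c1: str, c2: str) -> tuple[str, str]:
        return (c1, c2) if c1 <= c2 else (c2, c1)

    def add_compound(self, compound_id: str) -> None:
        self._ids.add(compound_id)

    def add_entry(self, c1: str, c2: str, score: float) -> None:
        """Register a symmetric pairwise score (unfloored).

        Duplicate records with equal scores are tolerated; conflicting
        duplicates and self-scores different from 1 are load errors.
        """
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"similarity score for ({c1!r}, {c2!r}) out of [0, 1]: {score}"
            )
        if c1 == c2:
            if score != 1.0:
                raise ValueError(
                    f"self-similarity for {c1!r} must be 1, got {score}"
                )
            self._ids.add(c1)
            return
        key = self._key(c1, c2)
        old = self._entries.get(key)
        if old is not None and old != score:
            raise ValueError(
                f"conflicting duplicate scores for pair {key}: {old} vs {score}"
            )
        self._entries[key] = score
        self._ids.update(key)

    # -- queries ------------------------------------------------------

    @property
    def compound_ids(self) -> frozenset[str]:
        return frozenset(self._ids)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._ids

    def __len__(self) -> int:
        return len(self._entries)

    def raw_score(self, c1: str, c2: str) -> float | None:
        """The stored (unfloored) score, or None if no entry exists."""
        return self._entries.get(self._key(c1, c2))

    def similarity(self, c1: str, c2: str) -> float:
        """Serve the floored similarity between two known compounds.

        Returns 1 for identical ids, 0 for absent pairs and for stored
        scores below the floor, the stored score otherwise.
        """
        for c in (c1, c2):
            if c not in self._ids:
                raise KeyError(f"unknown compound id {c!r}")
        if c1 == c2:
            return 1.0
        score = self._entries.get(self._key(c1, c2))
        if score is None or score < self.floor:
            return 0.0
        return score

    def items(self):
        """Iterate stored (c1, c2) -> raw score entries (c1 <= c2)."""
        return self._entries.items()


def compound_similarity(c1: str, c2: str, store: CompoundSimilarityStore) -> float:
    """Floored compound similarity served from a store (see the store)."""
    return store.similarity(c1, c2)


def normalize_smiles_score(raw: float) -> float:
    """Rescale a fingerprint-Tanimoto score exported on 0-1000 to [0, 1].

    Applied before any floor: the floor acts on the [0, 1] scale.
    """
    if not 0 <= raw <= 1000:
        raise ValueError(f"raw fingerprint score must lie in [0, 1000], got {raw}")
    return raw / 1000


def enzyme_kernel_from_profiles(profiles: Mapping[str, DomainProfile]):
    """A (enzyme_id, enzyme_id) -> cosine kernel over a profile mapping.

    Unknown enzyme ids raise KeyError naming the id.
    """

    def kernel(e1: str, e2: str) -> float:
        for e in (e1, e2):
            if e not in profiles:
                raise KeyError(f"unknown enzyme id {e!r}")
        return domain_cosine_similarity(profiles[e1], profiles[e2])

    return kernel


def tanimoto_bitvector(f1, f2) -> float:
    """Tanimoto coefficient |A ∩ B| / |A ∪ B| of two equal-length bit vectors.

    A built-in fallback for self-contained runs when no precomputed
    compound scores are supplied.  Inputs are anything ``numpy`` can
    coerce to a boolean vector.
    """
    a = np.asarray(f1, dtype=bool)
    b = np.asarray(f2, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"fingerprints must be equal-length vectors, got {a.shape} and {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("all-zero fingerprint has no defined Tanimoto similarity")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return inter / union
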