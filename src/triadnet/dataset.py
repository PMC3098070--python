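"""Labelled triad benchmark assembly.

A *triad* is an ordered (substrate, enzyme, product) triple; it is
*networking* (positive) if the enzyme catalyses the substrate-to-product
transformation, *non-networking* (negative) otherwise.  Benchmarks pair
a curated positive list with randomly sampled negatives at a configurable
imbalance ratio (50:1 by default, reflecting that true reactions are a
tiny fraction of possible triples), and a random per-class hold-out
split.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NETWORKING",
    "NON_NETWORKING",
    "Triad",
    "TriadDataset",
    "read_triads",
    "write_triads",
    "sample_random_triads",
    "sample_negative_triads",
    "split_train_test",
]

#: Class labels: networking (positive) = 1, non-networking (negative) = 0.
NETWORKING = 1
NON_NETWORKING = 0


class Triad(NamedTuple):
    """Ordered (substrate, enzyme, product) triple with an optional label."""

    substrate: str
    enzyme: str
    product: str
    label: int | None = None

    @property
    def ids(self) -> tuple[str, str, str]:
        """The identifying (substrate, enzyme, product) triple, label-free."""
        return (self.substrate, self.enzyme, self.product)


def _check_unique(triads: Sequence[Triad], what: str) -> None:
    seen = set()
    for t in triads:
        if t.ids in seen:
            raise ValueError(f"duplicate triad in {what}: {t.ids}")
        seen.add(t.ids)


@dataclass
class TriadDataset:
    """Positive and negative triad collections with an optional split.

    ``partition`` maps each class to (train_indices, test_indices) into
    that class's collection; together they cover the class exactly once.
    """

    positives: list[Triad]
    negatives: list[Triad]
    partition: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.positives, "positives")
        _check_unique(self.negatives, "negatives")
        overlap = {t.ids for t in self.positives} & {t.ids for t in self.negatives}
        if overlap:
            raise ValueError(
                f"{len(overlap)} triads appear in both classes, e.g. {next(iter(overlap))}"
            )
        if self.partition is not None:
            for cls, coll in ((NETWORKING, self.positives), (NON_NETWORKING, self.negatives)):
                train, test = self.partition[cls]
                combined = np.concatenate([train, test])
                if not np.array_equal(np.sort(combined), np.arange(len(coll))):
                    raise ValueError(
                        f"partition for class {cls} does not cover the class exactly once"
                    )

    def _class(self, label: int) -> list[Triad]:
        return self.positives if label == NETWORKING else self.negatives

    def _part(self, label: int, which: int) -> list[Triad]:
        if self.partition is None:
            raise ValueError("dataset has no train/test partition; call split_train_test first")
        idx = self.partition[label][which]
        coll = self._class(label)
        return [coll[i] for i in idx]

    @property
    def train_positives(self) -> list[Triad]:
        return self._part(NETWORKING, 0)

    @property
    def train_negatives(self) -> list[Triad]:
        return self._part(NON_NETWORKING, 0)

    @property
    def test_positives(self) -> list[Triad]:
        return self._part(NETWORKING, 1)

    @property
    def test_negatives(self) -> list[Triad]:
        return self._part(NON_NETWORKING, 1)

    def training_triads_labels(self) -> tuple[list[Triad], np.ndarray]:
        """All training triads (positives first) with their labels."""
        triads = self.train_positives + self.train_negatives
        labels = np.concatenate([
            np.full(len(self.train_positives), NETWORKING),
            np.full(len(self.train_negatives), NON_NETWORKING),
        ])
        return triads, labels

    def test_triads_labels(self) -> tuple[list[Triad], np.ndarray]:
        triads = self.test_positives + self.test_negatives
        labels = np.concatenate([
            np.full(len(self.test_positives), NETWORKING),
            np.full(len(self.test_negatives), NON_NETWORKING),
        ])
        return triads, labels


# ---------------------------------------------------------------------------
# I/O


def _parse_label(token: str, lineno: int) -> int:
    if token == "1":
        return NETWORKING
    if token == "0":
        return NON_NETWORKING
    raise ValueError(f"line {lineno}: label must be 0 or 1, got {token!r}")


def read_triads(path: str | Path, default_label: int | None = None) -> list[Triad]:
    """Read triads from a tab-separated file.

    Three columns ``substrate<TAB>enzyme<TAB>product`` with an optional
    fourth label column (1 = networking, 0 = non-networking) that
    overrides ``default_label``.  Lines starting with ``#`` are headers
    or comments.  Duplicate rows are collapsed with a warning;
    a substrate equal to its product is rejected (a self-loop reaction
    is vacuous and never occurs in curated reactant-pair data).
    """
    triads: list[Triad] = []
    seen: dict[tuple[str, str, str], int | None] = {}
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            s, e, p = parts[:3]
            if not (s and e and p):
                raise ValueError(f"{path}: line {lineno}: empty identifier field")
            if s == p:
                raise ValueError(
                    f"{path}: line {lineno}: substrate equals product ({s!r})"
                )
            label = _parse_label(parts[3], lineno) if len(parts) == 4 else default_label
            key = (s, e, p)
            if key in seen:
                if seen[key] != label:
                    raise ValueError(
                        f"{path}: line {lineno}: duplicate triad {key} with conflicting label"
                    )
                n_dup += 1
                continue
            seen[key] = label
            triads.append(Triad(s, e, p, label))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate triad row(s)", path, n_dup)
    return triads


def write_triads(path: str | Path, triads: Iterable[Triad], header: bool = True) -> None:
    """Write triads as tab-separated rows, with label column when present."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("#substrate\tenzyme\tproduct\tlabel\n")
        for t in triads:
            if t.label is None:
                fh.write(f"{t.substrate}\t{t.enzyme}\t{t.product}\n")
            else:
                fh.write(f"{t.substrate}\t{t.enzyme}\t{t.product}\t{t.label}\n")


# ---------------------------------------------------------------------------
# Negative sampling and splitting


def sample_random_triads(
    compounds: Sequence[str],
    enzymes: Sequence[str],
    n: int,
    seed: int,
    label: int | None = None,
    exclude: Sequence[Triad] = (),
) -> list[Triad]:
    """Sample ``n`` unique random triads uniformly over the id universes.

    Each triad is an ordered (substrate, enzyme, product) triple with
    substrate != product, distinct from every triad in ``exclude`` and
    from every other sampled triad.  Rejection sampling over batched
    uniform draws; fully reproducible from the seed.

    Raises
    ------
    ValueError
        If the universe admits fewer distinct triples than requested;
        the message states the attainable maximum.
    """
    compounds = list(dict.fromkeys(compounds))
    enzymes = list(dict.fromkeys(enzymes))
    n_c, n_e = len(compounds), len(enzymes)
    excl_keys = {t.ids for t in exclude}
    admissible = n_c * (n_c - 1) * n_e - len(excl_keys)
    if n > admissible:
        raise ValueError(
            f"cannot sample {n} unique triads: the universe admits at most "
            f"{admissible} triples distinct from the excluded set"
        )

    rng = np.random.default_rng(seed)
    c_of = {c: i for i, c in enumerate(compounds)}
    e_of = {e: i for i, e in enumerate(enzymes)}
    # excluded triads with ids outside the universe can never collide
    excl_idx: set[tuple[int, int, int]] = set()
    for s, e, p in excl_keys:
        si, ei, pi = c_of.get(s), e_of.get(e), c_of.get(p)
        if si is not None and ei is not None and pi is not None:
            excl_idx.add((si, ei, pi))

    seen: set[tuple[int, int, int]] = set()
    out: list[Triad] = []
    batch = max(1024, min(n * 2, 1_000_000))
    while len(out) < n:
        s = rng.integers(0, n_c, size=batch)
        p = rng.integers(0, n_c, size=batch)
        e = rng.integers(0, n_e, size=batch)
        ok = s != p
        for si, ei, pi in zip(s[ok], e[ok], p[ok]):
            key = (int(si), int(ei), int(pi))
            if key in seen or key in excl_idx:
                continue
            seen.add(key)
            out.append(Triad(compounds[key[0]], enzymes[key[1]], compounds[key[2]], label))
            if len(out) == n:
                break
    return out


def sample_negative_triads(
    compounds: Sequence[str],
    enzymes: Sequence[str],
    positives: Sequence[Triad],
    ratio: int,
    seed: int,
) -> list[Triad]:
    """Sample ``ratio * len(positives)`` unique random non-networking triads.

    Uniform over the id universes, substrate != product, never colliding
    with a positive or with another sampled negative; reproducible from
    the seed (see :func:`sample_random_triads`).
    """
    if ratio < 1:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    out = sample_random_triads(
        compounds, enzymes, ratio * len(positives), seed,
        label=NON_NETWORKING, exclude=positives,
    )
    logger.info("sampled %d unique negative triads (ratio %d)", len(out), ratio)
    return out


def split_train_test(dataset: TriadDataset, test_fraction: float, seed: int) -> TriadDataset:
    """Random per-class hold-out split, reproducible from the seed.

    Per class, ``ceil(test_fraction * class_size)`` triads are drawn
    uniformly without replacement as the test set (ceiling so that a
    one-tenth split of 14,592 yields 1,460 test triads).  Returns a new
    dataset sharing the triad collections, with the partition set.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    if not dataset.positives or not dataset.negatives:
        raise ValueError("both classes must be non-empty to split")
    rng = np.random.default_rng(seed)
    partition: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cls, coll in ((NETWORKING, dataset.positives), (NON_NETWORKING, dataset.negatives)):
        n = len(coll)
        n_test = math.ceil(test_fraction * n)
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        partition[cls] = (train, test)
    logger.info(
        "split: %d/%d train/test positives, %d/%d train/test negatives",
        len(partition[NETWORKING][0]), len(partition[NETWORKING][1]),
        len(partition[NON_NETWORKING][0]), len(partition[NON_NETWORKING][1]),
    )
    return TriadDataset(dataset.positives, dataset.negatives, partition)
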