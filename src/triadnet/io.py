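"""Readers and writers for the tab-separated exchange formats.

All files are UTF-8, tab-separated, Unix newlines; lines starting with
``#`` are headers or comments.  Every reader accepts what the matching
writer produces (round-trip identity).

Formats
-------
compound similarity : ``compound_id<TAB>compound_id<TAB>score`` with
    score a decimal in [0, 1]; symmetric closure applied at load.
domain annotations : ``enzyme_id<TAB>domain_accession``, one row per hit.
triads : see :mod:`triadnet.dataset`.
predictions : one row per query triad with true/predicted labels and
    nearest-positive / nearest-negative distances.
"""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset import NETWORKING, NON_NETWORKING, Triad, TriadDataset
from .similarity import DEFAULT_FLOOR, CompoundSimilarityStore, DomainProfile

__all__ = [
    "read_compound_similarities",
    "write_compound_similarities",
    "read_domain_annotations",
    "write_domain_annotations",
    "write_predictions",
    "read_predictions",
    "write_metrics",
    "write_split_manifest",
    "write_run_manifest",
]

PREDICTION_COLUMNS = [
    "substrate",
    "enzyme",
    "product",
    "true_label",
    "predicted_label",
    "nearest_positive_distance",
    "nearest_negative_distance",
]


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_compound_similarities(
    path: str | Path, floor: float = DEFAULT_FLOOR
) -> CompoundSimilarityStore:
    """Load pairwise compound scores into a store (floor applied at serve)."""
    store = CompoundSimilarityStore(floor=floor)
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
        c1, c2, raw = parts
        try:
            score = float(raw)
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: malformed score {raw!r}") from None
        try:
            store.add_entry(c1, c2, score)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return store


def write_compound_similarities(path: str | Path, store: CompoundSimilarityStore) -> None:
    """Write stored (unfloored) pair scores, plus bare ids for isolated compounds."""
    paired = set()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#compound_id\tcompound_id\tscore\n")
        for (c1, c2), score in sorted(store.items()):
            fh.write(f"{c1}\t{c2}\t{score!r}\n")
            paired.update((c1, c2))
        for c in sorted(store.compound_ids - paired):
            fh.write(f"{c}\t{c}\t1.0\n")


def read_domain_annotations(path: str | Path) -> dict[str, DomainProfile]:
    """Load enzyme -> functional-domain profiles (one row per hit)."""
    hits: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
        enzyme, domain = parts
        if not enzyme or not domain:
            raise ValueError(f"{path}: line {lineno}: empty field")
        hits.setdefault(enzyme, set()).add(domain)
    return {e: DomainProfile(e, frozenset(d)) for e, d in hits.items()}


def write_domain_annotations(path: str | Path, profiles: Mapping[str, DomainProfile]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#enzyme_id\tdomain_accession\n")
        for e in sorted(profiles):
            for d in sorted(profiles[e].domains):
                fh.write(f"{e}\t{d}\n")


def write_predictions(
    path: str | Path,
    queries: Sequence[Triad],
    predicted: Sequence[int],
    d_pos: Sequence[float],
    d_neg: Sequence[float],
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(PREDICTION_COLUMNS) + "\n")
        for t, lab, dp, dn in zip(queries, predicted, d_pos, d_neg):
            true = "" if t.label is None else str(t.label)
            fh.write(
                f"{t.substrate}\t{t.enzyme}\t{t.product}\t{true}\t{int(lab)}\t{dp!r}\t{dn!r}\n"
            )


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=PREDICTION_COLUMNS,
        comment="#",
        dtype={"true_label": "Int64", "predicted_label": int},
    )
    return df


def write_metrics(path: str | Path, rows: pd.DataFrame) -> None:
    """Write an evaluation table (e.g. one row per w or K) as TSV."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_split_manifest(path: str | Path, dataset: TriadDataset) -> None:
    """Audit record of the split: per class, triad index -> train/test."""
    if dataset.partition is None:
        raise ValueError("dataset has no partition")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#class\ttriad_index\tsubset\n")
        for cls, name in ((NETWORKING, "positive"), (NON_NETWORKING, "negative")):
            train, test = dataset.partition[cls]
            assignment = {int(i): "train" for i in train}
            assignment.update({int(i): "test" for i in test})
            for idx in sorted(assignment):
                fh.write(f"{name}\t{idx}\t{assignment[idx]}\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_run_manifest(
    path: str | Path,
    command: str,
    config: Mapping,
    seed: int | None,
    inputs: Iterable[str | Path],
    outputs: Iterable[str | Path],
) -> None:
    """One JSON manifest per CLI run: command, config echo, seed, digests."""
    manifest = {
        "command": command,
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": sys.version.split()[0],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
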