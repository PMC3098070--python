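"""Margin diagnostics for the KNN triad predictor.

For each held-out networking triad T_i the distances to its nearest
networking (P_i) and nearest non-networking (N_i) training triad
diagnose how the classifier decided: at K = 1 the triad is predicted
networking exactly when P_i <= N_i (ties go to the positive by
training-order convention when positives precede negatives).  Plotted
over the test index these give the P-curve and N-curve; for
misclassified positives the margin P_i - N_i measures how far the triad
was from a correct call.

A reference margin table for the 67 misclassified networking triads of
the yeast KEGG-derived benchmark (w = 1/4, K = 1, graph compound
similarity) ships with the package for regression checks; see
:func:`load_reference_margins`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Triad, TriadDataset
from .knn import SimilarityCache, predict_batch
from .metric import MetricConfig

__all__ = [
    "MarginRecord",
    "pn_curves",
    "margin_table",
    "margin_summary",
    "distance_histogram",
    "load_reference_margins",
]


@dataclass(frozen=True)
class MarginRecord:
    """P/N distances and their difference for one test triad."""

    triad: Triad
    dist_to_nearest_positive: float
    dist_to_nearest_negative: float
    difference: float


def pn_curves(
    test_positives: Sequence[Triad],
    training: TriadDataset,
    config: MetricConfig,
    cache: SimilarityCache,
    K: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-triad (P_i, N_i) in test order.

    P_i is the minimum distance from test triad i to any training
    networking triad, N_i to any training non-networking triad.
    """
    train_triads, labels = (
        training.training_triads_labels()
        if training.partition is not None
        else (training.positives + training.negatives, None)
    )
    pos = training.train_positives if training.partition is not None else training.positives
    neg = training.train_negatives if training.partition is not None else training.negatives
    if not pos or not neg:
        raise ValueError("both training classes must be non-empty for P/N curves")
    result = predict_batch(list(test_positives), training, K, config, cache)
    return result.nearest_positive_distance, result.nearest_negative_distance


def margin_table(
    triads: Sequence[Triad],
    p_distances: Sequence[float],
    n_distances: Sequence[float],
    decimals: int | None = None,
) -> list[MarginRecord]:
    """Assemble margin records with difference = P_i - N_i.

    When ``decimals`` is given, distances and differences are rounded to
    that many decimal places — use this when the distances come from a
    table printed at fixed precision, so that comparisons against a
    threshold behave as they do on the printed numbers rather than on
    binary floating-point residues.
    """
    if not (len(triads) == len(p_distances) == len(n_distances)):
        raise ValueError("triads, p_distances and n_distances must have equal lengths")
    records = []
    for t, p, n in zip(triads, p_distances, n_distances):
        diff = p - n
        if decimals is not None:
            p, n, diff = round(p, decimals), round(n, decimals), round(diff, decimals)
        records.append(MarginRecord(t, p, n, diff))
    return records


def margin_summary(
    differences: Sequence[float], threshold: float
) -> tuple[float, float, int, float]:
    """(min, max, count strictly below threshold, percent below).

    "Below" is strict: a difference exactly equal to the threshold is
    not counted.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise ValueError("differences must be non-empty")
    below = int(np.sum(diffs < threshold))
    return (
        float(diffs.min()),
        float(diffs.max()),
        below,
        100.0 * below / diffs.size,
    )


def distance_histogram(values: Sequence[float], edges: Sequence[float]) -> np.ndarray:
    """Counts per half-open bin [e_i, e_{i+1}), last bin closed.

    A value equal to an interior edge falls in the upper bin; values
    outside [edges[0], edges[-1]] are not counted.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be a strictly increasing 1-D sequence")
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return counts


def load_reference_margins() -> pd.DataFrame:
    """The packaged reference margin table (67 misclassified positives).

    Columns: substrate, enzyme, product, dist_pos, dist_neg, difference
    — distances printed at up to 6 decimal places.
    """
    with resources.files("triadnet.data").joinpath("misclassified_margins.tsv").open() as fh:
        return pd.read_csv(
            fh,
            sep="\t",
            names=["substrate", "enzyme", "product", "dist_pos", "dist_neg", "difference"],
            comment="#",
        )
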