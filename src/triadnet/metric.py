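"""The weighted triad distance.

The distance between two triads T1 = (s1, e1, p1) and T2 = (s2, e2, p2)
is a convex combination of the three component dissimilarities

    d(T1, T2) = w_s (1 - S_c(s1, s2)) + w_e (1 - S_e(e1, e2))
                + w_p (1 - S_c(p1, p2))

where S_c is the floored compound similarity and S_e the enzyme
functional-domain cosine.  A single weight parameter w controls the
enzyme/compound balance; under the default *enzyme* convention
w_e = w and w_s = w_p = (1 - w)/2, so the weights always sum to 1 and
the distance lies in [0, 1].  The alternative *compound* convention
puts w on the compound side (w_s = w_p = w/2, w_e = 1 - w).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .dataset import Triad, TriadDataset
from .similarity import DEFAULT_FLOOR

__all__ = ["MetricConfig", "triad_distance", "sweep_w"]

CompoundKernel = Callable[[str, str], float]
EnzymeKernel = Callable[[str, str], float]


@dataclass(frozen=True)
class MetricConfig:
    """Weighting of the triad distance.

    Parameters
    ----------
    w:
        Balance parameter in [0, 1].  Under the ``"enzyme"`` convention
        (default) it multiplies the enzyme dissimilarity and each
        compound dissimilarity gets (1 - w)/2; under ``"compound"``
        each compound dissimilarity gets w/2 and the enzyme 1 - w.
    convention:
        ``"enzyme"`` or ``"compound"``.
    floor:
        The compound-similarity floor the kernel is expected to apply;
        carried here so a configuration fully describes a run.
    """

    w: float = 0.25
    convention: str = "enzyme"
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if self.convention not in ("enzyme", "compound"):
            raise ValueError(
                f"convention must be 'enzyme' or 'compound', got {self.convention!r}"
            )

    @property
    def weights(self) -> tuple[float, float, float]:
        """(substrate, enzyme, product) weights; non-negative, sum to 1."""
        if self.convention == "enzyme":
            return ((1 - self.w) / 2, self.w, (1 - self.w) / 2)
        return (self.w / 2, 1 - self.w, self.w / 2)


def triad_distance(
    t1: Triad,
    t2: Triad,
    config: MetricConfig,
    compound_kernel: CompoundKernel,
    enzyme_kernel: EnzymeKernel,
) -> float:
    """Weighted triad distance in [0, 1] (0 iff all three similarities are 1)."""
    ws, we, wp = config.weights
    try:
        sc_s = compound_kernel(t1.substrate, t2.substrate)
        se = enzyme_kernel(t1.enzyme, t2.enzyme)
        sc_p = compound_kernel(t1.product, t2.product)
    except KeyError as exc:
        raise KeyError(f"while comparing triads {t1.ids} and {t2.ids}: {exc}") from exc
    return ws * (1.0 - sc_s) + we * (1.0 - se) + wp * (1.0 - sc_p)


def sweep_w(
    values: Sequence[float],
    dataset: TriadDataset,
    K: int,
    compound_kernel: CompoundKernel,
    enzyme_kernel: EnzymeKernel,
    convention: str = "enzyme",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Evaluate the held-out split at each weight in ``values``.

    Returns one row per w, in input order, with SN, SP, ACC in percent
    and MCC in percent (the scale the benchmark tables use).
    """
    from .evaluate import confusion, sensitivity, specificity, accuracy, mcc
    from .knn import SimilarityCache, predict_batch

    if len(values) == 0:
        raise ValueError("values must be non-empty")
    queries, true_labels = dataset.test_triads_labels()
    train_triads, _ = dataset.training_triads_labels()
    cache = SimilarityCache.from_kernels(
        queries + train_triads, compound_kernel, enzyme_kernel
    )
    rows = []
    for w in values:
        config = MetricConfig(w=w, convention=convention, floor=floor)
        result = predict_batch(queries, dataset, K, config, cache)
        c = confusion(result.labels, true_labels)
        rows.append(
            {
                "w": w,
                "SN": sensitivity(c),
                "SP": specificity(c),
                "ACC": accuracy(c),
                "MCC": 100.0 * mcc(c),
            }
        )
    return pd.DataFrame(rows)
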