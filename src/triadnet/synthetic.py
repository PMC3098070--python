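"""Self-contained synthetic benchmarks with triad-similarity structure.

The predictor rests on one empirical regularity: triads that are
similar — substrates alike, enzymes sharing functional domains,
products alike — tend to share the networking label.  The generator
builds universes with exactly that structure, so the full pipeline can
be exercised and its recovery measured without external compound- or
domain-similarity services:

* compounds fall into clusters; within a cluster pairwise similarities
  are drawn uniformly from ``within_cluster_sim_range``, across
  clusters the similarity is ``cross_cluster_sim`` (0 by default, i.e.
  below any sensible floor — mirroring sources that only report scores
  above the floor);
* enzymes fall into families; each family owns a disjoint pool of
  functional-domain accessions and each member carries a random subset
  of its family pool, giving high within-family cosine and zero
  across;
* positive (networking) triads are instantiated from *reaction
  templates*: a template binds a substrate cluster, an enzyme family
  and a distinct product cluster, and contributes a fixed number of
  distinct member-level triads.

Negatives are then sampled uniformly at the configured imbalance ratio
by the dataset module, exactly as in the benchmark protocol.

Default scale (~120 compounds, ~70 enzymes, 300 positives, ratio 50,
i.e. 15,000 negatives) keeps a full generate/sample/split/predict/
evaluate run in the tens of seconds on one CPU.  Many small clusters
(30 x 4 compounds, 24 x 3 enzymes) keep randomly sampled negatives
thinly spread over the template cells, which is the regime where the
label actually follows triad similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    NETWORKING,
    Triad,
    TriadDataset,
    sample_negative_triads,
    split_train_test,
)
from .evaluate import accuracy, confusion, mcc, sensitivity, specificity
from .knn import SimilarityCache, predict_batch
from .metric import MetricConfig
from .similarity import (
    DEFAULT_FLOOR,
    CompoundSimilarityStore,
    DomainProfile,
    enzyme_kernel_from_profiles,
)

__all__ = ["SyntheticConfig", "generate_benchmark", "run_experiment"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_compound_clusters: int = 30
    compounds_per_cluster: int = 4
    n_enzyme_families: int = 24
    enzymes_per_family: int = 3
    n_domains: int = 300
    domains_per_family_pool: int = 10
    domain_carry_prob: float = 0.8
    n_reaction_templates: int = 15
    triads_per_template: int = 20
    within_cluster_sim_range: tuple[float, float] = (0.5, 0.95)
    cross_cluster_sim: float = 0.0
    negative_ratio: int = 50
    floor: float = DEFAULT_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_compound_clusters", "compounds_per_cluster", "n_enzyme_families",
            "enzymes_per_family", "n_domains", "domains_per_family_pool",
            "n_reaction_templates", "triads_per_template", "negative_ratio",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        lo, hi = self.within_cluster_sim_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("within_cluster_sim_range must be ordered and within [0, 1]")
        if not 0.0 <= self.cross_cluster_sim <= 1.0:
            raise ValueError("cross_cluster_sim must lie in [0, 1]")
        if not 0.0 < self.domain_carry_prob <= 1.0:
            raise ValueError("domain_carry_prob must lie in (0, 1]")
        if self.n_enzyme_families * self.domains_per_family_pool > self.n_domains:
            raise ValueError("domain catalogue too small for disjoint family pools")

    @property
    def n_compounds(self) -> int:
        return self.n_compound_clusters * self.compounds_per_cluster

    @property
    def n_enzymes(self) -> int:
        return self.n_enzyme_families * self.enzymes_per_family


def generate_benchmark(
    config: SyntheticConfig,
) -> tuple[CompoundSimilarityStore, dict[str, DomainProfile], list[Triad]]:
    """Generate (compound store, enzyme profiles, positive triads).

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_cc, cpc = config.n_compound_clusters, config.compounds_per_cluster
    n_ef, epf = config.n_enzyme_families, config.enzymes_per_family

    compounds = [f"C{i:04d}" for i in range(config.n_compounds)]
    cluster_of = np.repeat(np.arange(n_cc), cpc)
    store = CompoundSimilarityStore(floor=config.floor)
    for c in compounds:
        store.add_compound(c)
    lo, hi = config.within_cluster_sim_range
    for i in range(len(compounds)):
        for j in range(i + 1, len(compounds)):
            if cluster_of[i] == cluster_of[j]:
                score = float(rng.uniform(lo, hi))
            else:
                score = config.cross_cluster_sim
            if score > 0.0:
                store.add_entry(compounds[i], compounds[j], score)

    domains = [f"D{i:04d}" for i in range(config.n_domains)]
    enzymes = [f"E{i:04d}" for i in range(config.n_enzymes)]
    family_of = np.repeat(np.arange(n_ef), epf)
    profiles: dict[str, DomainProfile] = {}
    pool_size = config.domains_per_family_pool
    for k, e in enumerate(enzymes):
        fam = family_of[k]
        pool = domains[fam * pool_size:(fam + 1) * pool_size]
        mask = rng.random(pool_size) < config.domain_carry_prob
        hits = [d for d, m in zip(pool, mask) if m]
        if not hits:
            hits = [pool[int(rng.integers(pool_size))]]
        profiles[e] = DomainProfile(e, frozenset(hits))

    # distinct template cells (substrate cluster, enzyme family, product cluster)
    cells: list[tuple[int, int, int]] = []
    seen_cells: set[tuple[int, int, int]] = set()
    n_cells = n_cc * (n_cc - 1) * n_ef
    if config.n_reaction_templates > n_cells:
        raise ValueError(
            f"cannot place {config.n_reaction_templates} templates: only "
            f"{n_cells} distinct (substrate cluster, family, product cluster) cells"
        )
    while len(cells) < config.n_reaction_templates:
        sc = int(rng.integers(n_cc))
        pc = int(rng.integers(n_cc))
        ef = int(rng.integers(n_ef))
        if sc == pc or (sc, ef, pc) in seen_cells:
            continue
        seen_cells.add((sc, ef, pc))
        cells.append((sc, ef, pc))

    n_combos = cpc * epf * cpc
    if config.triads_per_template > n_combos:
        raise ValueError(
            f"template admits only {n_combos} distinct triads, "
            f"requested {config.triads_per_template}"
        )
    positives: list[Triad] = []
    for sc, ef, pc in cells:
        subs = compounds[sc * cpc:(sc + 1) * cpc]
        prods = compounds[pc * cpc:(pc + 1) * cpc]
        enzs = enzymes[ef * epf:(ef + 1) * epf]
        picks = rng.choice(n_combos, size=config.triads_per_template, replace=False)
        for idx in picks:
            s_i, rest = divmod(int(idx), epf * cpc)
            e_i, p_i = divmod(rest, cpc)
            positives.append(Triad(subs[s_i], enzs[e_i], prods[p_i], NETWORKING))
    return store, profiles, positives


def build_dataset(
    config: SyntheticConfig,
    store: CompoundSimilarityStore,
    positives: Sequence[Triad],
    test_fraction: float = 0.1,
) -> TriadDataset:
    """Sample negatives at the configured ratio and split hold-out."""
    rng = np.random.default_rng(config.seed)
    neg_seed, split_seed = (int(x) for x in rng.integers(0, 2**31, size=2))
    compounds = sorted(store.compound_ids)
    enzymes = [f"E{i:04d}" for i in range(config.n_enzymes)]
    negatives = sample_negative_triads(
        compounds, enzymes, list(positives), config.negative_ratio, neg_seed
    )
    dataset = TriadDataset(list(positives), negatives)
    return split_train_test(dataset, test_fraction, split_seed)


def run_experiment(
    config: SyntheticConfig,
    K_values: Sequence[int] = (1,),
    w_values: Sequence[float] = (0.25,),
    test_fraction: float = 0.1,
    convention: str = "enzyme",
) -> pd.DataFrame:
    """Full pipeline at each (K, w): generate, sample, split, predict, score.

    Returns one row per combination with SN, SP, ACC in percent and MCC
    in percent.
    """
    store, profiles, positives = generate_benchmark(config)
    dataset = build_dataset(config, store, positives, test_fraction)
    queries, true_labels = dataset.test_triads_labels()
    train_triads, _ = dataset.training_triads_labels()
    cache = SimilarityCache.from_kernels(
        queries + train_triads, store.similarity, enzyme_kernel_from_profiles(profiles)
    )
    rows = []
    for K in K_values:
        for w in w_values:
            mc = MetricConfig(w=w, convention=convention, floor=config.floor)
            result = predict_batch(queries, dataset, K, mc, cache)
            c = confusion(result.labels, true_labels)
            rows.append(
                {
                    "K": K,
                    "w": w,
                    "SN": sensitivity(c),
                    "SP": specificity(c),
                    "ACC": accuracy(c),
                    "MCC": 100.0 * mcc(c),
                }
            )
    return pd.DataFrame(rows)
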