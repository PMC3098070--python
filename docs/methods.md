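# Methods

## The prediction problem

A metabolic reaction step is abstracted as a **triad** T = (s, e, p): a
substrate compound s, an enzyme e, and a product compound p.  The triad is
*networking* if e catalyses the transformation of s into p, and
*non-networking* otherwise.  Given a training collection of labelled triads,
the task is to predict the label of a query triad.  The method rests on one
empirical regularity: triads that are similar — substrates alike, enzymes
sharing functional domains, products alike — overwhelmingly share their
label.

## Component similarities

**Compounds.**  Pairwise compound similarity is consumed as precomputed
scores in [0, 1] (2D molecular-graph alignment scores, or fingerprint
Tanimoto scores exported on a 0–1000 scale and divided by 1000).  Scores
below a floor are served as 0; the default floor is **0.4**, matching the
cutoff below which graph-alignment services report no score at all.  The
floor is applied at serve time, so a loaded store can be re-floored without
re-reading.  Self-similarity is hard-wired to 1; a pair with no stored entry
is served as 0 (sparse absence means "no detectable similarity").  A
caller-supplied bit-vector Tanimoto kernel (|A∩B|/|A∪B|) is included so the
pipeline runs without external similarity services.

**Enzymes.**  An enzyme is encoded as the set A of functional-domain
accessions (InterPro-style) it hits — the sparse form of a binary
domain-hit vector.  Similarity of two enzymes is the cosine of those binary
vectors, which reduces to

    S_e(e1, e2) = |A ∩ B| / sqrt(|A| · |B|).

We compute `sqrt(|A|·|B|)` as a single square root: mathematically identical
to the product of square roots but exactly 1.0 for equal sets, which the
rest of the pipeline (distance 0 for identical triads) relies on.  Enzymes
with an empty domain set carry no information and are rejected at load, not
silently scored 0.

## The triad distance

For triads T1 = (s1, e1, p1), T2 = (s2, e2, p2):

    d(T1, T2) = (1−w)/2 · (1 − S_c(s1, s2))
              + w       · (1 − S_e(e1, e2))
              + (1−w)/2 · (1 − S_c(p1, p2))

with weight w ∈ [0, 1] (default 1/4).  The weights are non-negative and sum
to 1, so d ∈ [0, 1], is symmetric, and is 0 iff all three similarities are
1.  At w = 1/4 the compound coefficients are 0.375 and the enzyme
coefficient 0.25, which makes observed distances decompose cleanly given the
0.4 floor (e.g. 0.225 = 0.375 × 0.6 for one compound at the floor, 0.25 for
an enzyme with no shared domains and identical compounds).  The alternative
reading that puts w on the compound side (w/2 per compound term, 1−w on the
enzyme) is available as `MetricConfig(convention="compound")`; the enzyme
convention is the default because it is the one under which the reference
margin table's distance columns decompose into these clean products.

No renormalisation is applied after flooring: a floored similarity of 0
simply contributes its full weight to the distance.

## Voting KNN

A query is assigned the majority label among its K nearest training triads
(K = 1 by default; the benchmark protocol uses odd K).  Two deterministic
tie rules complete the contract:

* equal distances are ordered by ascending training index (positives are
  enumerated before negatives in a split dataset);
* an even-K vote tie falls back to the single nearest neighbour's label —
  defensive only, since odd K cannot tie.

Two execution paths produce bit-identical results: a per-query exhaustive
scan calling the kernels pair by pair (the oracle), and a batch path that
tabulates the compound-pair and enzyme-pair similarity matrices once and
evaluates all query–training distances with the same arithmetic expression
vectorised, using a stable argsort (which implements the index tie-break
for free).  The equivalence is asserted on randomized instances in the test
suite.  Memory for the batch path is O(observed compounds² + observed
enzymes²) plus one query-chunk × training block (256 × |train| doubles).

## Benchmark construction

* **Positives** come from a curated triad list (or the synthetic generator).
  Substrate = product rows are rejected: a self-loop transformation is
  vacuous and never occurs in curated reactant-pair data.
* **Negatives** are sampled uniformly over ordered (compound, enzyme,
  compound) triples with substrate ≠ product, excluding positives and
  duplicates, at `ratio` negatives per positive (default 50 — reflecting
  that true reactions are a vanishing fraction of possible triples).
  Rejection sampling over batched uniform draws; the draw order is part of
  the reproducibility contract, one integer seed governs it.  Requesting
  more negatives than the universe admits is an error stating the
  attainable maximum.
* **Split**: per class, ceil(test_fraction × class size) test samples drawn
  uniformly without replacement (default one tenth).  Ceiling is the
  convention that maps a class of 14,592 to 1,460 test samples.  With the
  published benchmark scale (1,326 compounds × 939 enzymes, 14,592
  positives, ratio 50) this reproduces 729,600 negatives and the
  1,460 / 72,960 test-class sizes exactly; the whole construction runs in a
  few seconds.

## Evaluation

With networking as the positive class: SN = 100·TP/(TP+FN),
SP = 100·TN/(TN+FP), ACC = 100·(TP+TN)/N, and Matthews' correlation
coefficient MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
ACC equals the class-size-weighted mean of SN and SP (property-tested).
MCC is the right headline number under 50:1 imbalance, where ACC is
dominated by the majority class.  A confusion with a zero marginal defines
MCC as 0 with a warning.  Values are kept at full precision internally;
rounding happens only at presentation.

## Margin diagnostics

For each held-out networking triad, P_i is its distance to the nearest
training positive and N_i to the nearest training negative.  At K = 1 the
prediction is networking iff P_i ≤ N_i (ties favour the positive through
the index tie-break), so for misclassified positives the margin
P_i − N_i > 0 measures how far the triad was from a correct call.
`margin_summary` reports extrema and the count *strictly* below a threshold.

A packaged reference table
(`triadnet/data/misclassified_margins.tsv`, 67 rows from the yeast
KEGG-derived benchmark at w = 1/4, K = 1) serves as a regression fixture:
its differences recompute from the printed P/N columns, with extrema
0.000256 / 0.285 and 47 rows (70.15%) strictly below 0.1.  Because the
table prints distances at ≤ 6 decimals, differences are recomputed at that
precision (`decimals=6`): in binary floating point 0.25 − 0.15 falls a hair
*below* 0.1 and would spuriously move one row across the strict threshold.

Histogram bins are lower-closed half-open, last bin closed (the `numpy`
convention), so "the interval from 0.15 to 0.4" is [0.15, 0.4).

## Synthetic benchmark generator

The generator emulates the *structure* the classifier consumes, not the
chemistry:

| parameter | default | meaning |
|---|---|---|
| n_compound_clusters × compounds_per_cluster | 30 × 4 | compound universe (120) |
| n_enzyme_families × enzymes_per_family | 24 × 3 | enzyme universe (72) |
| n_domains / domains_per_family_pool | 300 / 10 | domain catalogue; disjoint family pools |
| domain_carry_prob | 0.8 | P(an enzyme carries each pool domain) |
| n_reaction_templates × triads_per_template | 15 × 20 | positive triads (300) |
| within_cluster_sim_range | [0.5, 0.95] | uniform within-cluster compound similarity |
| cross_cluster_sim | 0 | below the floor, i.e. erased |
| negative_ratio | 50 | class imbalance |

Each reaction template binds (substrate cluster, enzyme family, product
cluster) with substrate cluster ≠ product cluster and instantiates distinct
member-level triads.  Within-family enzyme cosine is high (shared pool,
carry probability 0.8), across families zero.  The cluster granularity is
deliberately fine: with 30×29×24 ≈ 20,900 template cells and 15,000
negatives, a random negative rarely lands in an occupied cell, so held-out
positives find same-template training positives far nearer than any
negative — the separable regime in which label-follows-similarity is
recoverable.  On this default benchmark (one-tenth hold-out, K = 1,
w = 1/4) sensitivity and specificity averaged over seeds 1–3 are ≈ 99%,
and moving weight from the compounds to the enzyme (w = 3/4) never improves
sensitivity — the degradation pattern the weight sweep exists to show.
Setting `within_cluster_sim_range = (0, 0)` pushes all compound signal
below the floor and measurably degrades sensitivity (enzyme-only
information).

What the generator does **not** emulate: real molecular-graph similarity
distributions (which are heavy-tailed, not uniform), shared domains across
enzyme families (EC-number promiscuity), correlated reactions (one enzyme
catalysing many reactant pairs), or hard negatives (chemically plausible
but non-catalysed triples).  Passing recovery tests on it therefore shows
the engine is correct and the protocol sound — not that the accuracies
transfer to real KEGG/InterPro-scale data, whose published headline numbers
depend on those external similarity services.

## Numerical and degenerate-input choices

* Distances are computed with one fixed expression order in both KNN paths,
  so scan and batch agree bitwise.
* Duplicate similarity records with equal scores are tolerated; conflicting
  ones are load errors.  A stored self-similarity ≠ 1 is a load error.
* Unknown ids raise KeyError naming the id, at the kernel; triad context is
  attached where a metric call fails.
* Seeds: every stochastic operation takes an explicit integer seed; the
  experiment runner derives its sampling and split seeds from the config
  seed through one `default_rng` draw (documented, reproducible, below
  2^31).

## Problem sizes used in the shipped checks

Unit and property tests run on instances of ≤ 500 training triads.  The
recovery check runs the full default generator (300 positives, 15,000
negatives) at three seeds, ~2 s per seed on one CPU.  The
benchmark-scale construction check (744,192 triads) runs in ~5 s.
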