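# triadnet

Voting-KNN prediction of **substrate–enzyme–product triad networking** in
metabolic pathways.

A metabolic reaction step is abstracted as a triad T = (s, e, p): substrate
compound, enzyme, product compound.  The triad is *networking* when the
enzyme catalyses the s → p transformation.  Determining networking
experimentally is slow and expensive; `triadnet` predicts it
computationally for researchers studying metabolic-network completion,
enzyme promiscuity, or drug metabolism, by exploiting one robust
regularity: **similar triads almost always share their label**.

## The method

Similarity between triads combines two molecular encodings:

* compounds: precomputed pairwise structural similarity scores
  S_c ∈ [0, 1] (molecular-graph alignment or fingerprint Tanimoto),
  floored at 0.4 — scores below the floor count as 0;
* enzymes: functional-domain composition — an enzyme is a binary vector
  over a domain catalogue (InterPro-style), and
  S_e(e1, e2) = |A ∩ B| / √(|A|·|B|) is the cosine of two such vectors.

These feed a weighted triad distance

    d(T1, T2) = (1−w)/2 · (1 − S_c(s1, s2)) + w · (1 − S_e(e1, e2))
              + (1−w)/2 · (1 − S_c(p1, p2)),      w ∈ [0, 1], default 1/4,

and a query triad takes the majority label among its K nearest labelled
training triads (voting KNN, default K = 1).  Benchmarks pair curated
positive triads with uniformly sampled negatives at 50:1 imbalance and a
random one-tenth hold-out; performance is reported as sensitivity (SN),
specificity (SP), overall accuracy (ACC) and Matthews' correlation
coefficient (MCC).  See `docs/methods.md` for the full model description,
tie-breaking rules, and the synthetic benchmark generator.

## Worked example

Generate a synthetic benchmark with label-follows-similarity structure
(120 compounds in 30 clusters, 72 enzymes in 24 domain families, 300
networking triads from 15 reaction templates, 15,000 negatives at 50:1),
hold out one tenth, and sweep the metric weight at K = 1:

```python
from triadnet import SyntheticConfig, run_experiment

df = run_experiment(SyntheticConfig(seed=1), K_values=[1], w_values=[0.25, 0.5, 0.75])
print(df.round(2).to_string(index=False))
```

```
 K    w    SN    SP   ACC   MCC
 1 0.25 100.0 99.33 99.35 86.31
 1 0.50 100.0 97.40 97.45 65.08
 1 0.75 100.0 96.67 96.73 60.21
```

At w = 1/4 (most weight on the compound terms) all 30 held-out networking
triads are recovered (SN 100%) and only 10 of 1,500 held-out non-networking
triads are called networking (SP 99.33%).  Shifting weight onto the enzyme
term (w = 3/4) degrades both, and under 50:1 imbalance the damage shows
most clearly in MCC (86 → 60%), which — unlike ACC — is not dominated by
the majority class.

The same pipeline is scriptable from the shell:

```sh
triadnet simulate --seed 1 --out-dir bench/
triadnet sample-negatives --positives bench/positives.tsv \
    --compound-sim bench/compound_sim.tsv --domains bench/domains.tsv \
    --ratio 50 --seed 11 --out negatives.tsv
triadnet split --positives bench/positives.tsv --negatives negatives.tsv \
    --test-fraction 0.1 --seed 12 --out-dir split/
triadnet predict --train split/train.tsv --test split/test.tsv \
    --compound-sim bench/compound_sim.tsv --domains bench/domains.tsv \
    --k 1 --w 0.25 --out predictions.tsv
triadnet evaluate --pred predictions.tsv --out metrics.tsv
triadnet analyze --pred predictions.tsv --out margins.tsv
```

`predict` emits, per query, the predicted label and the distances to the
nearest networking / non-networking training triads; `analyze` turns these
into the P/N-curve margins of misclassified positives.  Every subcommand
writes a JSON manifest (seed, config echo, input digests) for audit.

All input files are plain TSV: 3-column compound similarity pairs,
2-column enzyme→domain annotations, 3–4-column triad lists.  Real
benchmarks (e.g. KEGG reactant pairs with graph-alignment compound scores
and InterPro domain hits) plug in through the same files.

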