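# wmcpm — connectome-based prediction of working-memory components

`wmcpm` is a tested, reusable implementation of a connectome-based
predictive-modeling (CPM) pipeline for working memory: it scores behavioral
capacities, builds composite component scores, predicts them from
resting-state functional-connectivity edges with a leave-one-out
cross-validated support-vector regression, establishes significance by
permutation with FDR correction, quantifies which brain networks carry the
predictive edges, and tests network necessity with virtual lesions. It is
aimed at researchers who want an auditable, leakage-free reference
implementation of this analysis style, validated end to end on synthetic
cohorts with known ground truth.

## The analysis

**Behavior.** Change-detection capacity is Cowan's K = S(H − F) (set size S,
hit rate H, false-alarm rate F), with K_max across loads per task; tracking
capacity is Scholl's K = S(2P − 1). Task scores are limited to the grand
mean ± 3 SD, z-scored across subjects, and averaged into composites — e.g.
BM = ½(z<sub>PLD</sub> + z<sub>Solid</sub>) and EVENT = ½(BM + NBM).

**Edges.** Node-pair Pearson correlations, Fisher-z transformed, vectorized
from the strict upper triangle in a fixed row-major order; a 268-node atlas
gives 35,778 edge features.

**Prediction.** For each held-out subject, a linear epsilon-SVR (C = 1,
ε = 0.1) fitted on the others ranks edges by |weight|; the top q‰
(q ∈ {1,3,5,7,9}; floor, min 1 — so 35 to 322 features at 35,778 edges) is
refitted to predict the held-out subject. Accuracy is Pearson's r between
predicted and actual scores. Permutations shuffle the scores and re-run the
entire nested procedure; p is the proportion of permuted r exceeding the
observed r, BH-corrected across the analysis family.

**Importance.** Edges selected in every fold (the consensus set) are
aggregated as Edge<sub>IJ</sub> = Σ|w| over edges linking networks I and J,
and each network's relative degree
RD<sub>I</sub> = Σ<sub>J</sub> binarize(Edge<sub>IJ</sub>) / Σ<sub>I</sub>Σ<sub>J</sub> binarize(Edge<sub>IJ</sub>)
(summing to 1). Node degree ranks nodes within a network by incident
consensus edges.

**Virtual lesions.** Removing all nodes of one network (keeping only edges
with both endpoints outside it) and re-running the full procedure tests that
network's necessity; the scan BH-corrects across thresholds × networks.

## Worked example

```python
import numpy as np
from wmcpm import (PredictionConfig, predict_component, simulate_dataset,
                   consensus_features, network_edge_matrix, relative_degree)

# a cohort with known truth: 103 subjects, 268 nodes, 30 signal edges
# confined to the 20-node cerebellum network, SNR 1.5
ds = simulate_dataset(seed=1)
cfg = PredictionConfig(n_permutations=100, seed=1)
results = predict_component(ds.X, ds.y, cfg)
for t, res in sorted(results.items()):
    print(f"{t} permille: {res.n_features:3d} features  "
          f"r={res.r_observed:+.2f}  p={res.p_permutation:.2f}  "
          f"significant={res.q_significant}")

best = min(t for t in results if results[t].q_significant)
cons = consensus_features(results[best].folds)
rd = relative_degree(network_edge_matrix(cons, ds.emap, ds.atlas))
print(rd.to_series().sort_values(ascending=False).head(3))
```

Output:

```
1 permille:  35 features  r=+0.80  p=0.00  significant=True
3 permille: 107 features  r=+0.79  p=0.00  significant=True
5 permille: 178 features  r=+0.78  p=0.00  significant=True
7 permille: 250 features  r=+0.74  p=0.00  significant=True
9 permille: 322 features  r=+0.70  p=0.00  significant=True
cerebellum        1.0
medial_frontal    0.0
frontoparietal    0.0
Name: relative_degree, dtype: float64
```

The planted signal is recovered (best r = 0.80 at the sparsest threshold,
no permuted r exceeding it in 100 shuffles), and the relative-degree profile
localizes all consensus network-pairs to the cerebellum network, where the
ground-truth edges were planted.

A command-line interface mirrors the library
(`wmcpm simulate | score | connect | predict | importance | lesion-scan | run`);
`wmcpm run --config config.json` executes the whole pipeline and writes a
manifest that reproduces every output table byte for byte.

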