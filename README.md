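# phasetree

Phase-lag-index connectivity and minimum-spanning-tree topology analysis for
resting-state source-space recordings (MEG/EEG region-of-interest time
series), with permutation-based group statistics and a seeded
synthetic-cohort generator.

## Who this is for

Groups comparing the large-scale functional network organisation of a small
patient cohort against matched controls from band-limited phase
synchronization. The pipeline starts at reconstructed ROI time series (e.g.
90 regions of a whole-brain atlas) and ends at FDR-corrected group
comparisons and a clinical-score correlation. Because such clinical datasets
are rarely shareable, the package ships a generator of surrogate cohorts
with a controllable ground-truth coupling graph, so every stage — and the
statistical calibration of the whole chain — is testable without any data
download.

## The method

For each subject, the recording is band-pass filtered (0.5–48 Hz, 4th-order
Butterworth, zero-phase), resampled to 512 Hz, and cut into ten 8-s epochs.
Each epoch is decomposed into the five canonical bands (δ 0.5–4, θ 4–8,
α 8–13, β 13–30, γ 30–48 Hz) and the instantaneous phase φ_i(t) of each ROI is
taken from the analytic signal. Synchronization between ROIs i and j is the
**phase lag index**

    PLI(i, j) = | ⟨ sign( sin( φ_i(t) − φ_j(t) ) ) ⟩_t |  ∈ [0, 1],

which is 0 for zero-lag (leakage-like) coupling and 1 for a consistent
nonzero lag. Each epoch × band yields an N × N adjacency matrix (N = 90 by
default). The network backbone is the **minimum spanning tree** on 1/PLI
edge weights (Kruskal's algorithm; strong synchronization = light edge),
summarised by

* leaf fraction  `L = (#nodes with degree 1) / N`  (integration; star-like
  topology → high L),
* degree divergence  `K = ⟨k²⟩ / ⟨k⟩`  (broadness of the degree
  distribution; resilience / synchronizability),
* betweenness centrality  `BC(v) = (#paths through v) / (N(N−1)/2)`
  per node (paths are unique in a tree; leaves score 0).

Metrics are averaged across epochs per subject. Group differences are
assessed by permuting subject labels (difference of group means, two-sided,
add-one estimator, 10 000 permutations by default) with Benjamini–Hochberg
FDR correction over the declared family (2 global metrics × 5 bands; for BC
additionally across areas). Degree divergence is related to a clinical
disability score by Pearson correlation, with optional outlier exclusion.

## Worked example

`examples/demo_config.yaml` describes a reduced cohort (20 ROIs, 256 Hz,
five 2-s epochs, 10 patients with chain-topology coupling vs 10 controls
with star-topology coupling, coupling strength 0.8, unit noise):

```sh
phasetree all --config examples/demo_config.yaml --out demo_out --seed 42
```

prints

```
phasetree 0.1.0 run (seed=42, hash=d765e074bd1381a6)
global-metric family: 10 tests, 2 significant after FDR
betweenness family: 100 tests, 17 significant after FDR
clinical correlation (degree_divergence, beta): r=0.296610537793798, p=0.40529746920244836, n=10
runtime: 2.85 s
```

and `demo_out/stats/group_comparisons.csv` holds the global family:

```
           metric  band  observed    p_raw  n_permutations    p_fdr  significant
degree_divergence  beta -3.367368 0.000999            1000 0.004995         True
    leaf_fraction  beta -0.311000 0.000999            1000 0.004995         True
degree_divergence alpha  0.033684 0.488511            1000 0.697874        False
...
```

Only the carrier band (β, where the synthetic coupling lives) is
significant; `observed` is mean(patients) − mean(controls), so the planted
chain-vs-star contrast appears as lower patient degree divergence
(−3.37) and lower leaf fraction, exactly the direction encoded in the
generator. The per-patient clinical correlation is weak here because all
chain patients share the same ground-truth K (see `docs/methods.md`).

Stages can also be run one at a time
(`phasetree simulate|spectral|connect|topology|stats`), each reading the
previous stage's directory, or from Python:

```python
from phasetree.synthdata import CohortSpec
from phasetree.pipeline import cohort_global_metrics

metrics = cohort_global_metrics(CohortSpec(seed=7))   # tidy DataFrame
```

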