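# liketolike

Tools for structure–function analysis of cortical microcircuits: do
excitatory neurons wire preferentially onto neurons with similar visual
tuning ("like-to-like"), at which anatomical scale does the selectivity act,
and is there higher-order structure beyond any pairwise wiring rule?

The package is written for analyses that combine dense electron-microscopy
reconstructions (neuron skeletons, synapse tables) with functional
characterization of the same neurons (response correlations, tuning
features). Because such datasets are terabyte-scale, every analysis here
also runs on a built-in synthetic cortical volume with configurable ground
truth, which doubles as the test bed for parameter-recovery checks.

## What it computes

**Anatomy.** Skeletons are discretized to ≤ 1 µm edges. An axon–dendrite
proximity (ADP) is any pair of skeleton vertices within 5 µm; the
*co-travel distance* `L_d` is the summed length of dendritic edges touching
a proximal vertex — the anatomical opportunity to synapse (a Peters'-rule
quantity). Synapses are attributed to an ADP when within 3 µm of it.
Unconnected pairs with `L_d > 0` form the ADP control cohort; unconnected
pairs in the same region with `L_d = 0` form the same-region control.

**Function.** Per unit: response reliability `CC_max`, model fidelity
`CC_abs` (both gate inclusion), orientation selectivity (gOSI / OSI, von
Mises mixture fits). Per pair: signal correlation (Pearson over 500-ms
bins), feature-weight cosine similarity, and receptive-field-centre
distance in visual angle.

**Statistics.** Like-to-like selectivity is estimated with generalized
linear mixed models (log link, presynaptic random intercepts):

- `L_d ~ Tweedie(ξ ∈ (1,2))` — a compound Poisson–gamma model for a
  non-negative quantity with exact zeros (axonal scale);
- `N_syn ~ Poisson` — synapse counts (both scales combined);
- `N_syn ~ Poisson with offset log L_d` — the synapse conversion rate
  `N_syn / L_d` (synaptic scale).

Each model is `log E[y] = β₀ + β₁·Sim + β₂·Proj + β₃·Sim×Proj + u`, and the
like-to-like coefficient of projection *k* is `β₁ + β₃[k]`. The
*common-input* statistic `ρ(i)` is the synapse-weighted mean pairwise
similarity among a presynaptic neuron's targets; comparing it with the
expectation `ρ'(i)` under a fitted pairwise rule (Wilcoxon signed-rank over
presynaptic neurons) tests for higher-order structure.

**Recurrent-network experiment.** A vanilla tanh RNN (numpy
implementation: BPTT + Adam) trained on image classification develops the
same signatures: connected hidden-unit pairs become more correlated,
connection probability rises with signal correlation, ablating like-to-like
connections hurts accuracy more than strength-matched random ablation, and
`ρ` exceeds `ρ'` from a logistic pairwise null.

## Worked example

```python
from liketolike.synthetic_world import WorldConfig, generate_pair_table
from liketolike.likelike_stats import GlmmSpec, fit_likelike_glmm

cfg = WorldConfig(n_neurons=350, n_presyn_full=110, n_presyn_partial=40,
                  seed=11, feature_dim=48, beta_axonal=0.4, beta_synaptic=0.5)
sim = generate_pair_table(cfg)
fit = fit_likelike_glmm(sim["pairs"], GlmmSpec(response="N_syn_per_Ld"))
print(fit.slope_table[["projection", "slope", "se", "p_adj"]])
```

```
  projection     slope        se         p_adj
0   HVA->HVA  0.526634  0.046261  1.004353e-29
1    HVA->V1  0.449546  0.046439  4.871121e-22
2    V1->HVA  0.379943  0.048286  3.586030e-15
3     V1->V1  0.572667  0.048961  5.314516e-31
```

Each row is the conditional synaptic-scale like-to-like slope for one
projection type: the change in log synapse conversion rate per unit of
feature similarity. The generative slope was 0.5; all four estimates
recover it within sampling error, and the marginal `N_syn` model instead
recovers ≈ 0.9 = β_axonal + β_synaptic, since the raw count combines both
scales.

A command-line interface mirrors the stages
(`liketolike simulate | geometry | stats | common-input | rnn | all`).

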