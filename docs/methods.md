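# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data experiments do and do not show.

## Anatomical quantities

Skeletons are polyline forests in micrometre coordinates. Before any
distance query, every edge is subdivided into equal sub-edges of at most
1 µm; subdivision preserves geometry exactly, so total cable is conserved
to machine precision and all subsequent distances are vertex-to-vertex with
a discretization error bounded by the edge length.

An **axon–dendrite proximity** is any (axon vertex, dendrite vertex) pair
at Euclidean distance ≤ 5 µm (boundary inclusive). The proximal set is
defined set-theoretically and found with a KD-tree (`scipy.spatial.cKDTree
.query_ball_tree`); the test suite holds the implementation to exact
agreement with an O(n²) brute force. The **co-travel distance** `L_d` sums
the lengths of dendritic edges incident to at least one proximal dendritic
vertex, each edge counted once — counting an edge per nearby axon vertex
would let `L_d` exceed the neuron's total cable. Both incident edges of a
proximal vertex are included (the symmetric reading; a
downstream-edges-only variant would need rooted orientation information the
SWC forest does not guarantee).

Synapses are attributed to a proximity when within 3 µm (inclusive) of any
proximal vertex. Synapses whose (pre, post) pair has no computed proximity
are flagged, never dropped.

**Cohorts.** For each presynaptic neuron, every reliability-passing
candidate (CC_max > 0.4 and CC_abs > 0.2) is assigned exactly one label:
`connected` (≥ 1 synapse), `adp_control` (no synapse, `L_d` > 0),
`same_region_control` (no synapse, `L_d` = 0, located in a region hosting
that presyn's actual postsynaptic targets — optionally layer-matched for
layer-resolved analyses), or `excluded`. A candidate qualifying for both
controls is an ADP control only; the ADP cohort is the stricter anatomical
null.

## Functional metrics

- `CC_max = sqrt((N·Var(ȳ) − mean Var(y)) / ((N−1)·Var(ȳ)))` over an
  N-repeat stimulus block: the attainable ceiling on model–data
  correlation. A negative radicand or constant trial mean yields NaN —
  undefined metrics propagate as missing values, never zeros.
- `CC_abs`: Pearson correlation between the trial-averaged prediction and
  observation.
- Signal correlation: Pearson correlation over 500-ms bins concatenated
  across trials.
- Feature similarity: cosine of readout feature-weight vectors (length 512
  by default).
- RF-centre distance: visual angle between eye-to-point vectors, with the
  monitor centred on, normal to, and 15 cm from the eye. Readout locations
  are normalized [−1, 1]² monitor coordinates; the physical monitor
  half-extent (default 28 × 16 cm) converts them to centimetres and is a
  config argument, since the viewing distance fixes the geometry only up to
  monitor size.
- `gOSI = |Σ R_θ e^{2iθ}| / Σ R_θ` over 16 equispaced directions;
  `OSI = (R_po − R_ortho)/(R_po + R_ortho)` reads the measured curve at the
  direction pair nearest the preferred orientation (averaging the two
  opposite directions). Units with gOSI ≤ 0.25 are flagged below the
  orientation-analysis gate.
- Direction tuning is fit by least squares with a two-bump von Mises
  mixture `α·e^{κcos(θ−μ)} + β·e^{κcos(θ−μ+π)} + γ`, from 8 equispaced μ
  starts with κ started at 1 (log-parameterized, clipped to keep `e^κ`
  finite); the best residual wins, ties broken toward smaller κ. Preferred
  orientation is μ mod 180°. Near-flat fits are flagged unreliable.

## Mixed models

All three like-to-like models share the linear predictor
`β₀ + β₁·Sim + β₂·Proj + β₃·Sim×Proj + u`, log link, with random
intercepts `u` for presynaptic neuron nested in projection-by-proofread
stratum. The engine is a purpose-built penalized IRLS: for fixed
random-effect variance σ², (β, u) maximize the penalized (quasi-)likelihood;
σ² is updated by the Breslow–Clayton/Laplace rule
σ² ← (u'u + tr(H⁻¹_uu))/q until convergence. Standard errors come from the
fixed-effect block of the inverse penalized information, scaled by the
dispersion. Against `glmmTMB` (full Laplace ML) the Poisson slope agrees to
better than 1% in the cross-check test.

- **`L_d` (axonal scale):** Tweedie family with index ξ ∈ (1, 2) — the
  compound Poisson–gamma: N ~ Pois(λ*) proximity stretches with iid gamma
  lengths, so `L_d = Σ z_i` has a point mass at zero and continuous bulk,
  and `E[L_d] = λ*·µ_gamma`. ξ is profiled over {1.1, …, 1.9} by exact
  series (Dunn–Smyth) log-likelihood with the dispersion φ maximized per
  grid point; the profile is checked to be unimodal. On data generated with
  gamma shape 1.5 (true ξ = 1.4) the profile selects 1.4.
- **`N_syn`:** Poisson. Marginally over the co-travel draw this model's
  similarity slope estimates the *sum* of the axonal and synaptic slopes —
  the count reflects both scales.
- **`N_syn` with offset `log L_d` (synaptic scale):** the synapse
  conversion rate per mm. The offset formulation is algebraically a model
  of the density `N_syn/L_d`; fitting the density as a weighted
  quasi-Poisson (weights `L_d`) gives identical score equations, and the
  two solutions agree to < 1e-12 in the tests.

Conditional like-to-like slopes per projection are `β₁ + β₃[k]` with
delta-method standard errors; projections with ≤ 30 synapses, ≤ 5
presynaptic neurons, or one presyn holding > half the synapses are reported
as filtered, not silently dropped. Benjamini–Hochberg adjustment is applied
within each reported table. Similarity covariates enter raw by default (a
standardize switch exists); raw units keep the slope interpretable as
log-rate change per unit similarity.

Binned visualization curves subtract per-presyn means from both axes
(presynaptic neurons with fewer than two qualifying pairs are dropped), bin
by centred similarity, and attach bootstrap standard errors from 1,000 pair
resamples; bins need more than ten pairs and more than ten presynaptic
neurons to be displayed. The density curve averages over pairs with
`L_d > 0` (the zero-connection restriction would make the density
identically zero).

## Common-input test

For presynaptic neuron *i*, `ρ(i)` is the N_ij·N_ik-weighted mean pairwise
similarity over ordered candidate pairs (j, k); since similarity is
symmetric this equals the unordered sum, which is what the implementation
evaluates. Candidates are all filtered co-registered units, because the
pairwise null predicts a mean count for *every* pair — that is what lets
`ρ'` differ from `ρ`. The null is one Poisson mixed model over all pairs
with every similarity metric and its projection interaction; predictions
marginalize the random intercepts (zero random effect), so `ρ'` encodes the
pairwise rule only, not presyn identity. A two-sided Wilcoxon signed-rank
across presynaptic neurons (≥ 5 with both scores defined, ≥ 2 connected
targets each) compares the two.

## Synthetic worlds

The generator's defaults are the package's study conditions, frozen once:

- Geometry: somas uniform with 10 µm minimum spacing in a 400³ µm volume,
  area boundary plane at x = 200 µm, three depth layers. Arbors are
  branching persistent random walks (axons 2 mm target cable, dendrites
  0.8 mm within a 300 µm radius); walks stop at the cable target so the
  realized length is the target up to one 2-µm step.
- Tuning: preferred orientation mixes a smooth sinusoidal cortical map with
  iid noise (`orientation_map_bias` is the mixture weight); feature vectors
  put 70% of their energy into the orientation doublet (cos 2θ, sin 2θ), so
  feature cosine tracks orientation match; retinotopy is an isotropic
  linear soma-to-monitor map jittered by `rf_scatter` (3° default).
- Connectivity: `L_d` is compound Poisson–gamma (mean 2 contacts of mean
  60 µm, gamma shape 1.5 → ξ = 1.4) with log-mean slope `beta_axonal` per
  unit similarity; `N_syn | L_d ~ Pois(L_d[mm]·rate·exp(beta_synaptic·Sim
  + h·A))`. The higher-order factor `A` marks candidates in the presyn's
  *target assembly* — one of four orientation-defined clusters assigned to
  each presyn at random, independent of its own tuning. A pairwise rule in
  pre–post similarity cannot express this concentration, which is exactly
  what makes it a higher-order structure; `h = 0` recovers a purely
  pairwise generative law, under which the common-input test is calibrated
  (≈ 5% rejection, uniform p-values across 100 worlds).
- Responses: white feature drive through each unit's weights, softplus
  nonlinearity, iid Gaussian noise, plus a repeated block for CC_max.

Two generation paths share this law: the full geometric path (arbors,
KD-tree proximities, synapses at proximal-pair midpoints) and a pair-level
path that draws `L_d` and `N_syn` directly. Statistical experiments use the
pair-level path at sizes (350 neurons, 150 presynaptic, ~52,000 pairs for
slope recovery; 180 neurons, 40 presynaptic, 100 replicate worlds for
calibration) where per-vertex geometry is irrelevant to the quantities
under test.

What passing these tests shows: the estimators recover the parameters of
their own generative law at realistic sizes, the test statistics are
calibrated under the null, and the geometry is exact. What they do not
show: robustness to proofreading truncation biases, co-registration errors,
non-log-linear wiring rules, or morphology beyond an isotropic branching
walk — real arbors are laminated and polarized, and real similarity
structure is richer than one orientation doublet.

## Recurrent-network experiment

The vanilla RNN (tanh recurrence, static input injection, linear readout of
the final state) is implemented directly in numpy with
backpropagation-through-time and Adam; the printed defaults are 1,000
hidden units, 20 time steps, 10 epochs, batch 512. The bundled
synthetic-digits task renders ten 7×5 glyphs at random offsets with pixel
noise into 16×16 images, generated on the fly — no download. The test-scale
experiment uses 400 hidden units, 12,000 training images and batch 256,
which trains in about a minute and reproduces all four connectivity
signatures; at this reduced scale the convergence (ρ vs ρ') sign test is
the noisiest of the four, with occasional null seeds, consistent with its
dependence on network size. Connections are classified at signed weight
> 0.01 (at the printed width this is the top ~35th percentile of the
uniform ±1/√H initialization; an absolute-value variant is a switch).
Ablation candidates additionally require signal correlation > 0.2; random
ablation draws strength-matched counts from all connections via
magnitude-decile matching. Hidden-unit signal correlations concatenate
activations over all time steps by default (final-step-only is a switch).
MNIST/FashionMNIST runs read IDX files from a configured directory.
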