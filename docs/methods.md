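# Methods

This note records the modelling assumptions, parameter choices, and numerical
conventions behind `canmf`, and what the simulation benchmarks do and do not
demonstrate about real recordings.

## Network simulators

Both simulators generate binary spike rasters (time steps × neurons) from
discrete-time Bernoulli recursions, gated by a refractory state that closes
for `refractory_steps` frames after each spike.

**Nodal architecture.** `n_neurons` (default 100) neurons are split into
`n_nodes` (default 5) disjoint nodes. The adjacency matrix is 1 within a node
(diagonal excluded) and 0 between nodes. Neuron *n* spikes at step *t* when a
fresh uniform draw falls below

    rate · (n_nodes / n_neurons) · dt  +  A_row(n) · spikes[t−1]

clipped at 1 and multiplied by the refractory gate. The baseline term makes
each node initiate events at `rate` (default 3 events/s); the adjacency term
is ≥ 1 whenever any node-mate spiked on the previous frame, so propagation
within a node is certain. Consequences worth knowing:

* The neuron that initiates an event fires one frame before, and is
  refractory during, its node's synchronized response. Within-node spike
  trains are therefore identical except for initiator offsets; noise-free
  within-node trace correlations are near, not exactly, 1 (≈0.96–0.99 at the
  default node size). Exactly synchronized events (e.g. forced initial
  spikes) do give correlations of exactly 1.
* `refractory_steps` must be ≥ 2 here: with q ≤ 1 the initiator is eligible
  again when its node-mates fire, and the node locks into a perpetual
  two-phase oscillation that destroys the planted block structure.

**Random-process propagation.** `n_processes` (default 5) latent processes
spike i.i.d. with probability `rate · dt` per step. Each process connects to
all `n_neurons` (default 150) neurons: per process, a random 20% of neurons
draw Uniform(0.2, 1.0) weights and the remaining 80% draw exponential
(rate λ = 8.0472) weights bounded above by 0.2 — λ is such that exactly 20%
of unbounded draws would exceed the bound. The bound is enforced by
resampling (no point mass at 0.2); a clipping mode exists for comparison.
The strong subsets are drawn independently per process. A neuron spikes at
*t* with probability `weights_row · process_spikes[t−1]` (clipped, gated);
neurons have no intrinsic drive, so every neuronal event traces back to a
latent process one frame earlier.

**Calcium and fluorescence.** Spike trains drive a forward-Euler recursion

    Ca[t] = Ca[t−1] − (dt/τ)(Ca[t−1] − baseline) + A_sp·spike[t] + σ_c·dt·ε[t]
    F[t]  = α·Ca[t] + β + σ_F·ε′[t]

with τ = 0.265 s, σ_c = 0.5, baseline 0.1, spike amplitude A_sp = 5, α = 5,
β = 10, σ_F = 1, and Ca[−1] = baseline. The calcium noise enters with the
literal `σ_c·dt` scaling; a `sqrt_dt_noise` flag switches to the
Euler–Maruyama `σ_c·√dt` form (≈5.5× larger per-step noise at 30 Hz). The
recursion requires dt < τ and is rejected otherwise. With both noise scales
zero the output matches the closed-form superposition of geometric decays to
relative error below 1e−10.

## Defaults the simulators had to choose

| parameter | default | rationale |
|---|---|---|
| `dt` | 1/30 s | typical two-photon frame rate; comfortably below τ |
| `n_steps` | 9000 (300 s) | a standard 5-minute session length |
| `refractory_steps` | 2 (≈67 ms) | minimal value that quenches the intra-node echo (see above); real absolute refractory periods are ms-scale, so the smallest workable value is the physiologically defensible one |
| process `rate` | 3 events/s | reuses the nodal nominal rate so event statistics are comparable across architectures |

One master seed spawns independent substreams for connectivity sampling,
spiking, calcium noise, and photon noise, so each stage is separately and
bit-exactly reproducible.

## Decomposition conventions

* **Normalization** is global: one (min, max) pair for the whole trace
  matrix, preserving relative amplitudes across neurons. Per-neuron scaling
  would discard how strongly each neuron is driven, which is exactly the
  information the weight-recovery metrics measure.
* **NMF**: scikit-learn coordinate descent, Frobenius loss, tolerance 1e−4,
  iteration cap 1000, plain `nndsvd` initialization (deterministic, so two
  fits of the same matrix are identical). Components are reported in order
  of decreasing activity variance.
* **Adapted AIC**: `2·(SS_res/σ² + k·(n+t))` with σ² the grand variance of
  the normalized matrix. The printed form of the criterion has R² in the
  numerator, but R² *rises* with k, which would penalize better fits; since
  the fit term is described as the reconstruction error, SS_res is used.
  A `literal_r2=True` mode evaluates the printed form verbatim. The rank
  scan fits k = 1, 2, … and stops at the first AIC increase, selecting the
  preceding k (exhaustive global-argmin mode available; default
  `k_max = min(n_neurons, 30)`).
* **PCA**: economy SVD of the column-centered matrix; deterministic sign fix
  (largest-magnitude loading of each component made positive). Per-component
  variance explained uses squared singular values (the variance convention);
  the linear singular-value proportions are also recorded in
  `extras["singular_value_proportion"]` since both readings of "proportion of
  its singular value" occur in practice. The reported R² is computed on the
  centered matrix, where it equals the cumulative variance proportion.
* **ICA**: FastICA, parallel estimation, logcosh contrast, unit-variance
  whitening, seeded; traces are centered but never individually
  variance-scaled, so relative activity magnitudes survive whitening.
  Non-convergence is flagged on the result, not raised.
* **UMAP**: neurons are points described by their time series (transposed
  input), embedded into k dimensions; `n_neighbors = 15`, `min_dist = 0.1`,
  Euclidean metric, fixed seed (which forces single-threaded layout but
  makes the embedding deterministic). UMAP yields only the weight-matrix
  analogue — no activities, no variance explained.

## Assignment scoring

The nodal criterion aggregates each component's weights per node and demands
an entry that is simultaneously the strict maximum of its row (node) and
column (component); ties fail. The process criterion correlates each
component's weight vector with each process's sampled connection
probabilities and demands a strict row maximum that no other component
claims. Accuracy is the fraction of nodes/processes assigned.

* **Sign convention.** Scoring uses raw (signed) sums and correlations by
  default. PCA/ICA/UMAP orientations are arbitrary in principle but fixed
  and reproducible here (PCA by the sign convention, ICA/UMAP by seeding);
  raw scoring is what reproduces the published baseline accuracy levels for
  all three methods, whereas absolute-value scoring inflates ICA markedly.
  An `absolute=True` mode scores magnitudes and is invariant to flipping any
  component's sign.
* **Displacement** (nodal): per assigned component, mean in-node weight
  minus mean out-of-node weight, divided by the model's maximum absolute
  displacement so scores lie in [−1, 1] and are comparable across models.
  The node→component map is the row argmax even for failing nodes, so the
  score is defined for imperfect models.
* **Activity correlation** (process): component activities are correlated
  against the latent raster shifted by one frame (neurons respond to the
  previous step's process spikes) and convolved through the noise-free
  calcium kernel — components model fluorescence, not spikes. Without the
  shift the correlation is capped by the kernel's one-frame autocorrelation;
  `delay_steps=0` and a raw-raster mode are available.

## Benchmark scale

Replicate campaigns default to 32 replicates (nodal accuracy comparisons)
and 16 replicates (rank-selection scans and process-recovery correlations),
with replicate seeds bound to the replicate index so results are independent
of execution order. The published experiments used 256 replicates; the
smaller campaigns trade Monte-Carlo precision (binomial s.e. of a mean
accuracy over 32 replicates of 5 units ≈ 0.03–0.04) for desk-scale runtime,
and the test tolerances account for this.

## What the simulations do and do not show

The generators emulate the *structure* of population calcium recordings:
sparse synchronized events, a small number of macroscopic drivers, heavily
skewed coupling weights, indicator-limited temporal resolution, and two
noise sources. They do not emulate indicator rise kinetics (single time
constant only), bursting or adaptation, slow drift, neuropil contamination,
motion artifacts, or ROI-segmentation errors. Passing the benchmarks
therefore shows that the pipeline recovers planted linear-mixture structure
under realistic noise — not that every in-vivo recording satisfies the
linear-mixture assumption. On real data, the `fit_recording` path reports
diagnostics (weight-distribution shape, pairwise component-activity
coupling) that should be inspected rather than assumed.

## Known limitations

* The nodal initiator offset means "perfect" within-node correlation is an
  idealization; at 30 Hz and default node size the noise-free correlation is
  ≈0.96–0.99, and tests assert exact unity only for synchronized events.
* NMF weight recovery on the process architecture is extremely clean at the
  default 300 s recording length; published single-instance weight
  correlations near 0.84 likely reflect shorter or noisier recordings than
  these defaults, and the benchmark reports what the stated conditions
  actually produce (≈0.98) rather than tuning the conditions to a target.
* The AIC penalty term scales with n + t, so for very long recordings the
  scan is conservative (later stopping requires proportionally larger
  residual reductions).
* FastICA occasionally fails to converge within its iteration cap on
  near-Gaussian inputs; results are flagged, not discarded.
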