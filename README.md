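# canmf

Sub-network detection in calcium-imaging recordings via non-negative matrix
factorization, with ground-truth spiking-network simulators and benchmarks
against PCA, ICA, and UMAP.

## The problem

Two-photon calcium imaging yields hundreds of single-neuron fluorescence time
series per recording. A recurring analysis goal is to decompose that
population activity into a small number of *sub-networks* — weighted groups of
neurons whose shared, time-varying activation sums to reconstruct the observed
dynamics — without averaging away the temporal structure. `canmf` implements
an NMF pipeline built for this purpose, plus everything needed to validate it:
simulators that plant known network structure, a forward model from spikes to
noisy fluorescence, and metrics that score how well a decomposition recovers
the planted structure.

## The model

Given a trace matrix **X** (time points × neurons, globally rescaled to
[0, 1]), NMF factorizes

    X ≈ W H,   W ≥ 0 (time × k),   H ≥ 0 (k × neurons)

where each row of **H** is a sub-network (per-neuron weights) and the matching
column of **W** its activity over time. Fit quality is the coefficient of
determination R² = 1 − SS_res/SS_tot, and the number of components k is chosen
by an adapted Akaike information criterion

    AIC(k) = 2 · ( SS_res / σ² + k · (n + t) )

scanned over k = 1, 2, … and stopped at the first increase (σ² is the grand
variance of the normalized matrix, n the neuron count, t the time-point
count). PCA (SVD of the per-trace-centered matrix), FastICA, and UMAP (neurons
embedded as points described by their time series) are fitted under matching
normalization conventions as baselines.

Two simulated architectures provide ground truth:

* **Nodal** — 100 neurons in 5 disjoint, perfectly intraconnected nodes;
  a spike by any member recruits the whole node on the next frame.
* **Random-process propagation** — 5 latent Bernoulli spike processes drive
  150 neurons through a sampled weight matrix (20% strong uniform weights,
  80% capped-exponential weak weights).

Spikes become fluorescence through a single-time-constant calcium recursion
(jGCaMP7f-like, τ = 0.265 s) with calcium and photon noise. Recovered
components are scored by a two-condition assignment criterion (per node or
per latent process), a per-component weight-displacement score, and Pearson
correlations of weights and activities against the planted ground truth.

## Worked example

```python
import numpy as np
from canmf import (NodalConfig, simulate_nodal, normalize_global,
                   scan_rank, fit_nmf, assess_nodal)

config = NodalConfig(seed=1)            # 100 neurons, 5 nodes, 300 s at 30 Hz
traces, spikes, truth = simulate_nodal(config)
X = normalize_global(traces)

scan = scan_rank(X)
print(f"selected k = {scan.selected_k}")
print("AIC trajectory:", [f"{a/1e6:.3f}" for a in scan.aic_values])

model = fit_nmf(X, scan.selected_k)
print(f"R^2 at k={model.k}: {model.r_squared:.3f}")

report = assess_nodal(model, truth)
print(f"assignment accuracy: {report.accuracy}")
print("displacement:", np.round(report.displacement_scores, 3))
```

prints

```
selected k = 5
AIC trajectory: ['1.484', '1.127', '0.792', '0.461', '0.141', '0.159']
R^2 at k=5: 0.972
assignment accuracy: 1.0
displacement: [1.    0.88  0.736 0.775 0.733]
```

The AIC falls until five components (the planted node count) and rises at
six, so the scan stops and selects k = 5. The refitted model explains 97% of
the variance; every node maps one-to-one onto a component (accuracy 1.0), and
all displacement scores are positive — each component's assigned node carries
visibly higher weights than the rest of the population.

The same workflow is available from the shell:

```bash
canmf simulate nodal --seed 1 --out-dir sim/
canmf fit sim/traces.csv --method nmf --auto-k --out model/
canmf assess --truth sim/ground_truth.json --decomp model/
canmf benchmark --arch nodal --replicates 32 --seed 0 --out bench/
canmf fit-recording my_traces.csv --out recording/   # user-supplied data
```

`fit-recording` applies the normalize → AIC scan → NMF path to any
non-negative trace CSV (time × neurons, header row of neuron IDs, optional
`# dt=` comment) and reports weight-distribution and component-coupling
diagnostics.

## Layout

```
src/canmf/simulate.py     simulators + calcium/fluorescence forward model
src/canmf/decompose.py    normalization, NMF/PCA/ICA/UMAP, R², AIC, rank scan
src/canmf/assess.py       assignment criteria, displacement, correlations
src/canmf/experiments.py  replicate benchmarks, recording-fitting path
src/canmf/io.py, cli.py   CSV/JSON readers-writers, manifests, CLI
docs/methods.md           modelling assumptions, defaults, limitations
```
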