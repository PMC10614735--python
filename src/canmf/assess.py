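"""Scoring a fitted decomposition against simulator ground truth.

Two discrete assignment-success frameworks, one per simulated architecture:

* **Nodal** — component weights are summed per node into an
  n_nodes x k aggregated weight matrix. A node is successfully assigned
  when some entry of its row is simultaneously the strict maximum of its
  row and of its column (an ideal model has one such entry per row and
  column). Accuracy is the fraction of nodes assigned.
* **Process** — a k x k Pearson correlation matrix between component
  neuron-weight vectors and the sampled process-to-neuron connection
  probabilities. A component is successfully assigned when its best
  correlation strictly exceeds its correlations with every other process
  *and* no other component picks the same process.

Continuous companions: the per-component weight displacement (mean in-node
weight minus mean out-of-node weight, normalized per model) and the Pearson
correlation between component activities and the latent process activity
passed through the noise-free calcium kernel.

Sign convention: scoring uses the raw (signed) weight sums and correlations
by default. PCA/ICA/UMAP components carry an arbitrary overall sign or
location; PCA rows are deterministically oriented at fit time and ICA/UMAP
keep their (seeded, reproducible) solver orientation. ``absolute=True``
scores absolute values instead, which makes every score invariant to
flipping the sign of any single component row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import CalciumParams, GroundTruth, SpikeRaster, spikes_to_fluorescence

__all__ = [
    "AssignmentReport",
    "aggregate_node_weights",
    "assign_nodes",
    "weight_displacement",
    "process_correlation_matrix",
    "assign_processes",
    "activity_correlation",
    "assess_nodal",
    "assess_process",
]

SIGN_INDETERMINATE = {"pca", "ica", "umap"}


@dataclass
class AssignmentReport:
    """Outcome of scoring one decomposition against one ground truth.

    ``assignment_map`` is node -> component for the nodal framework and
    component -> process for the process framework (best match under the
    relevant criterion, recorded even for failing units so the continuous
    scores remain defined).
    """

    kind: str  # "nodal" | "process"
    per_unit_success: np.ndarray
    accuracy: float
    assignment_map: np.ndarray
    displacement_scores: np.ndarray | None = None
    weight_correlations: np.ndarray | None = None
    activity_correlations: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# nodal framework
# ---------------------------------------------------------------------------


def aggregate_node_weights(H: np.ndarray, node_membership: np.ndarray) -> np.ndarray:
    """Sum each component's weights over the neurons of each node.

    Returns an n_nodes x k matrix whose (i, j) entry is the sum of
    component j's weights over the neurons of node i.
    """
    H = np.asarray(H, dtype=float)
    membership = np.asarray(node_membership)
    if membership.shape != (H.shape[1],):
        raise ValueError(
            f"node_membership length {membership.shape} does not cover the "
            f"{H.shape[1]} neurons of H"
        )
    if np.any(membership < 0):
        raise ValueError("every neuron needs a non-negative node label")
    n_nodes = int(membership.max()) + 1
    agg = np.zeros((n_nodes, H.shape[0]))
    for i in range(n_nodes):
        agg[i] = H[:, membership == i].sum(axis=1)
    return agg


def _strict_row_col_max(agg: np.ndarray, i: int, j: int) -> bool:
    row, col = agg[i], agg[:, j]
    v = agg[i, j]
    row_ok = np.all(np.delete(row, j) < v)
    col_ok = np.all(np.delete(col, i) < v)
    return bool(row_ok and col_ok)


def assign_nodes(agg: np.ndarray) -> AssignmentReport:
    """Apply the two-condition success criterion to an aggregated matrix.

    Node i succeeds iff some entry agg[i, j] strictly exceeds every other
    entry of column j (condition one) and every other entry of row i
    (condition two). Exact ties fail the strict comparisons, so tied
    candidates are never counted as successes. The assignment map records
    each node's row-argmax component regardless of success.
    """
    agg = np.asarray(agg, dtype=float)
    if not np.isfinite(agg).all():
        raise ValueError("aggregated weight matrix must be finite")
    n_nodes, k = agg.shape
    success = np.zeros(n_nodes, dtype=bool)
    mapping = np.empty(n_nodes, dtype=int)
    for i in range(n_nodes):
        j = int(np.argmax(agg[i]))
        mapping[i] = j
        success[i] = any(_strict_row_col_max(agg, i, jj) for jj in range(k))
    return AssignmentReport(
        kind="nodal",
        per_unit_success=success,
        accuracy=float(success.mean()),
        assignment_map=mapping,
    )


def weight_displacement(
    H: np.ndarray,
    node_membership: np.ndarray,
    assignment_map: np.ndarray,
    absolute: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Per-node separation between in-node and out-of-node weights.

    For node i assigned to component j, the raw displacement is
    mean(weight of node-i neurons in component j) minus mean(weight of all
    other neurons in component j); positive values mean the assigned node
    carries the higher weights. With ``normalize=True`` the raw scores are
    divided by the model's maximum absolute displacement, mapping them to
    [-1, 1] so models of different weight scales are comparable.
    """
    H = np.asarray(H, dtype=float)
    if absolute:
        H = np.abs(H)
    membership = np.asarray(node_membership)
    n_nodes = int(membership.max()) + 1
    if n_nodes < 2:
        raise ValueError("displacement is undefined for a single-node model")
    raw = np.empty(n_nodes)
    for i in range(n_nodes):
        j = int(assignment_map[i])
        inside = membership == i
        raw[i] = H[j, inside].mean() - H[j, ~inside].mean()
    if not normalize:
        return raw
    scale = np.abs(raw).max()
    return raw / scale if scale > 0 else raw


# ---------------------------------------------------------------------------
# process framework
# ---------------------------------------------------------------------------


def process_correlation_matrix(
    H: np.ndarray, process_weights: np.ndarray
) -> np.ndarray:
    """Pearson correlations between component weights and process weights.

    Entry (c, p) correlates component c's neuron-weight vector with latent
    process p's connection-probability vector. Zero-variance vectors give
    NaN entries (correlation undefined).
    """
    H = np.asarray(H, dtype=float)
    P = np.asarray(process_weights, dtype=float)
    if H.shape[1] != P.shape[1]:
        raise ValueError(
            f"H has {H.shape[1]} neurons but process_weights has {P.shape[1]}"
        )
    k, kp = H.shape[0], P.shape[0]
    corr = np.full((k, kp), np.nan)
    for c in range(k):
        hc = H[c] - H[c].mean()
        sh = np.sqrt((hc**2).sum())
        if sh == 0:
            continue
        for p in range(kp):
            pp = P[p] - P[p].mean()
            sp = np.sqrt((pp**2).sum())
            if sp == 0:
                continue
            corr[c, p] = float(hc @ pp / (sh * sp))
    return corr


def assign_processes(corr: np.ndarray, absolute: bool = False) -> AssignmentReport:
    """Apply the two-condition criterion to a component-process correlation matrix.

    Component c is matched to its most-correlated process; the match
    succeeds iff that correlation strictly exceeds the component's
    correlation with every other process *and* no other component matches
    the same process (each component must identify a unique process).
    Missing (NaN) correlations never win. Raw correlations are compared by
    default; ``absolute=True`` compares absolute values.
    """
    corr = np.asarray(corr, dtype=float)
    scores = np.abs(corr) if absolute else corr
    scores = np.where(np.isnan(scores), -np.inf, scores)
    k = corr.shape[0]
    mapping = np.argmax(scores, axis=1)
    success = np.zeros(k, dtype=bool)
    for c in range(k):
        best = scores[c, mapping[c]]
        if not np.isfinite(best):
            continue
        others = np.delete(scores[c], mapping[c])
        strict = np.all(others < best)
        unique = np.sum(mapping == mapping[c]) == 1
        success[c] = bool(strict and unique)
    return AssignmentReport(
        kind="process",
        per_unit_success=success,
        accuracy=float(success.mean()),
        assignment_map=mapping,
    )


def reference_process_activity(
    process_raster: SpikeRaster, params: CalciumParams, delay_steps: int = 1
) -> np.ndarray:
    """Latent process raster passed through the noise-free calcium kernel.

    Decomposition activities model fluorescence, not spikes, so the fair
    reference for activity correlations is each process's spike train
    convolved with the same calcium/fluorescence forward model, with both
    noise sources switched off. Because neurons respond to the process
    spikes of the *previous* step, the raster is shifted by ``delay_steps``
    (default one step) before convolution so the reference is aligned with
    the population response it drives.
    """
    values = process_raster.values
    if delay_steps:
        values = np.vstack(
            [np.zeros((delay_steps, values.shape[1]), dtype=values.dtype),
             values[:-delay_steps]]
        )
    shifted = SpikeRaster(values, dt=process_raster.dt)
    return spikes_to_fluorescence(shifted, params.noiseless(), seed=0).values


def activity_correlation(
    W: np.ndarray,
    process_raster: SpikeRaster,
    params: CalciumParams,
    assignment_map: np.ndarray,
    use_kernel: bool = True,
) -> np.ndarray:
    """Pearson r between component activities and assigned process activity.

    Component c's activity column is correlated with its assigned process's
    reference activity (the raster convolved through the noise-free calcium
    kernel by default; ``use_kernel=False`` correlates against the raw
    binary raster). Constant activities yield NaN.
    """
    if W is None:
        raise ValueError(
            "this decomposition has no activity time series (UMAP produces none)"
        )
    W = np.asarray(W, dtype=float)
    ref = (
        reference_process_activity(process_raster, params)
        if use_kernel
        else process_raster.values.astype(float)
    )
    if W.shape[0] != ref.shape[0]:
        raise ValueError(
            f"activities have {W.shape[0]} steps but the process raster has "
            f"{ref.shape[0]}"
        )
    out = np.full(W.shape[1], np.nan)
    for c in range(W.shape[1]):
        a = W[:, c] - W[:, c].mean()
        b = ref[:, assignment_map[c]] - ref[:, assignment_map[c]].mean()
        sa, sb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
        if sa == 0 or sb == 0:
            continue
        out[c] = float(a @ b / (sa * sb))
    return out


# ---------------------------------------------------------------------------
# one-call pipelines
# ---------------------------------------------------------------------------


def assess_nodal(
    decomposition, truth: GroundTruth, absolute: bool = False
) -> AssignmentReport:
    """Score a decomposition of nodal-architecture traces.

    Aggregates weights per node, applies the two-condition criterion, and
    attaches normalized per-node displacement scores. ``absolute=True``
    compares absolute aggregated sums and absolute weights (useful when
    component orientation should not matter).
    """
    if truth.kind != "nodal":
        raise ValueError("assess_nodal requires nodal ground truth")
    agg = aggregate_node_weights(decomposition.weights, truth.node_membership)
    if absolute:
        agg = np.abs(agg)
    report = assign_nodes(agg)
    report.displacement_scores = weight_displacement(
        decomposition.weights,
        truth.node_membership,
        report.assignment_map,
        absolute=absolute,
    )
    report.extras["aggregated_weights"] = agg
    return report


def assess_process(
    decomposition,
    truth: GroundTruth,
    params: CalciumParams | None = None,
    absolute: bool = False,
) -> AssignmentReport:
    """Score a decomposition of process-architecture traces.

    Builds the component-process correlation matrix, applies the
    two-condition criterion (raw correlations by default,
    ``absolute=True`` for orientation-blind scoring), and attaches the
    per-component weight correlation at the assigned process plus, when
    the method produces activities, the activity correlation against the
    delay-aligned, kernel-convolved latent process.
    """
    if truth.kind != "process":
        raise ValueError("assess_process requires process ground truth")
    if params is None:
        params = CalciumParams(dt=truth.process_raster.dt)
    corr = process_correlation_matrix(decomposition.weights, truth.process_weights)
    report = assign_processes(corr, absolute=absolute)
    scored = np.abs(corr) if absolute else corr
    report.weight_correlations = scored[
        np.arange(corr.shape[0]), report.assignment_map
    ]
    if decomposition.activities is not None:
        act = activity_correlation(
            decomposition.activities,
            truth.process_raster,
            params,
            report.assignment_map,
        )
        if absolute:
            act = np.abs(act)
        report.activity_correlations = act
    report.extras["correlation_matrix"] = corr
    return report
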