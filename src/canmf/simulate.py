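"""Ground-truth spiking-network simulators and the calcium fluorescence forward model.

Two network architectures generate benchmark data for sub-network detection:

* **Nodal** — ``n_neurons`` neurons split into ``n_nodes`` disjoint,
  perfectly intraconnected nodes. A spike by any member recruits every
  non-refractory member of the same node on the next time step, so each
  node behaves as a single synchronous unit.
* **Process propagation** — a small number of latent Bernoulli spike
  processes drive the whole population through a sampled weight matrix,
  so every neuron reflects a weighted mixture of a few hidden drivers.

Spike rasters from either architecture are converted to noisy fluorescence
traces by a single-time-constant calcium recursion followed by an affine
photon map, emulating a fast genetically encoded calcium indicator
(jGCaMP7f-like kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "NodalConfig",
    "ProcessConfig",
    "CalciumParams",
    "AdjacencyMatrix",
    "SpikeRaster",
    "TraceMatrix",
    "GroundTruth",
    "build_nodal_adjacency",
    "simulate_nodal_spikes",
    "sample_process_weights",
    "simulate_process_spikes",
    "spikes_to_fluorescence",
    "nodal_membership",
    "simulate_nodal",
    "simulate_process",
]

DEFAULT_DT = 1.0 / 30.0  # s; typical two-photon frame interval
DEFAULT_N_STEPS = 9000  # 300 s of recording at 30 Hz


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodalConfig:
    """Parameters of the perfectly intraconnected, independent-node network.

    ``rate`` is the nominal per-node event rate (events per second): each
    neuron's baseline spike probability per step is
    ``rate * n_nodes / n_neurons * dt``, so a node of
    ``n_neurons / n_nodes`` neurons initiates events at ``rate`` per second
    in the absence of refractory saturation.
    """

    n_neurons: int = 100
    n_nodes: int = 5
    rate: float = 3.0
    dt: float = DEFAULT_DT
    n_steps: int = DEFAULT_N_STEPS
    refractory_steps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_nodes < 1:
            raise ValueError("n_neurons and n_nodes must be positive")
        if self.n_neurons % self.n_nodes != 0:
            raise ValueError(
                f"n_neurons={self.n_neurons} must be divisible by n_nodes={self.n_nodes}"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        p0 = self.rate * self.n_nodes / self.n_neurons * self.dt
        if not 0.0 <= p0 <= 1.0:
            raise ValueError(
                f"baseline spike probability rate*(n_nodes/n_neurons)*dt = {p0:.4g} "
                "must lie in [0, 1]"
            )

    @property
    def node_size(self) -> int:
        return self.n_neurons // self.n_nodes

    @property
    def baseline_probability(self) -> float:
        return self.rate * self.n_nodes / self.n_neurons * self.dt


@dataclass(frozen=True)
class ProcessConfig:
    """Parameters of the random-process propagation network.

    Each of ``n_processes`` latent processes spikes independently with
    probability ``rate * dt`` per step. Every neuron receives each process
    with a weight in [0, 1]: a ``strong_fraction`` subset of neurons draws
    Uniform(``strong_low``, ``strong_high``) weights, the remainder draw
    exponential(``exp_rate``) weights bounded above by ``exp_cap``, so a few
    strongly driven neurons dominate while most follow weakly.
    """

    n_neurons: int = 150
    n_processes: int = 5
    rate: float = 3.0
    dt: float = DEFAULT_DT
    n_steps: int = DEFAULT_N_STEPS
    refractory_steps: int = 2
    strong_fraction: float = 0.20
    strong_low: float = 0.2
    strong_high: float = 1.0
    exp_rate: float = 8.0472
    exp_cap: float = 0.2
    weak_tail: Literal["resample", "clip"] = "resample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_processes < 1:
            raise ValueError("n_neurons and n_processes must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")
        if not 0.0 <= self.strong_fraction <= 1.0:
            raise ValueError("strong_fraction must lie in [0, 1]")
        if not 0.0 <= self.strong_low < self.strong_high <= 1.0:
            raise ValueError("need 0 <= strong_low < strong_high <= 1")
        if self.exp_rate <= 0:
            raise ValueError("exp_rate must be positive")
        if not 0.0 < self.exp_cap <= 1.0:
            raise ValueError("exp_cap must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.rate * self.dt <= 1.0:
            raise ValueError(f"rate*dt = {self.rate * self.dt:.4g} must lie in [0, 1]")


@dataclass(frozen=True)
class CalciumParams:
    """Parameters of the calcium recursion and fluorescence map.

    The intracellular calcium proxy decays toward ``baseline`` with time
    constant ``tau`` (seconds), jumps by ``spike_amplitude`` on each spike,
    and accumulates Gaussian noise of scale ``sigma_ca``. Fluorescence is
    ``alpha * Ca + beta`` plus Gaussian shot noise of scale ``sigma_f``.

    By default the calcium noise term enters as ``sigma_ca * dt * eps``;
    ``sqrt_dt_noise=True`` switches to the Euler–Maruyama scaling
    ``sigma_ca * sqrt(dt) * eps``.
    """

    tau: float = 0.265
    sigma_ca: float = 0.5
    baseline: float = 0.1
    spike_amplitude: float = 5.0
    alpha: float = 5.0
    beta: float = 10.0
    sigma_f: float = 1.0
    dt: float = DEFAULT_DT
    sqrt_dt_noise: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_ca < 0 or self.sigma_f < 0:
            raise ValueError("noise scales must be non-negative")

    def noiseless(self) -> "CalciumParams":
        """Copy of these parameters with all noise switched off."""
        return replace(self, sigma_ca=0.0, sigma_f=0.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyMatrix:
    """Connectivity weights.

    ``orientation="incoming"``: square N x N matrix, row n holds the
    incoming connections of neuron n (nodal architecture, entries in {0,1}).
    ``orientation="process"``: k x N matrix, row p holds the connection
    probabilities from latent process p to every neuron (entries in [0,1]).
    """

    values: np.ndarray
    orientation: Literal["incoming", "process"] = "incoming"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("adjacency must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("adjacency weights must be non-negative")


@dataclass
class SpikeRaster:
    """Binary spike indicator array, time steps x neurons."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("spike raster must be 2-D (time x neurons)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("spike raster entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass
class TraceMatrix:
    """Fluorescence trace array, time steps x neurons."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (time x neurons)")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix entries must be finite")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    """What the simulator actually planted, for scoring a decomposition.

    * nodal: ``node_membership`` maps each neuron to its node index.
    * process: ``process_weights`` is the k x N connection-probability
      matrix used in the simulation and ``process_raster`` the latent
      process spike raster (time x k).
    """

    kind: Literal["nodal", "process"]
    node_membership: np.ndarray | None = None
    process_weights: np.ndarray | None = None
    process_raster: SpikeRaster | None = None

    def __post_init__(self) -> None:
        if self.kind == "nodal":
            if self.node_membership is None:
                raise ValueError("nodal ground truth requires node_membership")
            self.node_membership = np.asarray(self.node_membership, dtype=int)
        elif self.kind == "process":
            if self.process_weights is None or self.process_raster is None:
                raise ValueError(
                    "process ground truth requires process_weights and process_raster"
                )
            self.process_weights = np.asarray(self.process_weights, dtype=float)
        else:
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")

    @property
    def n_units(self) -> int:
        """Number of ground-truth units (nodes or latent processes)."""
        if self.kind == "nodal":
            return int(self.node_membership.max()) + 1
        return self.process_weights.shape[0]


# ---------------------------------------------------------------------------
# nodal architecture
# ---------------------------------------------------------------------------


def nodal_membership(config: NodalConfig) -> np.ndarray:
    """Neuron -> node index map: consecutive blocks of ``node_size`` neurons."""
    return np.repeat(np.arange(config.n_nodes), config.node_size)


def build_nodal_adjacency(config: NodalConfig) -> AdjacencyMatrix:
    """Block-diagonal 0/1 adjacency: 1 within a node, 0 between, zero diagonal."""
    membership = nodal_membership(config)
    values = (membership[:, None] == membership[None, :]).astype(float)
    np.fill_diagonal(values, 0.0)
    return AdjacencyMatrix(values, orientation="incoming")


def _gated_bernoulli_raster(
    n_steps: int,
    n_neurons: int,
    refractory_steps: int,
    rng: np.random.Generator,
    drive: "callable",
    initial_spikes: np.ndarray | None,
    initial_probability: float,
) -> np.ndarray:
    """Shared recursion for both architectures.

    At each step a neuron spikes iff a fresh uniform draw falls below its
    drive probability (clipped at 1) *and* its refractory gate is open. The
    gate closes for ``refractory_steps`` steps after every spike.
    """
    spikes = np.zeros((n_steps, n_neurons), dtype=np.uint8)
    if initial_spikes is not None:
        initial = np.asarray(initial_spikes).astype(bool)
        if initial.shape != (n_neurons,):
            raise ValueError("initial_spikes must have shape (n_neurons,)")
        spikes[0] = initial
    else:
        spikes[0] = rng.random(n_neurons) < initial_probability
    remaining = np.where(spikes[0] == 1, refractory_steps, 0)
    for t in range(1, n_steps):
        p = np.clip(drive(spikes[t - 1]), 0.0, 1.0)
        open_gate = remaining == 0
        fired = (rng.random(n_neurons) < p) & open_gate
        spikes[t] = fired
        remaining = np.where(fired, refractory_steps, np.maximum(remaining - 1, 0))
    return spikes


def simulate_nodal_spikes(
    config: NodalConfig,
    adjacency: AdjacencyMatrix,
    rng: np.random.Generator | None = None,
    initial_spikes: np.ndarray | None = None,
) -> SpikeRaster:
    """Simulate the nodal network's spiking.

    A neuron spikes at step t when a uniform draw falls below
    ``rate*(n_nodes/n_neurons)*dt + A_row . spikes[t-1]``, clipped at 1 and
    gated by its refractory state. An incoming connection of weight 1 from a
    neuron that spiked at t-1 therefore forces a spike (certainty
    propagation) unless the neuron is refractory.

    Step 0 spikes come from the baseline term alone, or from
    ``initial_spikes`` when supplied (useful for controlled propagation
    experiments).
    """
    A = adjacency.values
    if A.shape != (config.n_neurons, config.n_neurons):
        raise ValueError(
            f"adjacency shape {A.shape} does not match n_neurons={config.n_neurons}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p0 = config.baseline_probability
    values = _gated_bernoulli_raster(
        config.n_steps,
        config.n_neurons,
        config.refractory_steps,
        rng,
        drive=lambda prev: p0 + A @ prev,
        initial_spikes=initial_spikes,
        initial_probability=p0,
    )
    return SpikeRaster(values, dt=config.dt)


# ---------------------------------------------------------------------------
# process-propagation architecture
# ---------------------------------------------------------------------------


def sample_process_weights(
    config: ProcessConfig, rng: np.random.Generator | None = None
) -> AdjacencyMatrix:
    """Sample the k x N process-to-neuron connection-probability matrix.

    Per process, a fresh random ``strong_fraction`` subset of neurons gets
    Uniform(strong_low, strong_high) weights; every other neuron gets an
    exponential(exp_rate) weight bounded above by ``exp_cap``. The bound is
    enforced by resampling draws above the cap (no point mass at the cap);
    ``weak_tail="clip"`` switches to hard clipping.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k, n = config.n_processes, config.n_neurons
    n_strong = int(round(config.strong_fraction * n))
    weights = np.empty((k, n))
    for p in range(k):
        strong = rng.choice(n, size=n_strong, replace=False)
        row = _sample_capped_exponential(
            n, config.exp_rate, config.exp_cap, config.weak_tail, rng
        )
        row[strong] = rng.uniform(config.strong_low, config.strong_high, size=n_strong)
        weights[p] = row
    return AdjacencyMatrix(weights, orientation="process")


def _sample_capped_exponential(
    size: int, rate: float, cap: float, tail: str, rng: np.random.Generator
) -> np.ndarray:
    draws = rng.exponential(scale=1.0 / rate, size=size)
    if tail == "clip":
        return np.minimum(draws, cap)
    # resample the tail until every draw falls below the cap
    over = draws > cap
    while over.any():
        draws[over] = rng.exponential(scale=1.0 / rate, size=int(over.sum()))
        over = draws > cap
    return draws


def simulate_process_spikes(
    config: ProcessConfig,
    weights: AdjacencyMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeRaster, GroundTruth]:
    """Simulate latent processes and the neuron spikes they drive.

    Each of the k processes spikes i.i.d. with probability ``rate*dt`` per
    step. A neuron spikes at t with probability
    ``weights_row . process_spikes[t-1]`` (clipped at 1), gated by its
    refractory state; neurons have no baseline drive of their own.
    Returns the neuron raster together with the ground truth (the weight
    matrix and the latent process raster).
    """
    Wm = weights.values
    if Wm.shape != (config.n_processes, config.n_neurons):
        raise ValueError(
            f"weights shape {Wm.shape} does not match "
            f"(n_processes={config.n_processes}, n_neurons={config.n_neurons})"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_proc = config.rate * config.dt
    process_values = (
        rng.random((config.n_steps, config.n_processes)) < p_proc
    ).astype(np.uint8)
    # The neuron drive depends on the *process* raster, not the neuron raster,
    # so run the gated recursion explicitly rather than via the shared helper.
    spikes = np.zeros((config.n_steps, config.n_neurons), dtype=np.uint8)
    remaining = np.zeros(config.n_neurons, dtype=int)
    for t in range(1, config.n_steps):
        p = np.clip(process_values[t - 1] @ Wm, 0.0, 1.0)
        open_gate = remaining == 0
        fired = (rng.random(config.n_neurons) < p) & open_gate
        spikes[t] = fired
        remaining = np.where(
            fired, config.refractory_steps, np.maximum(remaining - 1, 0)
        )
    raster = SpikeRaster(spikes, dt=config.dt)
    process_raster = SpikeRaster(process_values, dt=config.dt)
    truth = GroundTruth(
        kind="process", process_weights=Wm, process_raster=process_raster
    )
    return raster, truth


# ---------------------------------------------------------------------------
# calcium / fluorescence forward model
# ---------------------------------------------------------------------------


def spikes_to_fluorescence(
    raster: SpikeRaster,
    params: CalciumParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TraceMatrix:
    """Convert a spike raster to noisy fluorescence traces.

    Per neuron the calcium proxy follows the forward-Euler recursion

        Ca[t] = Ca[t-1] - (dt/tau) * (Ca[t-1] - baseline)
                + spike_amplitude * spike[t] + sigma_ca * s(dt) * eps[t]

    with ``Ca[-1] = baseline`` and ``s(dt) = dt`` (or ``sqrt(dt)`` when
    ``sqrt_dt_noise`` is set), and fluorescence is

        F[t] = alpha * Ca[t] + beta + sigma_f * eps'[t].

    Calcium and fluorescence noise draws come from independent substreams of
    the supplied seed, so traces are bit-reproducible.
    """
    if params is None:
        params = CalciumParams(dt=raster.dt)
    if not np.isclose(params.dt, raster.dt):
        raise ValueError(
            f"params.dt={params.dt} does not match raster.dt={raster.dt}"
        )
    if params.dt >= params.tau:
        raise ValueError(
            f"dt={params.dt} must be smaller than tau={params.tau}: the "
            "forward-Euler decay step is unstable otherwise"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    ca_stream, f_stream = [np.random.default_rng(s) for s in rng.bit_generator.seed_seq.spawn(2)]

    spikes = raster.values.astype(float)
    n_steps, n_neurons = spikes.shape
    decay = params.dt / params.tau
    noise_scale = np.sqrt(params.dt) if params.sqrt_dt_noise else params.dt

    ca_noise = (
        params.sigma_ca * noise_scale * ca_stream.standard_normal((n_steps, n_neurons))
        if params.sigma_ca > 0
        else np.zeros((n_steps, n_neurons))
    )
    ca = np.empty((n_steps, n_neurons))
    prev = np.full(n_neurons, params.baseline)
    for t in range(n_steps):
        prev = (
            prev
            - decay * (prev - params.baseline)
            + params.spike_amplitude * spikes[t]
            + ca_noise[t]
        )
        ca[t] = prev

    f = params.alpha * ca + params.beta
    if params.sigma_f > 0:
        f = f + params.sigma_f * f_stream.standard_normal((n_steps, n_neurons))
    return TraceMatrix(f, dt=raster.dt)


# ---------------------------------------------------------------------------
# convenience pipelines
# ---------------------------------------------------------------------------


def simulate_nodal(
    config: NodalConfig, calcium: CalciumParams | None = None
) -> tuple[TraceMatrix, SpikeRaster, GroundTruth]:
    """Simulate a full nodal data set: spikes, traces and ground truth.

    The config seed spawns independent substreams for spiking and for the
    calcium/fluorescence noise, so each stage is separately reproducible.
    """
    if calcium is None:
        calcium = CalciumParams(dt=config.dt)
    spike_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(2)
    adjacency = build_nodal_adjacency(config)
    raster = simulate_nodal_spikes(
        config, adjacency, rng=np.random.default_rng(spike_ss)
    )
    traces = spikes_to_fluorescence(raster, calcium, rng=np.random.default_rng(noise_ss))
    truth = GroundTruth(kind="nodal", node_membership=nodal_membership(config))
    return traces, raster, truth


def simulate_process(
    config: ProcessConfig, calcium: CalciumParams | None = None
) -> tuple[TraceMatrix, SpikeRaster, GroundTruth]:
    """Simulate a full process-propagation data set.

    The config seed spawns independent substreams for the weight matrix,
    the spiking recursion, and the calcium/fluorescence noise.
    """
    if calcium is None:
        calcium = CalciumParams(dt=config.dt)
    weight_ss, spike_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(3)
    weights = sample_process_weights(config, rng=np.random.default_rng(weight_ss))
    raster, truth = simulate_process_spikes(
        config, weights, rng=np.random.default_rng(spike_ss)
    )
    traces = spikes_to_fluorescence(raster, calcium, rng=np.random.default_rng(noise_ss))
    return traces, raster, truth
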