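"""Simulator unit and property tests: adjacency, spiking, weights, calcium."""

import dataclasses

import numpy as np
import pytest

from canmf import (
    AdjacencyMatrix,
    CalciumParams,
    NodalConfig,
    ProcessConfig,
    SpikeRaster,
    build_nodal_adjacency,
    sample_process_weights,
    simulate_nodal,
    simulate_nodal_spikes,
    simulate_process,
    simulate_process_spikes,
    spikes_to_fluorescence,
)
from canmf.simulate import nodal_membership


# ---------------------------------------------------------------------------
# nodal adjacency
# ---------------------------------------------------------------------------


class TestNodalAdjacency:
    def test_default_network_rows_have_19_in_block_ones(self):
        cfg = NodalConfig(n_neurons=100, n_nodes=5)
        A = build_nodal_adjacency(cfg).values
        assert A.shape == (100, 100)
        assert np.all(A.sum(axis=1) == 19)
        membership = nodal_membership(cfg)
        # every connection stays within its 20-neuron block
        rows, cols = np.nonzero(A)
        assert np.all(membership[rows] == membership[cols])
        assert np.all(np.diag(A) == 0)

    def test_singleton_nodes_give_zero_matrix(self):
        A = build_nodal_adjacency(NodalConfig(n_neurons=2, n_nodes=2, n_steps=1)).values
        assert np.array_equal(A, np.zeros((2, 2)))

    def test_two_pair_nodes_enumerated(self):
        A = build_nodal_adjacency(NodalConfig(n_neurons=4, n_nodes=2, n_steps=1)).values
        expected = np.array(
            [
                [0, 1, 0, 0],
                [1, 0, 0, 0],
                [0, 0, 0, 1],
                [0, 0, 1, 0],
            ],
            dtype=float,
        )
        assert np.array_equal(A, expected)
        assert A.sum() == 4

    def test_indivisible_node_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NodalConfig(n_neurons=10, n_nodes=3)


# ---------------------------------------------------------------------------
# nodal spiking
# ---------------------------------------------------------------------------


class TestNodalSpiking:
    def test_zero_rate_zero_adjacency_silent(self):
        cfg = NodalConfig(n_neurons=10, n_nodes=5, rate=0.0, n_steps=50, seed=1)
        A = AdjacencyMatrix(np.zeros((10, 10)))
        raster = simulate_nodal_spikes(cfg, A)
        assert raster.values.sum() == 0

    def test_seed_spike_recruits_whole_node_and_nothing_else(self):
        # one forced spike in node 0 at t=0, no baseline drive: at t=1 every
        # other member of node 0 spikes with certainty; other nodes stay silent
        cfg = NodalConfig(n_neurons=100, n_nodes=5, rate=0.0, n_steps=4, seed=0)
        A = build_nodal_adjacency(cfg)
        initial = np.zeros(100)
        initial[3] = 1
        raster = simulate_nodal_spikes(cfg, A, initial_spikes=initial).values
        assert raster[1, :20].sum() == 19  # all of node 0 except the refractory seeder
        assert raster[1, 3] == 0
        assert raster[1, 20:].sum() == 0

    def test_certain_rate_with_two_step_refractory_spikes_every_third_step(self):
        # single neuron, r*dt = 1: deterministic spiking limited only by the gate
        cfg = NodalConfig(
            n_neurons=1, n_nodes=1, rate=30.0, dt=1.0 / 30.0, n_steps=12,
            refractory_steps=2, seed=0,
        )
        raster = simulate_nodal_spikes(cfg, AdjacencyMatrix(np.zeros((1, 1)))).values
        assert np.array_equal(np.flatnonzero(raster[:, 0]), np.array([0, 3, 6, 9]))

    def test_whole_node_spikes_together_when_any_member_fired(self, small_nodal_data):
        # certainty propagation: at t, every non-refractory member of a node
        # with a spike at t-1 must spike — checked against a literal re-derivation
        raster = small_nodal_data["raster"].values
        cfg = small_nodal_data["config"]
        membership = nodal_membership(cfg)
        q = cfg.refractory_steps
        for node in range(cfg.n_nodes):
            block = raster[:, membership == node]
            for t in range(1, min(len(block), 200)):
                if block[t - 1].any():
                    refractory = (
                        block[max(0, t - q) : t].any(axis=0) if q else np.zeros(block.shape[1], bool)
                    )
                    assert np.all(block[t, ~refractory] == 1)

    def test_isolated_neuron_rate_matches_baseline(self):
        # no connectivity, no refractoriness: empirical rate -> r*k/N per second
        cfg = NodalConfig(
            n_neurons=100, n_nodes=5, rate=3.0, n_steps=6000, refractory_steps=0, seed=3
        )
        raster = simulate_nodal_spikes(cfg, AdjacencyMatrix(np.zeros((100, 100))))
        expected = cfg.rate * cfg.n_nodes / cfg.n_neurons  # spikes per second
        observed = raster.values.mean() / cfg.dt
        n_events = raster.values.sum()
        assert abs(observed - expected) / expected < 4 / np.sqrt(n_events)

    def test_refractory_interval_respected(self, small_nodal_data):
        raster = small_nodal_data["raster"].values
        q = small_nodal_data["config"].refractory_steps
        for n in range(raster.shape[1]):
            times = np.flatnonzero(raster[:, n])
            if len(times) > 1:
                assert np.diff(times).min() >= q + 1

    def test_fixed_seed_reproduces_raster(self, small_nodal_config):
        a = simulate_nodal(small_nodal_config)
        b = simulate_nodal(small_nodal_config)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(a[0].values, b[0].values)


# ---------------------------------------------------------------------------
# process weights and spiking
# ---------------------------------------------------------------------------


class TestProcessWeights:
    def test_bounds_and_strong_fraction(self):
        cfg = ProcessConfig(n_neurons=200, n_steps=1, seed=5)
        W = sample_process_weights(cfg).values
        assert W.shape == (5, 200)
        assert np.all((W >= 0) & (W <= 1))
        # at least the strong fraction of each row is >= 0.2
        assert np.all((W >= 0.2).mean(axis=1) >= cfg.strong_fraction)

    def test_degenerate_all_strong(self):
        cfg = ProcessConfig(n_neurons=50, n_steps=1, strong_fraction=1.0, seed=5)
        W = sample_process_weights(cfg).values
        assert np.all((W >= 0.2) & (W <= 1.0))

    def test_weak_weight_mean_matches_truncated_exponential(self):
        # closed-form oracle: E[X | X < c] = 1/lam - c*exp(-lam*c)/(1-exp(-lam*c))
        lam, cap = 8.0472, 0.2
        cfg = ProcessConfig(
            n_neurons=5000, n_processes=20, n_steps=1, strong_fraction=0.0, seed=11
        )
        W = sample_process_weights(cfg).values.ravel()
        expected = 1 / lam - cap * np.exp(-lam * cap) / (1 - np.exp(-lam * cap))
        assert np.all(W < cap)
        assert abs(W.mean() - expected) < 4 * W.std() / np.sqrt(W.size)

    def test_clip_mode_produces_cap_mass(self):
        cfg = ProcessConfig(
            n_neurons=2000, n_processes=5, n_steps=1, strong_fraction=0.0,
            weak_tail="clip", seed=11,
        )
        W = sample_process_weights(cfg).values
        # P(X > 0.2) = exp(-8.0472*0.2) ~ 0.2 of draws land exactly on the cap
        assert 0.1 < (W == 0.2).mean() < 0.3


class TestProcessSpiking:
    def test_zero_rate_all_silent(self):
        cfg = ProcessConfig(n_neurons=10, rate=0.0, n_steps=50, seed=1)
        W = sample_process_weights(cfg)
        raster, truth = simulate_process_spikes(cfg, W)
        assert raster.values.sum() == 0
        assert truth.process_raster.values.sum() == 0

    def test_unit_weight_neuron_follows_process_with_one_step_delay(self):
        cfg = ProcessConfig(
            n_neurons=1, n_processes=1, rate=3.0, n_steps=400,
            refractory_steps=0, seed=2,
        )
        W = AdjacencyMatrix(np.array([[1.0]]), orientation="process")
        raster, truth = simulate_process_spikes(cfg, W)
        proc = truth.process_raster.values[:, 0]
        assert np.array_equal(raster.values[1:, 0], proc[:-1])
        assert raster.values[0, 0] == 0

    def test_disjoint_processes_drive_their_own_neurons(self):
        # two processes firing on disjoint steps, identity-like weights:
        # each neuron reproduces its own process one step later
        cfg = ProcessConfig(
            n_neurons=2, n_processes=2, rate=3.0, n_steps=8, refractory_steps=0, seed=0
        )
        proc = np.array(
            [[1, 0], [0, 1], [1, 0], [0, 0], [0, 1], [1, 0], [0, 0], [1, 0]],
            dtype=np.uint8,
        )
        W = np.eye(2)
        # hand-stepped recursion: neuron n spikes at t iff its process spiked at t-1
        spikes = np.zeros((8, 2), dtype=np.uint8)
        spikes[1:] = proc[:-1]
        # run through the simulator by substituting the latent raster
        rng = np.random.default_rng(0)
        raster, truth = simulate_process_spikes(
            cfg, AdjacencyMatrix(W, orientation="process"), rng=rng
        )
        # oracle equivalence on the simulator's own latent raster
        expected = np.zeros_like(raster.values)
        expected[1:] = truth.process_raster.values[:-1]
        assert np.array_equal(raster.values, expected)

    def test_truth_carries_simulation_weights(self, small_process_data):
        truth = small_process_data["truth"]
        assert truth.kind == "process"
        assert truth.process_weights.shape == (5, 40)
        assert truth.process_raster.values.shape == (600, 5)

    def test_excessive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            ProcessConfig(rate=40.0, dt=1.0 / 30.0)


# ---------------------------------------------------------------------------
# calcium / fluorescence
# ---------------------------------------------------------------------------


class TestCalciumKernel:
    def test_silent_noiseless_trace_is_constant_baseline(self):
        raster = SpikeRaster(np.zeros((100, 3), dtype=np.uint8), dt=1 / 30)
        params = CalciumParams(dt=1 / 30, sigma_ca=0.0, sigma_f=0.0)
        traces = spikes_to_fluorescence(raster, params, seed=0)
        # fixed point: F = alpha*baseline + beta = 5*0.1 + 10 = 10.5
        assert np.allclose(traces.values, 10.5)

    def test_single_spike_matches_geometric_decay_closed_form(self):
        dt, tau = 1 / 30, 0.265
        t_star = 10
        spikes = np.zeros((200, 1), dtype=np.uint8)
        spikes[t_star, 0] = 1
        params = CalciumParams(dt=dt, sigma_ca=0.0, sigma_f=0.0)
        traces = spikes_to_fluorescence(SpikeRaster(spikes, dt=dt), params, seed=0)
        t = np.arange(200)
        ca = np.full(200, params.baseline)
        mask = t >= t_star
        ca[mask] += params.spike_amplitude * (1 - dt / tau) ** (t[mask] - t_star)
        expected = params.alpha * ca + params.beta
        rel = np.abs(traces.values[:, 0] - expected) / np.abs(expected)
        assert rel.max() < 1e-10

    def test_fluorescence_noise_statistics(self):
        raster = SpikeRaster(np.zeros((20000, 5), dtype=np.uint8), dt=1 / 30)
        params = CalciumParams(dt=1 / 30, sigma_ca=0.0, sigma_f=1.0)
        traces = spikes_to_fluorescence(raster, params, seed=4)
        assert abs(traces.values.mean() - 10.5) < 0.01
        assert abs(traces.values.var() - 1.0) < 0.05

    def test_unstable_time_step_rejected(self):
        raster = SpikeRaster(np.zeros((5, 1), dtype=np.uint8), dt=0.3)
        with pytest.raises(ValueError, match="tau"):
            spikes_to_fluorescence(raster, CalciumParams(dt=0.3), seed=0)

    def test_dt_mismatch_rejected(self):
        raster = SpikeRaster(np.zeros((5, 1), dtype=np.uint8), dt=0.01)
        with pytest.raises(ValueError, match="dt"):
            spikes_to_fluorescence(raster, CalciumParams(dt=1 / 30), seed=0)

    def test_sqrt_dt_mode_scales_noise(self):
        raster = SpikeRaster(np.zeros((5000, 2), dtype=np.uint8), dt=1 / 30)
        lit = CalciumParams(dt=1 / 30, sigma_f=0.0)
        sq = CalciumParams(dt=1 / 30, sigma_f=0.0, sqrt_dt_noise=True)
        v_lit = spikes_to_fluorescence(raster, lit, seed=9).values.var()
        v_sq = spikes_to_fluorescence(raster, sq, seed=9).values.var()
        assert v_sq > 10 * v_lit  # sqrt(dt)/dt = sqrt(30) per-step amplitude ratio

    def test_seeded_traces_bit_identical(self, small_nodal_data):
        raster = small_nodal_data["raster"]
        params = CalciumParams(dt=raster.dt)
        a = spikes_to_fluorescence(raster, params, seed=42)
        b = spikes_to_fluorescence(raster, params, seed=42)
        assert np.array_equal(a.values, b.values)


class TestTraceCorrelationStructure:
    def test_synchronized_node_event_gives_exactly_unit_correlation(self):
        # a synchronized node spike yields identical spike trains, and the
        # noise-free kernel maps identical trains to perfectly correlated traces
        cfg = NodalConfig(n_neurons=10, n_nodes=2, rate=0.0, n_steps=60, seed=0)
        A = build_nodal_adjacency(cfg)
        initial = np.zeros(10)
        initial[:5] = 1  # whole node 0 fires together at t=0
        raster = simulate_nodal_spikes(cfg, A, initial_spikes=initial)
        params = CalciumParams(dt=cfg.dt).noiseless()
        traces = spikes_to_fluorescence(raster, params, seed=0).values
        corr = np.corrcoef(traces[:, :5].T)
        assert np.allclose(corr, 1.0, atol=1e-12)

    def test_noisefree_blocks_nearly_perfectly_correlated(self):
        cfg = NodalConfig(n_steps=1500, seed=21)  # full 20-neuron nodes
        calcium = CalciumParams(dt=cfg.dt).noiseless()
        traces, _, truth = simulate_nodal(cfg, calcium)
        membership = truth.node_membership
        corr = np.corrcoef(traces.values.T)
        for node in range(5):
            idx = np.flatnonzero(membership == node)
            block = corr[np.ix_(idx, idx)]
            # event initiators fire one frame before the rest of their node, so
            # within-node correlation is near, not exactly, one
            assert block.min() > 0.95
        across = corr[np.ix_(membership == 0, membership == 1)]
        assert np.abs(across).max() < 0.3
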