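"""Integrate-and-fire dynamics: samplers, hand-traced updates, invariants."""

import numpy as np
import pytest

from codespectrum import (
    NeuronParams,
    SimulationConfig,
    Stimulus,
    SynapticWeights,
    build_topology,
    generate_weights,
    sample_instantaneous,
    sample_neuron_params,
    simulate,
)
from codespectrum.mesh import WeightConfig


def constant_weights(topology, value, overrides=None):
    """All edges at ``value`` except flat-index pairs in ``overrides``."""
    src, dst = topology.directed_pairs()
    values = np.full(len(src), float(value))
    for (i, j), w in (overrides or {}).items():
        mask = (src == i) & (dst == j)
        assert mask.sum() == 1
        values[mask] = w
    return SynapticWeights(topology=topology, values=values, source=src, target=dst)


class TestParamSamplers:
    def test_intrinsic_accepting_period_uniform_over_window(self, rng):
        cfg = SimulationConfig(a0=80)
        params = sample_neuron_params(cfg, 100_000, rng)
        values, counts = np.unique(params.a, return_counts=True)
        assert set(values) == {78, 79, 80, 81, 82}
        assert np.allclose(counts / counts.sum(), 0.2, atol=0.01)

    def test_basic_delay_uniform_over_2_to_8(self, rng):
        cfg = SimulationConfig()
        params = sample_neuron_params(cfg, 140_000, rng)
        values, counts = np.unique(params.d, return_counts=True)
        assert set(values) == set(range(2, 9))
        assert np.allclose(counts / counts.sum(), 1 / 7, atol=0.01)
        assert params.d.mean() == pytest.approx(5.0, abs=0.05)

    def test_a0_below_window_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(a0=2)

    def test_instantaneous_degenerate_at_p_zero(self, rng):
        assert sample_instantaneous(80, 0.0, rng) == 80

    def test_instantaneous_tail_probabilities(self, rng):
        draws = sample_instantaneous(np.full(100_000, 80), 1 / 12, rng)
        freqs = {v: np.mean(draws == v) for v in (79, 80, 81)}
        assert freqs[80] == pytest.approx(5 / 6, abs=0.01)
        assert freqs[79] == pytest.approx(1 / 12, abs=0.005)
        assert freqs[81] == pytest.approx(1 / 12, abs=0.005)
        assert set(np.unique(draws)) <= {79, 80, 81}

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sample_instantaneous(80, 0.6)


class TestSimulateHandTraces:
    """Tiny networks where the update rule can be traced by hand."""

    def setup_net(self, a_east=20, d_east=3):
        topo = build_topology(3, 3)
        center = topo.flat(1, 1)
        east = topo.flat(1, 2)
        weights = constant_weights(topo, -1.0, {(center, east): 1.0})
        a = np.full(9, 20)
        a[east] = a_east
        d = np.full(9, 3)
        d[east] = d_east
        params = NeuronParams(a=a, d=d)
        cfg = SimulationConfig(horizon=40, a0=20, p_a=0.0, p_d=0.0)
        return topo, center, east, weights, params, cfg

    def test_no_stimulus_gives_empty_raster(self):
        topo, _, _, weights, params, cfg = self.setup_net()
        raster = simulate(topo, weights, params, cfg, Stimulus.from_events([]))
        assert raster.n_spikes == 0

    def test_single_positive_path_fires_after_delay(self):
        # input at bin 0 -> fire decision at bin 0 -> emission at 0 + d_east
        topo, center, east, weights, params, cfg = self.setup_net(d_east=3)
        raster = simulate(topo, weights, params, cfg, Stimulus.from_events([(center, 0)]))
        east_bins = np.nonzero(raster.spikes[east])[0]
        assert list(east_bins) == [3]

    def test_second_input_during_refractory_is_absorbed(self):
        # stimulation at bins 0 and 1; east is refractory until bin 20, and
        # by its first post-refractory decision the bin-1 input has left the
        # accepting window: exactly one emission before bin 21
        topo, center, east, weights, params, cfg = self.setup_net(a_east=20)
        stim = Stimulus.from_events([(center, 0), (center, 1)])
        raster = simulate(topo, weights, params, cfg, stim)
        east_bins = np.nonzero(raster.spikes[east])[0]
        assert np.count_nonzero(east_bins < 21) == 1

    def test_mismatched_params_rejected(self):
        topo, _, _, weights, _, cfg = self.setup_net()
        bad = NeuronParams(a=np.full(4, 20), d=np.full(4, 3))
        with pytest.raises(ValueError):
            simulate(topo, weights, bad, cfg, Stimulus.from_events([]))

    def test_stimulus_outside_horizon_rejected(self):
        topo, center, _, weights, params, cfg = self.setup_net()
        with pytest.raises(ValueError):
            simulate(topo, weights, params, cfg, Stimulus.from_events([(center, 99)]))


class TestSimulatorInvariants:
    def run_default(self, seed=5, c=0.3, horizon=400, a0=30):
        topo = build_topology(9, 9)
        weights = generate_weights(topo, WeightConfig(c=c, seed=seed))
        cfg = SimulationConfig(horizon=horizon, a0=a0)
        rng = np.random.default_rng(seed)
        params = sample_neuron_params(cfg, topo.n_neurons, rng)
        stim = Stimulus.triple_at(topo, (4, 4), bin=2)
        raster = simulate(topo, weights, params, cfg, stim, rng)
        return topo, params, stim, raster

    def test_quiescence_with_nonpositive_weights(self):
        topo = build_topology(5, 5)
        weights = constant_weights(topo, -0.5)
        cfg = SimulationConfig(horizon=200, a0=10)
        params = sample_neuron_params(cfg, topo.n_neurons, np.random.default_rng(0))
        stim = Stimulus.triple_at(topo, (2, 2), bin=0)
        raster = simulate(topo, weights, params, cfg, stim)
        spiking = set(np.nonzero(raster.spikes.any(axis=1))[0])
        assert spiking == set(stim.neurons.tolist())

    def test_causality_no_spike_before_stimulus(self):
        _, _, stim, raster = self.run_default()
        first = np.nonzero(raster.spikes.any(axis=0))[0]
        assert len(first) > 0 and first[0] >= stim.bins.min()

    def test_refractory_minimum_interspike_interval(self):
        # with p_a = p_d = 0 the emission intervals equal the decision
        # intervals, which must exceed the neuron's accepting period
        topo = build_topology(9, 9)
        weights = generate_weights(topo, WeightConfig(c=0.3, seed=3))
        cfg = SimulationConfig(horizon=600, a0=15, p_a=0.0, p_d=0.0)
        params = sample_neuron_params(cfg, topo.n_neurons, np.random.default_rng(1))
        stim = Stimulus.triple_at(topo, (4, 4), bin=0)
        raster = simulate(topo, weights, params, cfg, stim, np.random.default_rng(2))
        assert raster.n_spikes > 50  # activity actually sustained
        stim_set = set(stim.neurons.tolist())
        for n in range(topo.n_neurons):
            if n in stim_set:
                continue
            bins = np.nonzero(raster.spikes[n])[0]
            if len(bins) > 1:
                assert np.diff(bins).min() >= params.a[n]

    def test_seed_determinism_bit_identical(self):
        _, _, _, r1 = self.run_default(seed=9)
        _, _, _, r2 = self.run_default(seed=9)
        assert np.array_equal(r1.spikes, r2.spikes)

    def test_different_seeds_differ(self):
        _, _, _, r1 = self.run_default(seed=9)
        _, _, _, r2 = self.run_default(seed=10)
        assert not np.array_equal(r1.spikes, r2.spikes)
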