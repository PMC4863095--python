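"""Leak-free integrate-and-fire dynamics with fluctuating timing parameters.

Time is discretised into 0.1 ms bins.  Neuron ``n`` accumulates the weighted
input spikes it received during its current accepting period ``A_nk`` (an
integer number of bins).  At every bin at which it is not refractory, if the
accumulated sum is strictly positive it "fires": an output spike is scheduled
``D_nk`` bins later, the input record is cleared, the neuron becomes
refractory for ``A_nk`` bins, and both timing parameters are re-sampled for
the next firing event.

Two levels of randomness shape the timing:

* intrinsic: each neuron owns a basic accepting period ``a_n`` drawn
  uniformly from {a0-2, ..., a0+2} and a basic output delay ``d_n`` drawn
  uniformly from {2, ..., 8} (bins);
* instantaneous: at each firing event k the realised ``A_nk`` is
  ``a_n + delta`` with delta in {-1, 0, +1} at probabilities
  {p_a, 1 - 2 p_a, p_a}, and likewise ``D_nk`` around ``d_n`` with ``p_d``.

There is no leak: old input is forgotten abruptly, either by the clearing on
firing or by falling out of the sliding accepting window.  All synaptic
transmission is instantaneous; latency lives entirely in the output delay.

Stimulation bypasses integration: a stimulated neuron simply emits a spike
at the stated bin.  It does not reset the neuron's own integration or
refractory state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshTopology, SynapticWeights

__all__ = [
    "REFRACTORY_OFFSET",
    "SimulationConfig",
    "NeuronParams",
    "Stimulus",
    "SpikeRaster",
    "sample_neuron_params",
    "sample_instantaneous",
    "simulate",
]

#: Refractory period = A_nk + REFRACTORY_OFFSET bins, starting at the
#: fire-decision bin.  The next fire decision happens at the first bin
#: strictly after the refractory period ends.  Zero offset treats the
#: refractory and accepting periods as equal.
REFRACTORY_OFFSET: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings; all durations in 0.1 ms bins.

    Parameters
    ----------
    horizon : simulated duration in bins (2000 bins = 200 ms).
    a0 : basic accepting period common to the network, in bins.  The
        inverse-fitting grid uses 55-100 bins (5.5-10 ms).
    p_a, p_d : per-firing fluctuation probabilities of the instantaneous
        accepting period and output delay (each tail gets p, the centre
        1 - 2p).
    seed : root seed for neuron parameters and per-firing fluctuations.
    """

    horizon: int = 2000
    a0: int = 80
    p_a: float = 1.0 / 12.0
    p_d: float = 1.0 / 12.0
    seed: int = 0
    bin_width_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 bin")
        if self.a0 < 3:
            raise ValueError("a0 must be >= 3 bins (the +/-2 intrinsic window)")
        if not (0.0 <= self.p_a <= 0.5 and 0.0 <= self.p_d <= 0.5):
            raise ValueError("fluctuation probabilities must lie in [0, 0.5]")


@dataclass
class NeuronParams:
    """Per-neuron basic accepting periods ``a`` and output delays ``d`` (bins)."""

    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        if self.a.shape != self.d.shape:
            raise ValueError("a and d must have identical shape")
        if np.any(self.a < 1):
            raise ValueError("accepting periods must be >= 1 bin")
        if np.any((self.d < 2) | (self.d > 8)):
            raise ValueError("basic delays must lie in {2, ..., 8} bins")

    @property
    def n_neurons(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class Stimulus:
    """Spatiotemporal stimulation: (neuron flat index, bin) emission events.

    Bins are 0-based here; bin 0 is the first 0.1 ms of the run.
    """

    neurons: np.ndarray
    bins: np.ndarray

    def __post_init__(self) -> None:
        if self.neurons.shape != self.bins.shape:
            raise ValueError("neurons and bins must have identical shape")
        if np.any(self.bins < 0):
            raise ValueError("stimulus bins must be >= 0")

    @classmethod
    def from_events(cls, events: list[tuple[int, int]]) -> "Stimulus":
        """Build from a list of (neuron flat index, bin) pairs."""
        if events:
            neurons, bins = map(np.asarray, zip(*events))
        else:
            neurons = bins = np.empty(0, dtype=np.int64)
        return cls(neurons=neurons.astype(np.int64), bins=bins.astype(np.int64))

    @classmethod
    def triple_at(
        cls, topology: MeshTopology, center: tuple[int, int], bin: int = 0
    ) -> "Stimulus":
        """Simultaneously stimulate the three neurons nearest a mesh point.

        Mimics electrical stimulation through an electrode, which excites a
        small group rather than a single cell: the centre neuron plus its two
        nearest neighbours (clockwise tie-break).
        """
        row, col = center
        picks = [(row, col)]
        for r, c in topology.neighbors(row, col):
            if len(picks) >= 3:
                break
            # prefer the 4-connected (distance-1) neighbours
            if abs(r - row) + abs(c - col) == 1:
                picks.append((r, c))
        for r, c in topology.neighbors(row, col):
            if len(picks) >= 3:
                break
            if (r, c) not in picks:
                picks.append((r, c))
        return cls.from_events([(int(topology.flat(r, c)), bin) for r, c in picks])


@dataclass
class SpikeRaster:
    """Binary neurons x bins record of emitted spikes."""

    spikes: np.ndarray  # bool (n_neurons, horizon)
    topology: MeshTopology

    def __post_init__(self) -> None:
        if self.spikes.shape[0] != self.topology.n_neurons:
            raise ValueError("raster rows must equal neuron count")

    @property
    def horizon(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.sum())

    def events(self) -> tuple[np.ndarray, np.ndarray]:
        """(neuron flat index, bin) arrays of all emissions, bin-major order."""
        neuron, t = np.nonzero(self.spikes)
        order = np.lexsort((neuron, t))
        return neuron[order], t[order]


def sample_neuron_params(
    config: SimulationConfig, n_neurons: int, rng: np.random.Generator | None = None
) -> NeuronParams:
    """Draw intrinsic parameters: a uniform on {a0-2..a0+2}, d uniform on {2..8}."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a = config.a0 + rng.integers(-2, 3, size=n_neurons)
    d = rng.integers(2, 9, size=n_neurons)
    return NeuronParams(a=a, d=d)


def sample_instantaneous(base, p: float, rng: np.random.Generator | None = None):
    """base - 1 / base / base + 1 with probabilities p / 1 - 2p / p (vectorised)."""
    if not (0.0 <= p <= 0.5):
        raise ValueError("p must lie in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng()
    base = np.asarray(base)
    u = rng.random(base.shape)
    delta = np.where(u < p, -1, 0) + np.where(u >= 1.0 - p, 1, 0)
    out = base + delta
    return int(out) if out.ndim == 0 else out


def simulate(
    topology: MeshTopology,
    weights: SynapticWeights,
    params: NeuronParams,
    config: SimulationConfig,
    stimulus: Stimulus,
    rng: np.random.Generator | None = None,
) -> SpikeRaster:
    """Run the network for ``config.horizon`` bins and return the spike raster.

    Per-bin update, in order:

    1. emissions at bin t = previously scheduled outputs plus stimulus events
       (output delays are >= 1 bin, so emissions never depend on decisions
       made in the same bin);
    2. each emission is instantly visible to the emitter's neighbours as
       weighted input at bin t;
    3. every neuron whose refractory period has ended evaluates the sum of
       weighted input over its accepting window (t - A_nk, t], excluding
       anything cleared at its previous firing; a strictly positive sum
       triggers a firing event as described in the module docstring.

    Deterministic given (config, seed/rng); the per-firing fluctuation draws
    are consumed in neuron-index order within each bin.
    """
    n = topology.n_neurons
    if params.n_neurons != n:
        raise ValueError("params length must equal neuron count")
    T = config.horizon
    if len(stimulus.bins) and np.any(stimulus.bins >= T):
        raise ValueError("stimulus bins must lie within the horizon")
    if len(stimulus.neurons) and np.any(
        (stimulus.neurons < 0) | (stimulus.neurons >= n)
    ):
        raise ValueError("stimulus neuron indices out of range")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    W = weights.input_matrix()

    # stimulus lookup: list of neuron arrays per bin
    stim_at: dict[int, np.ndarray] = {}
    for b in np.unique(stimulus.bins):
        stim_at[int(b)] = stimulus.neurons[stimulus.bins == b]

    spikes = np.zeros((n, T), dtype=bool)

    # instantaneous parameters for each neuron's *next* firing event
    A = sample_instantaneous(params.a, config.p_a, rng)
    D = sample_instantaneous(params.d, config.p_d, rng)

    refractory_until = np.full(n, -1, dtype=np.int64)  # decisions allowed at t > this
    # cumulative weighted input: cum[k] = summed input over bins 0..k-1
    cum = np.zeros((T + 1, n), dtype=np.float64)
    cleared = np.zeros(n, dtype=np.int64)  # cum-index below which input is cleared

    ring = 16  # > max possible D (d_n <= 8, +1 fluctuation)
    scheduled = np.zeros((ring, n), dtype=bool)

    idx = np.arange(n)
    for t in range(T):
        # 1. emissions
        emit = scheduled[t % ring].copy()
        scheduled[t % ring] = False
        stim = stim_at.get(t)
        if stim is not None:
            emit[stim] = True
        spikes[:, t] = emit

        # 2. propagate: weighted input received this bin
        if emit.any():
            x = W @ emit.astype(np.float64)
            cum[t + 1] = cum[t] + x
        else:
            cum[t + 1] = cum[t]

        # 3. fire decisions
        eligible = t > refractory_until
        if not eligible.any():
            continue
        lower = np.maximum(t + 1 - A, cleared)
        np.maximum(lower, 0, out=lower)
        acc = cum[t + 1, idx] - cum[lower, idx]
        fire = eligible & (acc > 0.0)
        if fire.any():
            f = idx[fire]
            scheduled[(t + D[f]) % ring, f] = True
            refractory_until[f] = t + A[f] + REFRACTORY_OFFSET
            cleared[f] = t + 1
            A[f] = sample_instantaneous(params.a[f], config.p_a, rng)
            D[f] = sample_instantaneous(params.d[f], config.p_d, rng)

    return SpikeRaster(spikes=spikes, topology=topology)
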