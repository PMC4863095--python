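"""Component-spectrum library, mixture fitting and the (a0, c) grid search.

An electrode pooling exactly ``m`` neurons produces a characteristic code
spectrum E_m whose shape depends on the network parameters: the basic
accepting period a0 and the weight-balance parameter c.  Simulating the
network over a grid of (a0, c) and for each capture class m = 2..9 (or up
to 16 in the expanded layout) yields a *component library*.

An observed spectrum — pooled over electrodes whose capture sizes vary —
is modelled as a convex mixture of the components at one grid cell,

    S(code) ~= sum_m q_m E_m(code),   q_m >= 0,  sum q_m = 1,

where q is the probability distribution of the number of neurons per
electrode.  Component spectra and targets are normalised to unit sum before
mixing, since a probability mixture is well defined only on shapes (raw
totals differ strongly across m).  Goodness of fit is the normalised RMS
error between unit-sum spectra; the grid search returns the full error
surface plus the best and second-best cells, inversely estimating (a0, c)
and q from a recording.

Cells whose simulations yield too few detections (activity dies out, e.g.
strong inhibition at long accepting periods) are marked missing and
excluded, mirroring the gaps seen in practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import codes
from ._rng import substream
from .electrodes import build_layout, pool_spikes
from .mesh import MeshTopology, WeightConfig, build_topology, generate_weights
from .neurons import SimulationConfig, Stimulus, sample_neuron_params, simulate

__all__ = [
    "PAPER_A0_GRID_MS",
    "PAPER_C_GRID",
    "MISSING_THRESHOLD",
    "ComponentLibrary",
    "FitResult",
    "ms_to_bins",
    "build_component_library",
    "mix_spectrum",
    "normalized_rms",
    "fit_mixture",
    "fit_mixture_grid_oracle",
    "grid_fit",
    "synthesize_target",
]

#: The (a0, c) grid used for the inverse estimation (a0 in ms).
PAPER_A0_GRID_MS: tuple[float, ...] = (5.5, 6.0, 7.0, 8.0, 9.0, 10.0)
PAPER_C_GRID: tuple[float, ...] = (0.1, 0.3, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Cells with fewer total detections than this (summed over m classes and
#: trials) are marked missing: too little activity to estimate a shape.
MISSING_THRESHOLD: int = 50

_STIM_ELECTRODE: int = 0  # flat index of the stimulating electrode, grid (0, 0)


def ms_to_bins(ms: float, bin_width_ms: float = 0.1) -> int:
    """Convert a duration in ms to an integer number of bins."""
    bins = round(ms / bin_width_ms)
    if abs(bins * bin_width_ms - ms) > 1e-9:
        raise ValueError(f"{ms} ms is not a whole number of {bin_width_ms} ms bins")
    return int(bins)


@dataclass
class ComponentLibrary:
    """E_m spectra over the (a0, c) grid; a0 keys in bins.

    ``spectra[(a0, c)]`` is a (21, n_m) array of trial-averaged counts with
    columns aligned to ``m_values``; ``totals`` holds the raw detection
    total of each cell (all m classes and trials summed).
    """

    a0_grid: tuple[int, ...]
    c_grid: tuple[float, ...]
    m_values: tuple[int, ...]
    n_trials: int
    seed: int
    spectra: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    missing_threshold: int = MISSING_THRESHOLD

    def cells(self) -> list[tuple[int, float]]:
        return [(a0, c) for a0 in self.a0_grid for c in self.c_grid]

    def is_missing(self, cell: tuple[int, float]) -> bool:
        return cell not in self.spectra or self.totals.get(cell, 0) < self.missing_threshold

    def non_missing_cells(self) -> list[tuple[int, float]]:
        return [cell for cell in self.cells() if not self.is_missing(cell)]


@dataclass
class FitResult:
    """Outcome of the grid search: best cell, mixture and error surface."""

    best_cell: tuple[int, float]
    weights: np.ndarray  # q over m_values at the best cell
    error: float
    error_grid: dict  # (a0, c) -> normalised RMS; missing cells absent
    second_cell: tuple[int, float] | None
    m_values: tuple[int, ...]
    cell_weights: dict = field(default_factory=dict)  # (a0, c) -> q


def _default_stimulus(topology: MeshTopology, layout_center) -> Stimulus:
    return Stimulus.triple_at(topology, tuple(layout_center), bin=0)


def _simulate_cell(
    topology: MeshTopology,
    a0_bins: int,
    c: float,
    seed: int,
    trial: int,
    horizon: int,
    p_a: float,
    p_d: float,
):
    """One simulation run of a grid cell: returns the spike raster and the
    stimulating electrode's centre (stimulation targets electrode (1,1))."""
    weights = generate_weights(
        topology,
        WeightConfig(c=c, seed=int(substream(seed, "weights", a0_bins, c, trial).integers(2**31))),
    )
    config = SimulationConfig(horizon=horizon, a0=a0_bins, p_a=p_a, p_d=p_d)
    params = sample_neuron_params(
        config, topology.n_neurons, substream(seed, "params", a0_bins, c, trial)
    )
    probe = build_layout(topology, m_spec=9, seed=0)  # centres only
    stim_center = probe.centers[_STIM_ELECTRODE]
    stimulus = _default_stimulus(topology, stim_center)
    raster = simulate(
        topology,
        weights,
        params,
        config,
        stimulus,
        substream(seed, "sim", a0_bins, c, trial),
    )
    return raster


def build_component_library(
    a0_grid=None,
    c_grid=PAPER_C_GRID,
    m_values=tuple(range(2, 10)),
    n_trials: int = 3,
    seed: int = 0,
    horizon: int = 2000,
    p_a: float = 1.0 / 12.0,
    p_d: float = 1.0 / 12.0,
    widths=codes.DEFAULT_WIDTHS,
    expanded: bool = False,
    topology: MeshTopology | None = None,
) -> ComponentLibrary:
    """Simulate the grid and decode per-capture-class component spectra.

    For each (a0, c) cell and trial, one network realisation is simulated
    (fresh weights and neuron parameters from named substreams) and its
    raster is pooled through one fixed-m layout per capture class; the 63
    non-stimulating electrodes are decoded and spectra averaged over trials.
    a0 grids may be given in bins (ints) or ms (floats).
    """
    if a0_grid is None:
        a0_grid = PAPER_A0_GRID_MS
    a0_bins_grid = tuple(
        int(a0) if float(a0).is_integer() and a0 >= 20 else ms_to_bins(float(a0))
        for a0 in a0_grid
    )
    if topology is None:
        topology = build_topology()
    lib = ComponentLibrary(
        a0_grid=a0_bins_grid,
        c_grid=tuple(c_grid),
        m_values=tuple(m_values),
        n_trials=n_trials,
        seed=seed,
    )
    for a0 in a0_bins_grid:
        for c in lib.c_grid:
            acc = np.zeros((codes.N_CODES, len(lib.m_values)))
            total = 0.0
            for trial in range(n_trials):
                raster = _simulate_cell(
                    topology, a0, c, seed, trial, horizon, p_a, p_d
                )
                for mi, m in enumerate(lib.m_values):
                    layout = build_layout(
                        topology,
                        m_spec=int(m),
                        expanded=expanded or m > 9,
                        rng=substream(seed, "layout", a0, c, trial, m),
                    )
                    trains = pool_spikes(raster, layout)
                    spec = codes.spectrum_from_trains(
                        trains, widths=widths, window=horizon, exclude=_STIM_ELECTRODE
                    )
                    acc[:, mi] += spec.counts
                    total += spec.total
            lib.spectra[(a0, c)] = acc / n_trials
            lib.totals[(a0, c)] = total
    return lib


def _unit_sum(x: np.ndarray) -> np.ndarray:
    s = x.sum()
    return x / s if s > 0 else x


def mix_spectrum(q: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Convex mixture sum_m q_m E_m of unit-sum-normalised component columns.

    ``components`` is (21, n_m); all-zero columns contribute nothing (their
    q must be 0).
    """
    q = np.asarray(q, dtype=float)
    components = np.asarray(components, dtype=float)
    if components.shape[0] != codes.N_CODES or components.shape[1] != q.size:
        raise ValueError("components must be (21, len(q))")
    if np.any(q < -1e-9) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("q must lie on the probability simplex")
    zero = components.sum(axis=0) == 0
    if np.any(zero & (q > 1e-9)):
        raise ValueError("nonzero q assigned to an all-zero component")
    norm = components.copy()
    norm[:, ~zero] = norm[:, ~zero] / norm[:, ~zero].sum(axis=0)
    return norm @ q


def normalized_rms(sim: np.ndarray, target: np.ndarray) -> float:
    """RMS distance between unit-sum spectra, normalised by the target's RMS.

    Both inputs are scaled to unit sum first, so the statistic is invariant
    to overall detection counts and zero iff the shapes coincide.
    """
    sim = np.asarray(sim, dtype=float)
    target = np.asarray(target, dtype=float)
    if sim.shape != target.shape:
        raise ValueError("spectra must have equal length")
    if target.sum() <= 0:
        raise ValueError("target spectrum must not be all-zero")
    s = _unit_sum(sim)
    t = _unit_sum(target)
    return float(np.sqrt(np.mean((s - t) ** 2)) / np.sqrt(np.mean(t**2)))


def _components_norm(components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    components = np.asarray(components, dtype=float)
    usable = components.sum(axis=0) > 0
    norm = components.copy()
    norm[:, usable] = norm[:, usable] / norm[:, usable].sum(axis=0)
    return norm, usable


def fit_mixture(target: np.ndarray, components: np.ndarray) -> tuple[np.ndarray, float]:
    """Best simplex mixture of the components for a target spectrum.

    Non-negative least squares on unit-sum shapes, renormalised onto the
    simplex, then polished by coordinate-pair mass transfers (step 0.01)
    until no move improves the normalised RMS.  Deterministic.  When every
    usable component has the same shape, the fit is degenerate and the
    uniform mixture is returned.
    """
    target = np.asarray(target, dtype=float)
    if target.sum() <= 0:
        raise ValueError("target spectrum must not be all-zero")
    norm, usable = _components_norm(components)
    k = norm.shape[1]
    if not usable.any():
        raise ValueError("no usable (nonzero) component present")
    t = _unit_sum(target)
    A = norm[:, usable]

    if np.allclose(A, A[:, :1], atol=1e-12):  # degenerate: identical shapes
        q = np.zeros(k)
        q[usable] = 1.0 / usable.sum()
        return q, normalized_rms(mix_spectrum(q, components), target)

    qa, _ = scipy.optimize.nnls(A, t)
    if qa.sum() <= 0:
        qa = np.ones(A.shape[1])
    qa = qa / qa.sum()

    def err(qv: np.ndarray) -> float:
        return float(np.sqrt(np.mean((A @ qv - t) ** 2)) / np.sqrt(np.mean(t**2)))

    best = err(qa)
    step = 0.01
    improved = True
    while improved:
        improved = False
        for i, j in itertools.permutations(range(A.shape[1]), 2):
            if qa[i] < step - 1e-12:
                continue
            trial = qa.copy()
            trial[i] -= step
            trial[j] += step
            e = err(trial)
            if e < best - 1e-12:
                qa, best = trial, e
                improved = True
    q = np.zeros(k)
    q[usable] = qa
    return q, best


def fit_mixture_grid_oracle(
    target: np.ndarray, components: np.ndarray, step: float = 0.1
) -> tuple[np.ndarray, float]:
    """Exhaustive simplex search at the given step; verification oracle.

    Enumerates every composition of 1/step units over the components
    (feasible for <= 8 components at step 0.1).
    """
    target = np.asarray(target, dtype=float)
    norm, usable = _components_norm(components)
    k = norm.shape[1]
    n_units = round(1.0 / step)
    idx = np.flatnonzero(usable)
    best_q, best_e = None, np.inf
    for combo in itertools.combinations_with_replacement(idx, n_units):
        q = np.zeros(k)
        for i in combo:
            q[i] += step
        e = normalized_rms(mix_spectrum(q, components), target)
        if e < best_e:
            best_q, best_e = q, e
    return best_q, best_e


def grid_fit(target: np.ndarray, library: ComponentLibrary) -> FitResult:
    """Fit the target at every non-missing grid cell and rank the cells."""
    cells = library.non_missing_cells()
    if not cells:
        raise ValueError("library has no non-missing cells")
    errors: dict = {}
    cell_weights: dict = {}
    for cell in cells:
        q, e = fit_mixture(target, library.spectra[cell])
        errors[cell] = e
        cell_weights[cell] = q
    ranked = sorted(errors, key=errors.get)
    best = ranked[0]
    second = ranked[1] if len(ranked) > 1 else None
    return FitResult(
        best_cell=best,
        weights=cell_weights[best],
        error=errors[best],
        error_grid=errors,
        second_cell=second,
        m_values=library.m_values,
        cell_weights=cell_weights,
    )


def synthesize_target(
    a0,
    c: float,
    q: dict | np.ndarray,
    n_trials: int = 9,
    seed: int = 0,
    horizon: int = 2000,
    p_a: float = 1.0 / 12.0,
    p_d: float = 1.0 / 12.0,
    widths=codes.DEFAULT_WIDTHS,
    m_values=tuple(range(2, 10)),
    topology: MeshTopology | None = None,
) -> np.ndarray:
    """Synthetic observed spectrum at known parameters (wet-recording stand-in).

    Simulates ``n_trials`` fresh network realisations; each trial pools the
    raster through one 8x8 layout whose per-electrode capture sizes are
    drawn from the distribution ``q``, decodes the 63 non-stimulating
    electrodes and the trials are averaged.  a0 accepts bins (int >= 20) or
    ms (float).
    """
    a0_bins = int(a0) if float(a0).is_integer() and a0 >= 20 else ms_to_bins(float(a0))
    if topology is None:
        topology = build_topology()
    if not isinstance(q, dict):
        q = {m: float(w) for m, w in zip(m_values, np.asarray(q, dtype=float))}
    acc = np.zeros(codes.N_CODES)
    for trial in range(n_trials):
        raster = _simulate_cell(
            topology, a0_bins, c, seed, ("target", trial), horizon, p_a, p_d
        )
        layout = build_layout(
            topology,
            m_spec=q,
            expanded=max(q) > 9,
            rng=substream(seed, "target-layout", a0_bins, c, trial),
        )
        trains = pool_spikes(raster, layout)
        spec = codes.spectrum_from_trains(
            trains, widths=widths, window=horizon, exclude=_STIM_ELECTRODE
        )
        acc += spec.counts
    return acc / n_trials
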