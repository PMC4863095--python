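# Methods

## Model overview

The package simulates spike propagation on a 33 × 33 mesh of leak-free
integrate-and-fire neurons, records it through a virtual 8 × 8
multielectrode array without spike sorting, counts the 21 canonical
three-one codes in the pooled trains, and uses the resulting code spectra
in two ways: as a fitting target for inverse estimation of the network
parameters, and as the raw material for a code-flow cross-correlation
statistic. All randomness flows from one root seed through named
substreams (`weights`, `params`, `layout`, `sim`, per-trial keys), so any
stage can be replayed in isolation and every pipeline run is bit-for-bit
reproducible.

## Network and weights

Neurons occupy a rectangular lattice with 8-neighbour (Chebyshev
distance 1) connectivity, no wraparound and nothing outside the lattice:
interior/edge/corner neurons have 8/5/3 neighbours. Every ordered
neighbour pair (i, j) carries an independent weight
`w_ij = F[(1+c)u − c]` with `u ~ U[0, 1)` and `F` the truncation to
[−1, 1], so `P(w > 0) = 1/(1+c)` and the positive-to-negative count ratio
is `1/c` (3:1 at c = 1/3, 1:1 at c = 1, 1:3 at c = 3). Exact zeros (a
measure-zero event) are stored as drawn, not re-drawn. Weights are
enumerated in a canonical order — row-major over the source neuron, then
clockwise from north over its neighbours — which fixes the RNG consumption
order and makes weight maps reproducible from the seed alone.

## Neuron dynamics

Time is discretised into 0.1 ms bins. Each neuron owns intrinsic
parameters drawn once per network: basic accepting period `a_n` uniform on
{a0−2 … a0+2} bins and basic output delay `d_n` uniform on {2 … 8} bins.
At each firing event the instantaneous values fluctuate by ±1 bin with
tail probability `p_a = p_d = 1/12` (centre probability 5/6).

Per-bin update order:

1. spikes scheduled earlier, plus stimulus events, are emitted (delays are
   ≥ 1 bin, so emissions never depend on same-bin decisions);
2. emissions are instantly visible to neighbours as weighted input (zero
   synaptic transmission delay — all latency lives in `D_nk`);
3. every neuron past its refractory period evaluates the summed weighted
   input over the sliding window `(t − A_nk, t]`, excluding anything
   cleared at its previous firing; a strictly positive sum triggers a
   firing: an output spike is scheduled at `t + D_nk`, the input record is
   cleared, the neuron is refractory until `t + A_nk`, and `A`, `D` are
   re-sampled for the next event.

Design choices where the model description is genuinely open, each held as
a named constant or documented convention:

- refractory period exactly equal to `A_nk` (`REFRACTORY_OFFSET = 0`),
  with the next decision at the first bin *strictly after* it ends;
- the input record is cleared on firing; inputs older than the accepting
  window are forgotten abruptly (no leak) — inputs arriving *during* the
  refractory period are retained as long as they remain inside the window
  at the first post-refractory decision;
- stimulation bypasses integration and delay: the stimulated neuron simply
  emits at the stated bin, and its own integration state is untouched;
- the default stimulus excites the three neurons nearest an electrode
  centre simultaneously (the centre plus its two nearest lattice
  neighbours), mimicking electrical stimulation through one electrode,
  which excites a small group and promotes stable wave propagation.

`a0` values are accepted in bins (integers ≥ 20) or in ms (e.g. 7.0);
the canonical fitting grid is 5.5–10 ms = 55–100 bins.

## Electrode array and pooling

Electrode centres sit on a regular 8 × 8 subgrid with pitch 4 (0-based
mesh rows/cols 2, 6, …, 30). Each electrode captures `m` member neurons
sampled without replacement from the 3 × 3 block around its centre (4 × 4
in the expanded layout, m ≤ 16); blocks of distinct electrodes are
disjoint at this pitch. The distribution of `m` across electrodes is a
configuration knob (`m_spec`): fixed, uniform on {2 … 9} (default), or an
explicit distribution — the latter is how mixture targets are synthesised.
Pooling is unsorted multiunit recording: the electrode train is the
bitwise OR of its members' raster rows. The stimulating electrode is
excluded from spectrum aggregation (63 of 64 electrodes analysed).

## Code detection

A code is a binary pattern of length 3–8 with exactly three 1s, starting
and ending with 1; there are L − 2 of length L, 21 in total, ordered by
(length, binary value). Detection samples a train at integer bit widths
6–20 bins (0.6–2.0 ms): pattern p matches at start bin t and width w iff
bin `t + k·w` holds a spike exactly where `p[k] = 1`. Conventions, chosen
explicitly and mirrored by the brute-force oracle used in tests:

- zero bits constrain only the sampled bins, not the whole gap (the code
  is a sampled sequence; chance-overlap false codes are inherent to the
  method);
- matches at different widths or shifted starts all count, may overlap,
  and are not subsumption-suppressed;
- bit positions land exactly on bins (integer widths), so no timing
  tolerance is needed; an optional ±δ-bin tolerance on 1-bits exists and
  defaults to 0.

The spectrum is the 21-vector of match counts aggregated over electrodes,
start bins and widths within the analysis window (default: the first 2000
bins = 200 ms after stimulation), optionally averaged over trials.

## Spectrum fitting

Component spectra `E_m(a0, c)` are built by simulating each grid cell
`n_trials` times with fresh weights and neuron parameters, pooling each
raster through one fixed-m layout per capture class, decoding the 63
non-stimulating electrodes, and averaging. Cells with fewer than 50 total
detections are marked *missing*: their activity died out before producing
enough codes to define a shape (this happens at strongly inhibitory
weights and long accepting periods).

An observed spectrum is modelled as a convex mixture `Σ_m q_m E_m` at one
grid cell. Components and targets are normalised to unit sum before
mixing and scoring, because a probability mixture over m is well defined
only on shapes — raw totals differ by orders of magnitude across m. The
goodness of fit is the normalized RMS error
`sqrt(mean((s − t)²)) / sqrt(mean(t²))` on unit-sum vectors; it is
scale-invariant in both arguments and zero iff the shapes coincide.

The simplex optimisation runs non-negative least squares on the normalised
components, renormalises onto the simplex (harmless, since the error is
scale-invariant in the mixture), then polishes by coordinate-pair mass
transfers of 0.01 until no move improves the error. Degenerate case: if
all usable components have identical shape the error is q-independent and
the uniform mixture is returned. An exhaustive simplex grid search (step
0.1) is provided as an independent verification oracle. `grid_fit` fits
every non-missing cell and reports the full error surface plus best and
second-best cells.

### Synthetic targets and parameter recovery

The wet recordings that motivated this pipeline are not distributed with
it; `synthesize_target` stands in for them. It simulates fresh network
realisations at known `(a0, c)`, pools each through a layout whose
per-electrode capture sizes are drawn from a known distribution q, and
averages 9 trials (the trial count used for real recordings). Parameter
recovery — synthesise at known parameters, then `grid_fit` against an
independently-seeded library — is the package's acceptance surface for
the fitting stage: the generating cell must rank best or second-best in
at least 80% of 20 replicates.

The recovery experiment runs at a0 ∈ {5.5, 7.0, 9.0} ms ×
c ∈ {0.3, 1.0, 2.0} with a library of 3 trials per cell and the true cell
at (7.0 ms, 1.0), q uniform on {2 … 9}. This reduced grid keeps the
experiment at roughly one minute while the cells remain clearly
distinguishable; the true cell sits in the regime where this
implementation sustains rich activity. In this implementation, activity
(and hence detection count) decreases monotonically in both c and a0:
cells with strong inhibition and long accepting periods go missing. Under
the modelling choices above, inputs arriving during the refractory period
can re-ignite a neuron right after it, which sustains reverberation in
excitation-dominant networks; model variants that drop those inputs shift
the boundary between sustained and dying activity across the (a0, c)
plane. The mixture weights q are only weakly identified — components for
large m have very similar shapes (the expanded classes E_9–E_16 are
similar enough that E_9 may represent them, via the `expanded` flag) — so
the `(a0, c)` cell, not q, is the robust output of the inverse fit.

## Code flow

Detections of code C at an electrode are quantised into 0.5 ms frames
(frame = start_bin // 5; counts, optionally clipped to binary).
`Φ_N(C)` is the maximum over the electrode's neighbours and over lags
−1, 0, +1 frames of the un-normalised cross-correlation
`Σ_t x_e(t)·x_f(t+ℓ)`. The electrodes sit much closer than in a real
array, so co-occurrence is high and no normalisation by code length is
applied. Neighbourhoods: 8N = Chebyshev distance 1; 20N = the 5 × 5 block
minus centre and four corners (the unique symmetric 20-electrode set),
both clipped at array edges; an empty neighbour set yields NaN. Enlarging
8N to 20N can only increase Φ. Per-electrode values and their array mean
are reported.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the laboratory setting —
stimulated spike waves on a lattice, unsorted multiunit pooling, code
statistics over 63 electrodes, 9-trial averaging — under exactly the
stated parameter distributions. It does not emulate irregular neuron
placement, distance-dependent connectivity or weights, electrode noise,
spike-waveform overlap, or plasticity. Passing the recovery test therefore
shows that the inverse method identifies parameters *within this model
family*; it does not by itself establish identifiability for real cultured
networks, where the component library and the recording would come from
different generative processes.

## Problem sizes and numerics

Default runs use the full 33 × 33 mesh, 2000-bin horizon and all 15 bit
widths. The test suite scales the fitting experiments down (reduced
(a0, c) grids, 1–3 trials, sometimes shorter horizons) — these sizes are
stated at each test and keep the whole suite under a minute while leaving
every code path exercised at full default sizes somewhere. Numerical
notes: spectra are float vectors (trial averaging makes them rational);
the simplex constraint is enforced to 1e−9; fit ties are broken toward
the uniform mixture; all-zero targets and all-missing libraries are
rejected with explicit errors.
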