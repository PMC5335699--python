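# Methods

## Model

Each node of a weighted structural network is a self-sustained oscillator
described only by its phase. The discrete-time (forward-Euler) update is

    θ_n(t+1) = θ_n(t) + ω_n + Σ_p K_np · sin(θ_p(t − τ_np) − θ_n(t))

- `ω_n = 2π f_n dt` — intrinsic angular velocity in rad/step; `f_n` is drawn
  uniformly from a frequency band, by default the gamma band 25–75 Hz.
- `K_np = k · C_np / N` — coupling matrix; `C_np` is the structural weight
  (GFA scale, typically 0.01–0.2), `k` the global coupling (default 1,000),
  and the canonical mean-field 1/N normalisation is applied (a
  `normalize_by_n=False` switch removes it, since the literature uses both
  conventions and the appropriate `k` differs accordingly).
- `τ_np = round(length_np / 20)` — integer conduction delay in steps, with
  round-half-to-even at the midpoint (50 mm → 2 steps). With `dt` = 1 ms this
  is a 20 m/s conduction velocity, a physiologically standard value; `dt` is
  a free parameter only through this identification, since the update rule
  itself is dimensionless.
- The model is deliberately **noise-free**. Multistability is probed by
  resampling initial conditions (uniform phases on [0, 2π) per node), not by
  stochastic exploration: each run either converges to an attracting
  synchronisation pattern or fails to, and distinct basins are revealed as
  distinct stabilised patterns.

Runs last 2,000 steps (2 s simulated); the first 100 steps are flagged as
pre-stabilisation transient and excluded from all synchrony computations.
Delay history for t < 0 is held constant at each node's initial phase (a
random-history option exists; for the attractor-sampling protocol the choice
only perturbs the transient).

### Assumptions and limits

Phase-only dynamics assume weak, slowly varying amplitude effects; Euler
integration of the *map* above is taken as the model definition rather than
as an approximation to an ODE, so no step-size convergence question arises.
At strong coupling (k = 1,000 with GFA-scale weights) per-step increments can
exceed π rad; the integration remains well defined (only non-finite phases
abort a run), but rendered signals `sin(θ)` are then aliased at the 1-step
sampling rate, which matters for the signal-pathway option below.

## Stroboscopic synchronisation index

For a node pair, take one as reference and extract the instants
`T_1 … T_M` at which its unwrapped phase crosses successive multiples of 2π.
The directional index is the circular mean resultant length of the concurrent
phase differences,

    ρ(q|p) = | (1/M) Σ_m exp(i (θ_q(T_m) − θ_p(T_m))) |,

and the reported index is the mean of `ρ(q|p)` and `ρ(p|q)`. It is 1 for a
pair locked at any fixed lag — including anti-phase — and 0 for uncorrelated
free-running oscillators. Lag-agnosticism is intentional: a large phase lag
can reflect strong but distant coupling, so unlike lag-penalising indices it
is not treated as weaker synchrony.

Numerical choices:

- **Crossing detection and interpolation.** `T_m` is located by linear
  interpolation of the unwrapped reference phase between samples, and the
  partner phase is interpolated to the same instant. At gamma frequencies a
  cycle spans only ~13–40 one-ms steps, so nearest-sample strobing would
  quantise the sampled phases visibly; a nearest-sample mode is available
  (`interpolate=False`).
- **Sampling error.** An unlocked pair's index is an average of M ≈ 95 unit
  vectors in a 1,900-step window, so it carries O(1/√M) ≈ 0.1 scatter; the
  index of a locked pair is exact. Any comparison between index estimates
  (e.g. between the two phase-extraction pathways, or after a global phase
  shift, which slides all strobe instants and can add/drop one event per
  window edge) is therefore reliable only to that scale for unlocked pairs.
- **Phase source.** Indices are computed directly from simulated phases by
  default. A fidelity mode (`source="signal"`) renders `sin(θ)` and
  re-extracts phases via the analytic signal (Hilbert transform), the route
  required for real oscillatory recordings. The two pathways agree to < 0.02
  for locked pairs; for unlocked pairs they differ at the strobe-sampling
  scale above, and in overdriven regimes (increments > π/step) the rendered
  signal is aliased and the signal pathway is not meaningful.
- Pair order is fixed: row-major upper triangle, (0,1), (0,2), …, (N−2,N−1);
  an N = 34 network yields 561 pairwise indices per run.
- Per-run patterns are averaged and mapped back to an N×N matrix for
  structure–function analysis, with the trivial diagonal set to 0.

## Attractor counting

Each dynamical system (one frequency vector bound to one network) is
simulated from `n_runs` = 100 random initialisations, giving an R×P pattern
matrix (P = N(N−1)/2). Columns are z-scored with the sample-variance
convention; zero-variance columns map to zero columns so P and the pair
order are preserved. The number of distinct patterns is selected by k-means
with the gap statistic:

    W_k = Σ_r D_r / (2 n_r),   Gap(k) = E*[log W_k] − log W_k

where `D_r` is the within-cluster sum of pairwise squared Euclidean distances
(so `W_k` equals the k-means inertia), and the expectation is estimated from
`n_reference` = 50 Monte-Carlo datasets drawn uniformly over the per-column
range of the standardised data (the simpler of Tibshirani's two reference
distributions). k is evaluated from 1 to 6 and chosen by the
one-standard-error rule — the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1},
`s_k = sd*(log W_k)·√(1 + 1/B)` — so "no multistability" (k = 1) is an
explicit outcome; an arg-max rule is available behind a flag because the
verbal "elbow" description admits both readings. k-means uses k-means++
seeding with 20 restarts. Ensembles whose rows are all identical short-circuit
to k = 1 with a degeneracy flag.

For reporting, runs are sorted by cluster label and the sorted **raw**
patterns are cross-correlated (Pearson) into an R×R matrix whose diagonal
blocks visualise the attractors; correlating the standardised rows instead is
an option. Rows with zero variance (fully saturated patterns) are assigned
zero off-diagonal correlation rather than NaN.

## Null models and comparisons

Null networks are built by connected Maslov–Sneppen double-edge swaps
(default 10 successful swaps per edge): a swap replaces edges (a,b),(c,d)
with (a,d),(c,b), each carrying its (weight, length) attribute pair, and is
reverted if it disconnects the graph. Node count, edge count, per-node degree
sequence, and the multiset of (weight, length) pairs are conserved; the
weight–length pairing on each edge is preserved rather than shuffled, since
both strength and length profiles are meant to be conserved jointly. For a
complete graph no swap is possible and the input topology is returned
unchanged (it is the unique graph with that degree sequence).

Network-level multistable potential is the distribution of optimal k over
`n_systems` = 200 independently frequency-sampled systems (40 per null
network, 15 null networks at protocol scale). Distributions are compared with
the two-sided two-sample KS test; the samples are small-support discrete
(k ∈ 1..6), and the asymptotic p-value is used by default (an exact option
exists for small samples). Contrast matrices subtract the null-average
pattern-correlation matrix from the real average; as a scalar diagnostic we
report the mean off-diagonal contrast within a near-diagonal band (band
width R/10) — a repository-defined summary of "high values aggregating near
the diagonal", since no quantitative criterion is standard. The
structure–function coupling is the Pearson r between the upper triangles of
the average-synchrony and weight matrices.

## Synthetic networks

The generator emulates the statistical structure of small tractography-derived
networks rather than any particular empirical matrix:

- **Topology**: planted balanced modules (default 4 on 34 nodes) with
  within/between edge probabilities 0.6/0.1; redrawn (same stream) until
  connected.
- **Weights**: log-normal on the GFA scale, median 0.05, σ = 0.6 (spanning
  roughly 0.01–0.2).
- **Lengths**: nodes are embedded in 3-D around their module centres
  (centre spread 1.0, node jitter 0.35 units); tract length = Euclidean
  distance × 45 mm/unit, floored at 20 mm (streamline tracking discards
  shorter fibres). Lengths therefore inherit a near-metric structure, and at
  1 ms steps give conduction delays of 1–8 steps.
- **Re-parcellation variant**: a coarse network can be split into more,
  smaller segments: children are distributed multinomially over parents (each
  parent keeps ≥ 1), every parent-level edge is inherited by exactly one
  random child pair with its attributes (keeping edge count comparable
  rather than duplicating edges to all pairs), and same-parent children are
  tied by short (20 mm) strong edges. The quotient graph over parents exactly
  recovers the original edge set.

What the generator does **not** reproduce: empirical degree/strength
correlations, hemispheric symmetry, the heavy spatial anisotropy of real
tract-length distributions, or measurement noise in GFA. Passing end-to-end
tests on these fixtures shows the pipeline's machinery is correct and that
modular anatomy raises multistable potential relative to rewired nulls; it
does not certify quantitative claims about any empirical brain network.

## Protocol scales and coupling calibration

Full-scale defaults (`RunConfig()`): 200 systems × 100 runs per network,
15 nulls × 40 systems, 2,000 steps, k = 1,000, k_max = 6. The test suite and
the worked example use a scaled-down smoke preset — an 8-node, 2-module
fixture (p_within = 0.9, p_between = 0.15), 20 systems × 20 runs, 3 nulls ×
7 systems — chosen so a full survey plus null comparison completes in
minutes on one CPU while exercising every stage at protocol shape.

The global coupling of the smoke preset was calibrated the same way k = 1,000
is motivated at full scale: to land in an *intermediate* range of
synchronisation levels. On the 8-node fixture the median pairwise index is
≈ 1 for k ≤ 120 (global locking), collapses below 0.1 for k ≥ 200
(overdriven), and passes through ≈ 0.5–0.6 around k = 150, which is the
preset value. This calibration used only the synchronisation level, not any
multistability outcome.

## Determinism

Every stochastic step (frequency sampling, initial phases, rewiring,
gap-statistic reference draws, k-means seeding) is driven by explicit seeds;
pipeline runs derive all sub-seeds hierarchically from one master seed
(master → stage → network → system → run), so any single simulation can be
replayed in isolation and identical configurations reproduce all numeric
artifacts byte-for-byte (matrices are written with `%.17g`, which round-trips
float64 exactly).

## Known limitations

- The coupling prefactor convention (with/without 1/N) is not standardised in
  the delayed-Kuramoto literature; both are supported and results depend on
  the pair (k, convention) only through their product with mean weight.
- The stroboscopic index of unlocked pairs is a stochastic estimate with
  O(1/√M) error at protocol window lengths; window extension is the only
  remedy.
- The gap statistic with a uniform-over-range reference is known to favour
  small k on strongly elongated clusters; patterns here are standardised
  first, which mitigates but does not remove this.
- KS p-values on heavily tied six-point discrete samples are asymptotic
  approximations; at smoke scale (20 vs 21 samples) they are indicative only.
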