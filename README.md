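# kurastab

Multistability analysis of delayed Kuramoto dynamics on weighted structural
brain networks.

## The problem

Tractography gives a *structural* network of a brain system: for every pair of
regions, a coupling strength (a generalised-fractional-anisotropy-scale weight
`C_np`) and a mean tract length in mm. A long-standing question is whether such
a network can support **multistability** — several distinct, stable
synchronisation patterns on the *same* anatomy — so that one set of active
regions could implement different processing modes as different coupling
configurations. `kurastab` implements the full simulation-and-analysis
pipeline for that question, for computational neuroscientists and
network-dynamics researchers:

1. **Dynamics.** Each region is a phase oscillator integrated with forward
   Euler (noise-free, delayed Kuramoto model):

   `θ_n(t+1) = θ_n(t) + ω_n + Σ_p K_np sin(θ_p(t − τ_np) − θ_n(t))`

   with intrinsic frequencies `f_n` drawn uniformly from the gamma band
   (25–75 Hz), `ω_n = 2π f_n dt` (dt = 1 ms), `K_np = k·C_np/N` (global
   coupling `k`, default 1,000), and integer conduction delays
   `τ_np = round(length_np / 20)` steps (20 m/s conduction at 1 ms steps).
   Runs last 2,000 steps; the first 100 are discarded as transient.

2. **Synchrony.** For every node pair a *stroboscopic* synchronisation index:
   sample the partner's phase at the instants the reference phase crosses
   multiples of 2π, average the complex unit vectors of the concurrent phase
   differences, take the norm, and average over the two role assignments.
   The index is 1 for a pair locked at *any* fixed lag (anti-phase included)
   and 0 for free-running uncorrelated oscillators.

3. **Attractor counting.** Each dynamical system (one frequency vector on one
   network) is simulated from many random initial phases (default 100); the
   resulting patterns are column-standardised and clustered by k-means with
   the Tibshirani gap statistic (`Gap(k) = E*[log W_k] − log W_k`, k ≤ 6,
   one-standard-error rule). `optimal_k ≥ 2` means multistable.

4. **Null comparison.** The distribution of `optimal_k` over many frequency
   vectors is compared against degree-, strength- and length-preserving
   rewired null networks (connected Maslov–Sneppen swaps; attributes travel
   with edges) with a two-sided two-sample KS test, plus contrast matrices of
   averaged pattern correlations and the structure–function correlation
   between average synchrony and coupling weights.

Because the original DSI-derived matrices are not deposited, the package
includes a synthetic-network generator (modular topology, spatially embedded
nodes, log-normal GFA-scale weights, distance-derived tract lengths) so the
whole pipeline is exercisable and testable end-to-end.

## Worked example

The scaled-down "smoke" protocol (8-node strongly modular fixture, 20 systems
× 20 runs, 3 rewired nulls × 7 frequency sets, k = 150 — see
`docs/methods.md` for the coupling calibration) runs in about two minutes:

```sh
kurastab run --preset smoke --seed 0 --out runs/smoke
```

prints (abridged):

```json
{
  "real_state_counts":  {"1": 0, "2": 8, "3": 10, "4": 2, "5": 0, "6": 0},
  "null_state_counts":  {"1": 6, "2": 12, "3": 3, "4": 0, "5": 0, "6": 0},
  "real_multistable_fraction": 1.0,
  "null_multistable_fraction": 0.714,
  "ks_statistic": 0.457,
  "ks_p_value": 0.0198,
  "structure_function_r": 0.282
}
```

Reading this: every one of the 20 frequency-sampled systems on the modular
fixture stabilised at ≥ 2 distinct synchronisation patterns (histogram peaked
at k = 3), while 6 of 21 null-network systems were monostable and none reached
k = 4 — the modular anatomy is more multistable than its degree-matched
rewirings (KS statistic 0.457). Average synchrony correlates positively
(r = 0.28) with coupling strength, the expected structure–function coupling.
The run directory additionally contains the network matrices, per-system
cluster assignments, the real-minus-null contrast matrix, and a manifest that
makes the run bit-reproducible.

Library use mirrors the CLI:

```python
import kurastab as ks

net = ks.generate_network(ks.SyntheticNetworkSpec(n_nodes=34, seed=1))
freqs = ks.sample_frequencies(net.n_nodes, (25, 75), seed=2)
system = ks.build_system(net, freqs, k_global=1000.0)
result = ks.assess(system, n_runs=100, seed=3)
print(result.optimal_k, result.is_multistable)
```

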