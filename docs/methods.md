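# Methods

This document specifies the models, algorithms, and parameter choices
implemented in `critresp`, and the rationale behind the desk-scale defaults.

## 1. Network model

### 1.1 Delay-coupled Stuart-Landau oscillators

Each brain region `j = 1..N` carries a complex state `z_j(t)` evolving as

```
dz_j = [ (λ + iω_j − |z_j|²) z_j  +  K Σ_k A_jk z_k(t − τ_jk)  +  u_j(t) ] dt  +  β dW_j
```

- `λ` is the Hopf bifurcation parameter.  For `λ > 0` the uncoupled,
  noise-free oscillator has a stable limit cycle of radius `√λ`; the default
  `λ = 1` places every node on a limit cycle of unit amplitude.
- `ω_j = 2πf_j` with `f_j ~ N(10 Hz, 0.5 Hz)`: heterogeneous alpha-band
  natural frequencies, redrawn per "frequency configuration".
- `A` is the binary, symmetric structural adjacency matrix; `K ≥ 0` is a
  single global coupling strength.  The coupling term is the plain
  (non-diffusive) sum of delayed neighbor states.
- `τ_jk = round(D_jk / v)` are conduction delays from the inter-region
  distances `D_jk` (mm) and conduction speed `v = 7 m/s`, rounded to integer
  steps of the integration grid (exact half-step ties round toward zero).
- `β = 0.05` scales additive complex white noise with independent real and
  imaginary components (`dW_j` has unit spectral density per component).
- `u_j(t)` is the pulsatile stimulus: a rectangular drift term of strength
  `p` applied to the target set on the open interval `t₁ < t < t₁ + T`,
  with `T = 50 ms`, `p = 10` for global (all-node) and `p = 30` for local
  (occipital) stimulation.

### 1.2 Numerical integration

The SDE is integrated with the Stratonovich-Heun predictor-corrector scheme
at `dt = 1 ms`: the predictor takes an Euler step, the corrector averages the
drift at the current and predicted states, and one Wiener increment is shared
by both stages.  Because the noise is additive, Itô and Stratonovich
interpretations coincide and the scheme is weak order 1, strong order 1 for
this model.  Delayed states are read from the trajectory buffer itself, so
the predictor of step `n` is visible to delayed reads of later steps at the
correct lags.

Runs start either from a small random state (`|z| = 0.1`, uniform phases,
held constant across the delay window) followed by a 10-s burn-in that is
discarded, or from the stored tail of a previous trajectory (continuation
runs used by the trial design, see §4).  The integrator is JIT-compiled
(numba) and bit-reproducible for a given seed.

## 2. Synthetic connectome

The reference substrate of the original study is a subject-measured
82-region diffusion-MRI connectome that is not redistributable.  The package
therefore ships a synthetic generator that reproduces the relevant summary
properties rather than any individual matrix:

- **Parcellation.** 82 regions: the 68 cortical regions of a
  Desikan-Killiany-style parcellation plus 14 subcortical structures, with
  approximate anatomical centroid coordinates mirrored across hemispheres
  and jittered by 4 mm per draw.
- **Spatial scale.** Centroids are rescaled so the maximum inter-region
  distance is 170 mm, keeping conduction delays below ~25 ms at 7 m/s
  (a quarter of the 10-Hz period).
- **Wiring rule.** Edges are drawn independently with probability
  `min(1, c·exp(−d/45 mm))`; the prefactor `c` is solved by bisection so the
  expected edge density matches the target 0.27, a typical density of
  group-averaged binarized DTI connectomes.  Distance-decaying wiring
  reproduces the short-range bias of tractography networks.  Draws are
  rejected until the graph is connected (bounded retries).
- **Occipital target set.** Local stimulation targets all regions within
  50 mm of the left cuneus centroid.  For non-82-node networks a generic
  brain-shaped ellipsoidal cloud is used and the most posterior node serves
  as the occipital seed.

Measured connectomes can be substituted via `load_connectome` (plain-text
adjacency + coordinates, or an explicit fiber-length matrix).

## 3. Criticality measures and state selection

- **Order parameter.** `r(t) = |N⁻¹ Σ_j e^{iθ_j(t)}|`, with
  `θ_j = arg z_j`.
- **Pair correlation function.** `PCF = N·Var[r(t)]`, the susceptibility
  analogue that peaks at the critical coupling.
- **Sweep.** For each frequency configuration, one unstimulated run
  (10-s burn-in, 25-s record) per coupling value on a grid over `[0, 0.4]`.
- **States.** Per configuration: `C_p` at the coupling maximizing the PCF
  (lowest coupling on ties); `C_b` / `C_a` at the couplings whose
  time-averaged `r` is nearest the 10th / 90th percentile of the averaged
  order parameters over the grid.

## 4. Stimulation trials

A trial needs (i) an ongoing-activity context at a random onset time and
(ii) a stimulated continuation.  Simulating every trial from a cold start
would spend most of the compute on burn-in, so the protocol uses a
branching design: per (configuration, state) one long unstimulated
*carrier* run is integrated; each trial reads its onset state (and hence
`r_s`, amplitudes, phases) directly from the carrier and branches at the
onset into the stimulated segment, integrated with fresh noise.  The
ongoing state at onset therefore carries the carrier's full slow history —
essential for relating instantaneous synchronization to the response,
because the baseline (below) is an ensemble around the recent past, and
only the carrier's actual excursion away from that ensemble makes the
trial's context informative.

- **Onsets.** `n_timings` onsets drawn uniformly over the carrier record,
  leaving room for the 1-s prestimulus segment (plus delay history) at the
  start and the stimulus + 500-ms window before the end.
- **Baseline.** Per trial, 10 fresh-noise realizations of the 1-s
  prestimulus segment are branched from the carrier state one second before
  onset; their node synchronization samples are pooled (10,000 samples per
  node).
- **Onset features.** At the onset step the carrier provides the global
  order parameter `r_s`, node amplitudes `|Z_sj|`, and node phases `θ_sj`
  (degrees).

## 5. Response quantification

- **Node synchronization.** `|S_j(t)|` is the modulus of the mean phase
  factor over node `j`'s `N_j` neighbors (the modulus makes the reference
  phase `θ_j` irrelevant).  Isolated nodes are excluded.
- **Binarization.** Post-stimulus values are z-scored against the pooled
  baseline mean/SD per node; `PR_j(t) = 1` where the z-score exceeds the
  empirical `(1 − α)` baseline quantile (`α = 0.05`), over the 500-ms
  window aligned at onset.  Nodes with degenerate (zero-variance) baselines
  never respond.
- **Responsivity.** `R_j` is the time average of `PR_j`; `⟨R⟩` averages
  over nodes.
- **Complexity.** The Lempel-Ziv 1976 exhaustive parsing counts phrases
  `c`.  Temporal complexity per node: `LZc_j = c_j · log₂(t)/t` over the
  window of `t` steps.  Spatial complexity per time step: the N-bit spatial
  pattern (canonical node order) gives `LZc(t) = c(t) · log₂(N)/N`;
  `⟨LZc⟩` averages over the window.
- **Amplitude responses.** The same binarization applied to `|z_j(t)|`
  yields amplitude responses; pooled onset amplitudes are also reported
  directly.

## 6. Statistical analysis

- Trials are split at the per-state mean of `r_s` into HS/LS; node-trials
  at the pooled mean amplitude into HA/LA (ties to the low class).
- Node phases at onset are assigned to 30 half-open 12° bins and to the two
  regimes `[60°, 240°)` and `[240°, 60°)`.
- Spearman rank correlation relates `r_s` to `⟨R⟩` and `⟨LZc⟩` per state.
- Kruskal-Wallis omnibus tests plus Tukey-Kramer multiple comparisons on
  rank-transformed data compare conditions; Wilcoxon rank-sum tests compare
  two groups; per-timepoint sign tests with a sustained-significance rule
  locate when one state's mean PR exceeds another's.
- Local stimulation node-trials are classified post hoc: *effective*
  (LS & LA & phases 240°-60°), *less effective* (HS & HA & phases
  60°-240°), and a *random* draw sized to the mean of the two counts.

## 7. Desk-scale design choices

The full-scale design (20 configurations × 30 timings = 600 trials per
state; coupling grid step 0.002) is the package default, but the bundled
acceptance script and test suite run a reduced design chosen to fit a
single CPU in minutes while keeping estimator errors inside the reported
tolerance bands:

| quantity | full scale | desk scale |
| --- | --- | --- |
| frequency configurations | 20 | 5 |
| timings per state | 30 | 40-60 |
| coupling grid step | 0.002 | 0.01 |
| trials per state | 600 | 200-300 |

Burn-in (10 s), record length (25 s), `dt` (1 ms), and all physiological
parameters are kept at full fidelity; only the number of repetitions is
reduced.

## 8. Limitations

- The synthetic connectome matches density, spatial embedding, and
  distance-decay statistics of DTI networks but not subject-specific
  topology; quantities sensitive to the exact network (e.g. the saturated
  coherence level far above the transition, and therefore the `C_a`
  statistics) can shift relative to measured-connectome results.
- Delays are rounded to the 1-ms integration grid; sub-millisecond delay
  structure is not represented.
- The binary adjacency ignores streamline-count weights.
- Euclidean centroid distances stand in for fiber lengths unless an
  explicit distance matrix is supplied.
- Statistical tests treat node-trials as exchangeable; within-trial
  dependence between nodes is not modeled.
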