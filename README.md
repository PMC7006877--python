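# critresp

**Criticality and responsiveness of delay-coupled alpha oscillations on
brain networks.**

`critresp` simulates a whole-brain network of delay-coupled Stuart-Landau
oscillators in the alpha band (10 Hz) and quantifies how the brain's
response to brief pulsatile stimulation depends on the network's proximity
to a critical state and on the instantaneous properties — synchronization,
amplitude, and phase — of the ongoing oscillation at the moment of
stimulation.

## The science in brief

Each of 82 brain regions carries a noisy Stuart-Landau (Hopf normal form)
oscillator; regions interact through a structural connectome with
distance-dependent conduction delays:

```
dz_j = [ (λ + iω_j − |z_j|²) z_j + K Σ_k A_jk z_k(t − τ_jk) + u_j(t) ] dt + β dW_j
```

Sweeping the global coupling `K` moves the network through a synchronization
phase transition, tracked by the Kuramoto order parameter `r(t)` and its
N-scaled variance (the pair correlation function, PCF), which peaks at the
critical coupling.  Three working states are selected per frequency
configuration: `C_b` below, `C_p` at, and `C_a` above the transition.

Brief pulses (`u_j = p` for 50 ms) are then applied at random times, and
the evoked change in each node's phase synchronization is binarized against
a prestimulus baseline into a perturbation-response matrix, summarized by
the responsivity `⟨R⟩` (how much of the network responds, for how long) and
the perturbational complexity `⟨LZc⟩` (Lempel-Ziv complexity of the spatial
response patterns).  The central phenomena this package reproduces:

- susceptibility (PCF) and responsiveness are maximal near criticality,
  and at the critical state the response magnitude and complexity depend
  strongly on the *instantaneous* state at stimulus onset;
- trials stimulated during high ongoing synchronization respond less
  (negative Spearman correlation between onset `r_s` and `⟨R⟩`/`⟨LZc⟩` at
  `C_p` only);
- responses depend on the oscillation phase at onset, and local (occipital)
  stimulation is most effective at low-synchronization, low-amplitude
  onsets in the favorable phase window.

Because the subject-measured diffusion-MRI connectome behind the original
study is not redistributable, the package ships a synthetic 82-region
connectome generator (Desikan-Killiany-style parcellation, exponential
distance-decay wiring at density 0.27); measured connectomes can be loaded
from plain-text files.  See `docs/methods.md` for the full model,
estimators, and limitations.

## Worked example

Generate a connectome, find the three states, and run a small stimulation
protocol (a few minutes on one CPU; the first call JIT-compiles the
integrator):

```python
import numpy as np
from critresp import (
    ProtocolConfig, generate_synthetic_connectome, run_global_protocol,
)
from critresp.analysis import spearman

conn = generate_synthetic_connectome(rng_seed=11)
cfg = ProtocolConfig(n_freq_configs=2, n_timings=20, dk=0.02, master_seed=7)
res = run_global_protocol(conn, cfg)

print(res.trials.groupby("state")["r_s"].median().round(3))
for c in range(res.profile.n_configs):
    sel = res.profile.selected[c]
    print(f"config {c}: K_b={sel['K_b']:.2f} K_p={sel['K_p']:.2f} K_a={sel['K_a']:.2f}")
cp = res.trials[res.trials.state == "C_p"]
rho, p = spearman(cp["r_s"], cp["R_mean"])
print(f"C_p: Spearman rho(r_s, <R>) = {rho:.2f} (p = {p:.1e}, n = {len(cp)})")
```

Output:

```text
state
C_a    0.883
C_b    0.107
C_p    0.251
Name: r_s, dtype: float64
config 0: K_b=0.10 K_p=0.18 K_a=0.36
config 1: K_b=0.04 K_p=0.16 K_a=0.36
C_p: Spearman rho(r_s, <R>) = -0.06 (p = 7.2e-01, n = 40)
```

At this toy scale (40 trials) the correlation is not statistically
resolved; the reproduction script below runs the 200-trial desk-scale
design.

The same pipeline is available from the command line:

```bash
critresp make-connectome --seed 11 --out-prefix net
critresp sweep --connectome net_adjacency.txt --coords net_coords.tsv \
    --dk 0.02 --configs 2 --seed 7 --out sweep_out
critresp global-protocol --seed 7 --scale 0.1 --dk 0.02 --out glob_out
critresp report --in glob_out
critresp local-protocol --seed 7 --scale 0.1 --dk 0.02 --out loc_out
```

## Package layout

| module | contents |
| --- | --- |
| `critresp.connectome` | synthetic connectome generator, file I/O, delays, target sets |
| `critresp.model` | Stuart-Landau network, Stratonovich-Heun integrator, stimuli |
| `critresp.criticality` | order parameter, PCF, coupling sweep, state selection |
| `critresp.response` | node synchronization, baseline z-scoring, PR, R, LZ76/LZc |
| `critresp.analysis` | onset features, HS/LS-HA/LA-phase grouping, statistics |
| `critresp.experiments` | global and local stimulation protocols, result tables |
| `critresp.cli` | `critresp` command-line interface |

## Reproduction

The repository includes a self-contained reproduction of the study's
headline numbers at desk scale (5 frequency configurations, 200 trials per
state, coupling grid step 0.01; full-fidelity burn-in, record length, and
time step):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This recomputes, from scratch (≈ 3-6 minutes on one CPU): the peak PCF at
`C_p` (t1), the median onset synchronization per state (t2–t4), the
Spearman correlations of `r_s` with `⟨R⟩` and `⟨LZc⟩` at `C_p` (t5–t6),
the mean perturbational complexity at `C_p` (t7), and the pooled median
onset amplitude at `C_a` (t8).  All randomness derives from `--seed`.

The test suite (`python -m pytest -q`) contains unit and property tests
plus `tests/test_acceptance.py`, which runs the full desk-scale protocol
once per session and checks every study-level criterion, including an
exact property suite (closed-form oscillator limits, LZ76 against a
brute-force oracle, baseline false-positive calibration, and bit-level
seed determinism of the whole protocol).
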