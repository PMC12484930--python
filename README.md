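# dsrspike

Tools for partitioning the spiking variability of neurons into **firing-rate
fluctuations** and **spiking irregularity**, built around the doubly
stochastic renewal (DSR) point process.

Neural spike trains vary from trial to trial for two distinct reasons: the
underlying firing rate λ(t) fluctuates (a network-level, slow source of
variability), and the spike-generation process itself is irregular (a fast,
cell-level source). The common inhomogeneous Poisson model pins the second
source at a fixed level — Fano factor one for constant rate — and cannot
describe the many cortical neurons that spike more regularly (FF < 1) or more
irregularly than Poisson. The DSR process generalizes it: spikes form a
renewal process with interspike-interval (ISI) density *g*(·) in
*operational time* t′ = Λ(t) = ∫₀ᵗ λ(s)ds, with the mean of *g* fixed at
μ_g = 1 s so that spiking in operational time is stationary renewal at 1 Hz.
A single parameter

φ = σ_g²/μ_g²  (the squared coefficient of variation of *g*)

controls irregularity: φ = 1 is Poisson, φ < 1 sub-Poisson, φ > 1
super-Poisson. For a gamma ISI density with unit mean, the across-trial
spike-count variance in bins of size T decomposes as

Var(N_T) = Var(λT) + φ·E[N_T] + (1 − φ²)/6 + O(1/T).

Applying this relation at two bin sizes T and αT (α = 2) eliminates the
unknown rate variance and yields a quadratic whose stable root estimates φ
from count moments alone — the **DSR estimator**. The package is intended
for systems and computational neuroscientists analyzing trial-structured
spike data or building spiking-network models.

## What's inside

| module | contents |
| --- | --- |
| `dsrspike.rate_models` | constant, uniform-across-trial, and sticky-boundary drift–diffusion rate processes |
| `dsrspike.simulator` | DSR spike-train generator (sample rate → renewal ISIs in operational time → warp to real time); inhomogeneous Poisson as the φ = 1 case |
| `dsrspike.estimators` | DSR quadratic estimator, variance partitioning, DTR (PSTH time-rescaling) and MR (minimum Fano factor) reference estimators, exact renewal count moments, MR bias prediction, unit-selection filter, modulation indices |
| `dsrspike.voltage` | intracellular validation pipeline: spike removal, voltage-to-rate spline fit, rescaling by the voltage-derived rate; synthetic voltage generator |
| `dsrspike.network` | spatially ordered three-layer balanced network of exponential integrate-and-fire neurons, with the attention experiment |
| `dsrspike.benchmark` | estimator benchmark across ground-truth φ and rate-variability grids |
| `dsrspike.io`, `dsrspike.cli` | delimited-text I/O and the `dsrspike` command-line umbrella |

## Worked example

```python
import dsrspike as d

# ground truth: phi = 0.3, rate constant within trials but uniform across
# trials on [20, 40] Hz — rate variance masquerades as irregularity for
# naive estimators
rates = d.sample_uniform_trial_rates(
    d.UniformTrialRateSpec(mu=30, w=20), duration=2.0, dt=1e-3,
    n_trials=200, seed=21,
)
spikes = d.simulate_dsr(d.ISIModel(phi=0.3), rates, seed=22)

for fn in (d.estimate_phi_dsr, d.estimate_phi_dtr, d.estimate_phi_mr):
    est = fn(spikes)
    print(f"{est.method}: phi = {est.phi:.3f}")

T = d.choose_bin_size(spikes)            # T = 2 / mean rate
part = d.partition_variance(spikes, 0.3, T)
print(f"T = {T*1e3:.0f} ms, rate variance fraction = "
      f"{(part.rate_variance / part.total_variance).mean():.2f}")
```

Output:

```
DSR: phi = 0.318
DTR: phi = 0.354
MR: phi = 0.305
T = 66 ms, rate variance fraction = 0.18
```

The DSR estimator lands within sampling error of the true φ = 0.3 and is
unbiased over replicates. The time-rescaling reference (DTR) overestimates
systematically because it attributes across-trial rate variance to the point
process — the gap grows with the rate spread *w*; the minimum-Fano reference
(MR) carries rate-variance and finite-bin biases of opposite sign that
partially cancel at this setting. The partition attributes 18% of the count
variance in 66 ms bins to rate fluctuations, matching the closed form
T²w²/12 ≈ 0.15 spikes² against Var(N_T) ≈ 0.9 spikes² for this rate spread.

The same operations are available from the shell:

```bash
dsrspike simulate --phi 0.3 --rate-model uniform --trials 200 --seed 21 --out spikes.csv
dsrspike estimate --method dsr --spikes spikes.csv --out phi.json
```

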